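"""Synthetic MIC/MAC architectures with planted ground truth.

Generates random germline layouts — Russian-doll chains of nested loci,
interleaved pairs, and a mix of arrangement patterns (identity,
odd-even repeat/return, tangled cords, random signed permutations) —
together with the planted per-contig truth (IDI, EI, relationship
class, scrambled flag), so every analysis stage can be exercised
without a genome download.  Only coordinates are modelled; pointer
microhomology bases are symbolic.

Defaults emulate the genome-wide study conditions: mean MDS count 9.7
per contig, ~12.8% scrambled loci, ~8% of contigs nested (IDI >= 1)
with a rapidly decaying depth tail, and ~3% interleaved.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` (PCG64); identical seeds give byte-identical
GFF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrangements import (
    FORWARD,
    INVERTED,
    ArrangementMap,
    MdsRecord,
    format_arrangement,
    is_scrambled,
    parse_arrangement,
)
from .gff_io import AnnotationFile

PATTERNS = (
    "nonscrambled",
    "odd_even",
    "inverted_odd_even",
    "tangled_cord",
    "random_permutation",
)


class SimError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_mic_contigs: int = 4
    loci_per_contig: int = 8
    # probability that a top-level locus starts a doll chain of the given depth
    nesting_depth_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.90, 1: 0.08, 2: 0.015, 3: 0.004, 4: 0.001}
    )
    fraction_interleaved: float = 0.03
    # genome-wide scrambled fraction 12.8%, split across pattern kinds
    scramble_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "nonscrambled": 0.872,
            "odd_even": 0.06,
            "inverted_odd_even": 0.03,
            "tangled_cord": 0.02,
            "random_permutation": 0.018,
        }
    )
    tangled_n_range: tuple[int, int] = (2, 4)
    mds_count_mean: float = 9.7  # sampled as 2 + Poisson(mean - 2)
    mds_length_range: tuple[int, int] = (30, 600)
    ies_length_range: tuple[int, int] = (20, 200)
    locus_gap_range: tuple[int, int] = (200, 1000)
    max_ies_length: int | None = None

    def __post_init__(self) -> None:
        for name, dist in (
            ("nesting_depth_distribution", self.nesting_depth_distribution),
            ("scramble_mix", self.scramble_mix),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise SimError(f"{name} proportions must sum to 1, got {total}")
        unknown = set(self.scramble_mix) - set(PATTERNS)
        if unknown:
            raise SimError(f"unknown scramble_mix patterns: {sorted(unknown)}")
        for name, rng_ in (
            ("mds_length_range", self.mds_length_range),
            ("ies_length_range", self.ies_length_range),
            ("locus_gap_range", self.locus_gap_range),
        ):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise SimError(f"{name} must be positive and ordered, got {rng_}")


@dataclass(frozen=True)
class TruthRecord:
    mac_contig_id: str
    idi: int
    ei: int
    relationship_class: str
    scrambled: bool
    pattern: str
    arrangement: str
    mds_count: int


@dataclass
class SyntheticTruth:
    records: list[TruthRecord]

    def by_mac(self) -> dict[str, TruthRecord]:
        return {t.mac_contig_id: t for t in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [t.__dict__ for t in sorted(self.records, key=lambda t: t.mac_contig_id)],
            columns=[
                "mac_contig_id",
                "idi",
                "ei",
                "relationship_class",
                "scrambled",
                "pattern",
                "arrangement",
                "mds_count",
            ],
        )


# ---------------------------------------------------------------------------
# explicit architecture builder (also used by test fixtures)
# ---------------------------------------------------------------------------

@dataclass
class LocusSpec:
    """One locus to place: arrangement plus children nested per IES gap.

    ``children`` maps a MIC-order gap index (0 = between the first and
    second MDS in MIC order) to the loci to insert into that IES.
    """

    mac_id: str
    arrangement: ArrangementMap | str
    children: dict[int, list["LocusSpec"]] = field(default_factory=dict)
    pattern: str = "explicit"

    def arrangement_map(self) -> ArrangementMap:
        if isinstance(self.arrangement, str):
            return parse_arrangement(self.arrangement, mac_contig_id=self.mac_id)
        return self.arrangement


def _build_locus(
    spec: LocusSpec,
    mic_id: str,
    mds_len: Callable[[], int],
    ies_len: Callable[[], int],
    max_ies_length: int | None,
) -> tuple[list[MdsRecord], int]:
    """Lay a locus (and its nested children) out from relative position 0.

    Returns records (relative coordinates, later shifted) and the total
    span length.
    """
    arr = spec.arrangement_map()
    k_entries = len(arr.entries)
    if k_entries < 1:
        raise SimError(f"locus {spec.mac_id!r} has no MDSs")
    for gap in spec.children:
        if not 0 <= gap < k_entries - 1:
            raise SimError(
                f"locus {spec.mac_id!r}: child gap index {gap} out of range "
                f"(locus has {k_entries - 1} IESs)"
            )
    records: list[MdsRecord] = []
    pos = 0
    for j, (idx, orient) in enumerate(arr.entries):
        length = mds_len()
        records.append(
            MdsRecord(
                mic_contig_id=mic_id,
                mac_contig_id=spec.mac_id,
                mds_index=idx,
                mic_start=pos,
                mic_end=pos + length - 1,
                orientation=orient,
            )
        )
        pos += length
        if j == k_entries - 1:
            break
        gap_len = ies_len()
        child_blocks: list[tuple[list[MdsRecord], int]] = []
        for child in spec.children.get(j, ()):  # children nested in this IES
            child_blocks.append(_build_locus(child, mic_id, mds_len, ies_len, max_ies_length))
        if child_blocks:
            inner = pos + ies_len()
            for block, span in child_blocks:
                records.extend(_shift(block, inner))
                inner += span + ies_len()
            gap_len = (inner - pos) + gap_len
        if max_ies_length is not None and gap_len > max_ies_length:
            raise SimError(
                f"locus {spec.mac_id!r}: IES after MIC position {j} needs "
                f"{gap_len} bp to host its children, exceeding max_ies_length="
                f"{max_ies_length}"
            )
        pos += gap_len
    return records, pos


def _shift(records: Sequence[MdsRecord], offset: int) -> list[MdsRecord]:
    return [
        MdsRecord(
            mic_contig_id=r.mic_contig_id,
            mac_contig_id=r.mac_contig_id,
            mds_index=r.mds_index,
            mic_start=r.mic_start + offset,
            mic_end=r.mic_end + offset,
            orientation=r.orientation,
        )
        for r in records
    ]


def realize(
    mic_id: str,
    loci: Sequence[LocusSpec],
    *,
    start: int = 1,
    mds_len: int = 100,
    ies_len: int = 60,
    gap_between: int = 500,
) -> list[MdsRecord]:
    """Deterministically place explicit loci on one MIC contig.

    Fixture-grade variant of the generator: fixed MDS/IES lengths, loci
    separated by ``gap_between``.  Children declared in
    :class:`LocusSpec` are nested inside the corresponding IES.
    """
    records: list[MdsRecord] = []
    pos = start
    for spec in loci:
        block, span = _build_locus(spec, mic_id, lambda: mds_len, lambda: ies_len, None)
        records.extend(_shift(block, pos))
        pos += span + gap_between
    return sorted(records, key=lambda r: (r.mic_start, r.mic_end, r.mac_contig_id))


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

def _draw_k(rng: np.random.Generator, config: SimConfig, minimum: int = 2) -> int:
    k = 2 + int(rng.poisson(max(config.mds_count_mean - 2.0, 0.1)))
    return max(k, minimum)


def _pattern_arrangement(
    pattern: str, mac_id: str, rng: np.random.Generator, config: SimConfig
) -> ArrangementMap:
    if pattern == "nonscrambled":
        k = _draw_k(rng, config)
        entries = tuple((i, FORWARD) for i in range(1, k + 1))
    elif pattern == "odd_even":
        k = _draw_k(rng, config, minimum=4)
        order = list(range(1, k + 1, 2)) + list(range(2, k + 1, 2))
        entries = tuple((i, FORWARD) for i in order)
    elif pattern == "inverted_odd_even":
        # odds ascending forward, evens descending inverted (a return word)
        k = _draw_k(rng, config, minimum=4)
        odds = tuple((i, FORWARD) for i in range(1, k + 1, 2))
        evens = tuple((i, INVERTED) for i in range(_largest_even_leq(k), 0, -2))
        entries = odds + evens
    elif pattern == "tangled_cord":
        lo, hi = config.tangled_n_range
        n = int(rng.integers(lo, hi + 1))
        # M2 M1 -M3 -M4 ... -M(n+1) M(n+2) has pointer word TC(n)
        entries = ((2, FORWARD), (1, FORWARD))
        entries += tuple((i, INVERTED) for i in range(3, n + 2))
        entries += ((n + 2, FORWARD),)
    elif pattern == "random_permutation":
        k = _draw_k(rng, config, minimum=3)
        order = rng.permutation(k) + 1
        entries = tuple(
            (int(i), INVERTED if rng.random() < 0.5 else FORWARD) for i in order
        )
    else:
        raise SimError(f"unknown pattern {pattern!r}")
    return ArrangementMap(mac_contig_id=mac_id, entries=entries)


def _largest_even_leq(k: int) -> int:
    return k if k % 2 == 0 else k - 1


def generate(config: SimConfig) -> tuple[AnnotationFile, SyntheticTruth]:
    """Sample an annotation file plus its planted truth.

    Doll chains are built by inserting each child locus wholly into one
    IES of its parent (layer *i* of a depth-*d* chain gets planted
    IDI = d - i and EI = i); interleaved pairs alternate the MDSs of
    two loci.  Everything else is a standalone locus.
    """
    rng = np.random.default_rng(config.seed)
    mds_len = lambda: int(rng.integers(*config.mds_length_range, endpoint=True))
    ies_len = lambda: int(rng.integers(*config.ies_length_range, endpoint=True))
    gap = lambda: int(rng.integers(*config.locus_gap_range, endpoint=True))

    depths = sorted(config.nesting_depth_distribution)
    depth_p = [config.nesting_depth_distribution[d] for d in depths]
    mix_names = [p for p in PATTERNS if p in config.scramble_mix]
    mix_p = [config.scramble_mix[p] for p in mix_names]

    serial = 0

    def next_mac() -> str:
        nonlocal serial
        serial += 1
        return f"mac{serial:05d}"

    records: list[MdsRecord] = []
    truths: list[TruthRecord] = []

    def sample_locus(mac_id: str) -> tuple[LocusSpec, str, ArrangementMap]:
        pattern = str(rng.choice(mix_names, p=mix_p))
        arr = _pattern_arrangement(pattern, mac_id, rng, config)
        return LocusSpec(mac_id, arr, pattern=pattern), pattern, arr

    for m in range(config.n_mic_contigs):
        mic_id = f"mic{m:04d}"
        pos = 1
        for _ in range(config.loci_per_contig):
            if rng.random() < config.fraction_interleaved:
                block, span = _interleaved_pair(
                    mic_id, next_mac(), next_mac(), rng, config, mds_len, ies_len, truths,
                    sample_locus,
                )
            else:
                depth = int(rng.choice(depths, p=depth_p))
                block, span = _doll_chain(
                    mic_id, depth, rng, config, mds_len, ies_len, truths, sample_locus,
                    next_mac,
                )
            records.extend(_shift(block, pos))
            pos += span + gap()

    records.sort(key=lambda r: (r.mic_contig_id, r.mic_start, r.mic_end, r.mac_contig_id))
    annotation = AnnotationFile(records=records, source_dialect="scramblekit-sim")
    return annotation, SyntheticTruth(records=truths)


def _doll_chain(
    mic_id, depth, rng, config, mds_len, ies_len, truths, sample_locus, next_mac
) -> tuple[list[MdsRecord], int]:
    """Chain of depth+1 loci, each wholly inside one IES of its parent."""
    specs: list[tuple[LocusSpec, str, ArrangementMap]] = [
        sample_locus(next_mac()) for _ in range(depth + 1)
    ]
    # wire children innermost-first
    for outer_i in range(depth):
        spec, _, arr = specs[outer_i]
        child_spec = specs[outer_i + 1][0]
        host_gap = int(rng.integers(0, len(arr.entries) - 1))
        spec.children[host_gap] = [child_spec]
    for layer, (spec, pattern, arr) in enumerate(specs):
        truths.append(
            TruthRecord(
                mac_contig_id=spec.mac_id,
                idi=depth - layer,
                ei=layer,
                relationship_class="none" if layer == 0 else "embedded_only",
                scrambled=is_scrambled(arr),
                pattern=pattern,
                arrangement=format_arrangement(arr),
                mds_count=len(arr.entries),
            )
        )
    return _build_locus(specs[0][0], mic_id, mds_len, ies_len, config.max_ies_length)


def _interleaved_pair(
    mic_id, mac_a, mac_b, rng, config, mds_len, ies_len, truths, sample_locus
) -> tuple[list[MdsRecord], int]:
    """Two loci with strictly alternating MDSs: A1 B1 A2 B2 ... Am Bm."""
    spec_a, pat_a, arr_a = sample_locus(mac_a)
    spec_b, pat_b, arr_b = sample_locus(mac_b)
    m = min(len(arr_a.entries), len(arr_b.entries))
    if m < 2:
        m = 2
    arr_a = ArrangementMap(mac_a, _trim_entries(arr_a, m))
    arr_b = ArrangementMap(mac_b, _trim_entries(arr_b, m))
    records: list[MdsRecord] = []
    pos = 0
    for j in range(m):
        for mac, arr in ((mac_a, arr_a), (mac_b, arr_b)):
            idx, orient = arr.entries[j]
            length = mds_len()
            records.append(
                MdsRecord(mic_id, mac, idx, pos, pos + length - 1, orient)
            )
            pos += length
            if not (j == m - 1 and mac == mac_b):
                pos += ies_len()
    for arr, pattern in ((arr_a, pat_a), (arr_b, pat_b)):
        truths.append(
            TruthRecord(
                mac_contig_id=arr.mac_contig_id,
                idi=1,
                ei=1,
                relationship_class="interleaved_only",
                scrambled=is_scrambled(arr),
                pattern=pattern,
                arrangement=format_arrangement(arr),
                mds_count=len(arr.entries),
            )
        )
    return records, pos


def _trim_entries(arr: ArrangementMap, m: int) -> tuple[tuple[int, str], ...]:
    """Keep the arrangement complete while truncating to m MDSs.

    Re-rank the first m entries so indices remain 1..m (order and
    orientation pattern preserved)."""
    head = arr.entries[:m]
    if len(head) < m:  # pad by extending the identity
        known = {i for i, _ in head}
        extra = [i for i in range(1, m + 1) if i not in known][: m - len(head)]
        head = head + tuple((i, FORWARD) for i in extra)
    rank = {idx: r + 1 for r, idx in enumerate(sorted(i for i, _ in head))}
    return tuple((rank[i], o) for i, o in head)
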