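"""Nesting metrics for germline loci: insertion depth and embedding.

When the MDSs of several MAC contigs share one MIC region, whole loci
can sit inside the IESs of other loci ("Russian doll" genes).  Two
indices quantify this:

* **IDI** (insertion depth index) — recursive count of nesting events
  on an IES: an IES containing no foreign MDS has IDI 0; otherwise its
  IDI is one more than the deepest IDI among the foreign contigs'
  IESs strictly inside it.  A contig's IDI is the maximum over its
  IESs, so an outermost doll of a depth-*d* chain scores *d*.
* **EI** (embedding index) — for an MDS, the number of distinct foreign
  contigs with an IES containing it (the layers surrounding it); a
  contig's EI is the maximum over its MDSs, so the innermost doll of a
  depth-*d* chain scores *d*.

Pairs of contigs are further classified as *embedded* (all MDSs of one
inside a single IES of the other) or *interleaved* (at least one MDS of
each inside an IES of the other), mirroring genome-wide tabulations of
embedding/interleaving counts and their scrambling enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .arrangements import (
    FORWARD,
    INVERTED,
    ArrangementMap,
    IesInterval,
    MdsRecord,
    arrangement_from_records,
    ies_intervals,
    is_scrambled,
)

RELATIONSHIP_CLASSES = ("none", "embedded_only", "interleaved_only", "both")


@dataclass(frozen=True)
class NestingReport:
    """Per-MAC-contig nesting summary."""

    mac_contig_id: str
    idi: int
    ei: int
    relationship_class: str
    scrambled: bool
    mds_count: int
    excluded: bool = False
    complete: bool = True


@dataclass(frozen=True)
class EnrichmentStats:
    """Scrambling-enrichment statistics over a report cohort."""

    chi2: float
    chi2_p: float
    contingency: tuple[tuple[int, int], tuple[int, int]]
    rho: float
    rho_p: float
    class_table: pd.DataFrame
    warnings: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# per-MIC-contig layout
# ---------------------------------------------------------------------------

class _MicLayout:
    """Indexed view of all MDS records on one MIC contig."""

    def __init__(self, records: Sequence[MdsRecord]):
        mics = {r.mic_contig_id for r in records}
        if len(mics) > 1:
            raise ValueError(f"layout spans several MIC contigs: {sorted(mics)}")
        by_mac: dict[str, list[MdsRecord]] = {}
        for r in records:
            by_mac.setdefault(r.mac_contig_id, []).append(r)
        self.mds: dict[str, list[MdsRecord]] = {
            mac: sorted(rs, key=lambda r: (r.mic_start, r.mic_end))
            for mac, rs in by_mac.items()
        }
        self.ies: dict[str, list[IesInterval]] = {
            mac: ies_intervals(rs) if len(rs) >= 2 else []
            for mac, rs in self.mds.items()
        }

    def macs(self) -> list[str]:
        return sorted(self.mds)


def _inside(interval: tuple[int, int], span: tuple[int, int]) -> bool:
    return span[0] <= interval[0] and interval[1] <= span[1]


def _strictly_inside(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return _inside(inner, outer) and inner != outer


def _as_layout(layout) -> _MicLayout:
    return layout if isinstance(layout, _MicLayout) else _MicLayout(list(layout))


# ---------------------------------------------------------------------------
# spec operations
# ---------------------------------------------------------------------------

def ei_of_contig(target: str, layout) -> int:
    """Embedding index: max over the target's MDSs of the number of
    distinct foreign contigs with an IES containing that MDS."""
    lay = _as_layout(layout)
    if target not in lay.mds:
        raise KeyError(f"MAC contig {target!r} has no MDSs in this layout")
    best = 0
    for rec in lay.mds[target]:
        depth = sum(
            1
            for mac, iess in lay.ies.items()
            if mac != target and any(_inside(rec.interval, e.interval) for e in iess)
        )
        best = max(best, depth)
    return best


def _idi_of_ies(
    ies: IesInterval, lay: _MicLayout, memo: dict[tuple[str, int, int], int]
) -> int:
    key = (ies.mac_contig_id, ies.start, ies.end)
    if key in memo:
        return memo[key]
    span = ies.interval
    depth = 0
    for mac, recs in lay.mds.items():
        if mac == ies.mac_contig_id:
            continue
        if not any(_inside(r.interval, span) for r in recs):
            continue
        inner = 0
        for sub in lay.ies.get(mac, ()):  # descend only into strictly smaller IESs
            if _strictly_inside(sub.interval, span):
                inner = max(inner, _idi_of_ies(sub, lay, memo))
        depth = max(depth, 1 + inner)
    memo[key] = depth
    return depth


def idi_of_contig(target: str, layout) -> int:
    """Insertion depth index: max over the target's IESs of the
    recursive nesting count."""
    lay = _as_layout(layout)
    if target not in lay.mds:
        raise KeyError(f"MAC contig {target!r} has no MDSs in this layout")
    memo: dict[tuple[str, int, int], int] = {}
    return max((_idi_of_ies(e, lay, memo) for e in lay.ies.get(target, ())), default=0)


def classify_pair(a: str, b: str, layout) -> str:
    """Relationship between two MAC contigs sharing a MIC contig.

    Returns one of ``a_embedded_in_b``, ``b_embedded_in_a``,
    ``interleaved`` (at least one MDS of each inside an IES of the
    other) or ``none``.  Embedding requires *all* of the inner contig's
    MDSs within a *single* IES of the outer one.
    """
    lay = _as_layout(layout)
    for mac in (a, b):
        if mac not in lay.mds:
            raise KeyError(f"MAC contig {mac!r} has no MDSs in this layout")

    def embedded(inner: str, outer: str) -> bool:
        recs = lay.mds[inner]
        return any(
            all(_inside(r.interval, e.interval) for r in recs)
            for e in lay.ies.get(outer, ())
        )

    def has_mds_inside(inner: str, outer: str) -> bool:
        return any(
            _inside(r.interval, e.interval)
            for r in lay.mds[inner]
            for e in lay.ies.get(outer, ())
        )

    if embedded(a, b):
        return "a_embedded_in_b"
    if embedded(b, a):
        return "b_embedded_in_a"
    if has_mds_inside(a, b) and has_mds_inside(b, a):
        return "interleaved"
    return "none"


def relationship_class(target: str, layout) -> str:
    """Aggregate pairwise relations of one contig: none / embedded_only /
    interleaved_only / both."""
    lay = _as_layout(layout)
    embedded = interleaved = False
    for other in lay.macs():
        if other == target:
            continue
        rel = classify_pair(target, other, lay)
        if rel == "a_embedded_in_b":
            embedded = True
        elif rel == "interleaved":
            interleaved = True
    if embedded and interleaved:
        return "both"
    if embedded:
        return "embedded_only"
    if interleaved:
        return "interleaved_only"
    return "none"


def terminal_overlap_filter(records: Sequence[MdsRecord], overlap_bp: int = 20) -> set[str]:
    """MAC contigs sharing > ``overlap_bp`` of MIC sequence with another.

    MDSs mapping to distinct MAC contigs whose sequences overlap on the
    MIC (beyond pointer scale) indicate alternative fragmentation /
    shared terminal segments; both partners are excluded from nesting
    metrics.
    """
    excluded: set[str] = set()
    by_mic: dict[str, list[MdsRecord]] = {}
    for r in records:
        by_mic.setdefault(r.mic_contig_id, []).append(r)
    for recs in by_mic.values():
        recs = sorted(recs, key=lambda r: (r.mic_start, r.mic_end))
        for i, r1 in enumerate(recs):
            for r2 in recs[i + 1 :]:
                if r2.mic_start > r1.mic_end:
                    break
                if r1.mac_contig_id == r2.mac_contig_id:
                    continue
                overlap = min(r1.mic_end, r2.mic_end) - r2.mic_start + 1
                if overlap > overlap_bp:
                    excluded.add(r1.mac_contig_id)
                    excluded.add(r2.mac_contig_id)
    return excluded


# ---------------------------------------------------------------------------
# whole-annotation analysis
# ---------------------------------------------------------------------------

def _portion_scrambled(arrangement: ArrangementMap) -> bool:
    # Incomplete maps: judge the observed portion only — nonscrambled iff
    # indices increase all-forward or decrease all-inverted.
    idx = arrangement.indices
    orients = tuple(o for _, o in arrangement.entries)
    ascending = all(b > a for a, b in zip(idx, idx[1:]))
    descending = all(b < a for a, b in zip(idx, idx[1:]))
    if ascending and all(o == FORWARD for o in orients):
        return False
    if descending and all(o == INVERTED for o in orients):
        return False
    return True


def analyze(records: Sequence[MdsRecord], overlap_bp: int = 20) -> list[NestingReport]:
    """Compute a :class:`NestingReport` for every MAC contig.

    MIC contigs are processed independently; a MAC contig spread over
    several MIC contigs is flagged incomplete and aggregated by taking
    the maximum IDI/EI over its portions.  Contigs caught by the
    terminal-overlap filter are reported with ``excluded=True`` and do
    not participate in any metric.
    """
    excluded = terminal_overlap_filter(records, overlap_bp)
    by_mic: dict[str, list[MdsRecord]] = {}
    by_mac: dict[str, list[MdsRecord]] = {}
    for r in records:
        by_mic.setdefault(r.mic_contig_id, []).append(r)
        by_mac.setdefault(r.mac_contig_id, []).append(r)

    idi: dict[str, int] = {}
    ei: dict[str, int] = {}
    emb: dict[str, bool] = {}
    ilv: dict[str, bool] = {}
    for mic_records in by_mic.values():
        kept = [r for r in mic_records if r.mac_contig_id not in excluded]
        if not kept:
            continue
        lay = _MicLayout(kept)
        for mac in lay.macs():
            idi[mac] = max(idi.get(mac, 0), idi_of_contig(mac, lay))
            ei[mac] = max(ei.get(mac, 0), ei_of_contig(mac, lay))
            rel = relationship_class(mac, lay)
            emb[mac] = emb.get(mac, False) or rel in ("embedded_only", "both")
            ilv[mac] = ilv.get(mac, False) or rel in ("interleaved_only", "both")

    reports: list[NestingReport] = []
    for mac in sorted(by_mac):
        recs = by_mac[mac]
        mics = sorted({r.mic_contig_id for r in recs})
        indices = sorted(r.mds_index for r in recs)
        complete = len(mics) == 1 and indices == list(range(1, max(indices) + 1))
        scrambled = False
        for mic in mics:
            portion = arrangement_from_records([r for r in recs if r.mic_contig_id == mic])
            if complete:
                scrambled = is_scrambled(portion)
            elif _portion_scrambled(portion):
                scrambled = True
        if not complete:
            warnings.warn(
                f"MAC contig {mac!r} is incomplete (indices {indices} over "
                f"{len(mics)} MIC contig(s)); scrambled flag judged from the "
                "observed portion",
                stacklevel=2,
            )
        if mac in excluded:
            reports.append(
                NestingReport(mac, 0, 0, "none", scrambled, len(recs), True, complete)
            )
            continue
        klass = (
            "both"
            if emb.get(mac) and ilv.get(mac)
            else "embedded_only"
            if emb.get(mac)
            else "interleaved_only"
            if ilv.get(mac)
            else "none"
        )
        reports.append(
            NestingReport(
                mac_contig_id=mac,
                idi=idi.get(mac, 0),
                ei=ei.get(mac, 0),
                relationship_class=klass,
                scrambled=scrambled,
                mds_count=len(recs),
                excluded=False,
                complete=complete,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# cohort statistics and summary tables
# ---------------------------------------------------------------------------

def spearman_by_class(class_values: Sequence[float], proportions: Sequence[float]):
    """Spearman rank correlation of class value vs per-class aggregate.

    The cohort-level test correlates each IDI class with its scrambled
    proportion, exactly as genome-wide tabulations report it (one data
    point per class; small-n caveat applies to the p-value).
    """
    res = stats.spearmanr(class_values, proportions)
    return float(res.statistic), float(res.pvalue)


def enrichment_stats(reports: Iterable[NestingReport]) -> EnrichmentStats:
    """Chi-square (scrambled x IDI>=1) and Spearman (IDI class vs
    scrambled proportion) over included reports.

    The 2x2 chi-square uses 1 df without continuity correction.
    Degenerate layouts (a single IDI class, or constant proportions)
    yield NaN statistics with an explanatory warning rather than a
    silent zero.
    """
    rows = [r for r in reports if not r.excluded]
    notes: list[str] = []
    nested = np.array([r.idi >= 1 for r in rows])
    scrambled = np.array([r.scrambled for r in rows])

    chi2 = chi2_p = float("nan")
    table = ((0, 0), (0, 0))
    if len(rows) > 0:
        tab = np.array(
            [
                [int((scrambled & nested).sum()), int((scrambled & ~nested).sum())],
                [int((~scrambled & nested).sum()), int((~scrambled & ~nested).sum())],
            ]
        )
        table = tuple(tuple(int(x) for x in row) for row in tab)
        if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
            res = stats.chi2_contingency(tab, correction=False)
            chi2, chi2_p = float(res.statistic), float(res.pvalue)
        else:
            notes.append("chi-square undefined: a margin of the 2x2 table is empty")
    else:
        notes.append("no reports")

    classes = sorted({r.idi for r in rows if r.idi >= 1})
    class_rows = []
    for c in classes:
        members = [r for r in rows if r.idi == c]
        n_scr = sum(r.scrambled for r in members)
        class_rows.append(
            {
                "idi": c,
                "n_contigs": len(members),
                "n_scrambled": n_scr,
                "scrambled_proportion": n_scr / len(members),
            }
        )
    class_table = pd.DataFrame(
        class_rows, columns=["idi", "n_contigs", "n_scrambled", "scrambled_proportion"]
    )
    rho = rho_p = float("nan")
    if len(classes) >= 2:
        props = class_table["scrambled_proportion"].to_numpy()
        if np.allclose(props, props[0]):
            notes.append("spearman undefined: scrambled proportion constant across classes")
        else:
            rho, rho_p = spearman_by_class(class_table["idi"].to_numpy(), props)
    else:
        notes.append("spearman undefined: fewer than 2 IDI classes")

    return EnrichmentStats(
        chi2=chi2,
        chi2_p=chi2_p,
        contingency=table,
        rho=rho,
        rho_p=rho_p,
        class_table=class_table,
        warnings=tuple(notes),
    )


def _summary_row(group: str, level, members: list[NestingReport]) -> dict:
    n = len(members)
    n_scr = sum(r.scrambled for r in members)
    return {
        "group": group,
        "level": level,
        "n_contigs": n,
        "n_scrambled": n_scr,
        "pct_scrambled": round(100.0 * n_scr / n, 1) if n else 0.0,
        "avg_mds_count": round(sum(r.mds_count for r in members) / n, 1) if n else 0.0,
    }


def summarize(reports: Iterable[NestingReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort tabulations: per-IDI/EI-class counts and the
    embedding/interleaving breakdown."""
    rows = [r for r in reports if not r.excluded]
    cols = ["group", "level", "n_contigs", "n_scrambled", "pct_scrambled", "avg_mds_count"]

    t1_rows = [_summary_row("processed", "all", rows)]
    for group, key in (("IDI", lambda r: r.idi), ("EI", lambda r: r.ei)):
        for level in sorted({key(r) for r in rows if key(r) >= 1}):
            t1_rows.append(_summary_row(group, level, [r for r in rows if key(r) == level]))
    table1 = pd.DataFrame(t1_rows, columns=cols)

    t2_rows = [
        _summary_row("processed", "all", rows),
        _summary_row(
            "with_mds_in_ies_of_other",
            "any",
            [r for r in rows if r.relationship_class != "none"],
        ),
    ]
    for klass in ("embedded_only", "interleaved_only", "both"):
        t2_rows.append(
            _summary_row(klass, "-", [r for r in rows if r.relationship_class == klass])
        )
    table2 = pd.DataFrame(t2_rows, columns=cols)
    return table1, table2
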