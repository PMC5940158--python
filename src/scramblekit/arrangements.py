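"""Signed MDS arrangement maps and germline IES intervals.

A ciliate macronuclear (MAC) nanochromosome is stitched together from
*macronuclear destined sequences* (MDSs) that lie on a micronuclear
(MIC) chromosome, possibly out of order and/or inverted.  The spans
eliminated between two MDSs of the same MAC contig are *internally
eliminated sequences* (IESs).  This module holds the domain types for
that architecture:

* :class:`MdsRecord` — one germline MDS occurrence (MIC location plus
  MAC identity, index and orientation);
* :class:`ArrangementMap` — the signed sequence of MDS indices of one
  MAC contig read in MIC-coordinate order, written in the compact
  notation ``"M2 M3 -M8 -M7 -M1 -M4 M5 M6"`` (a leading ``-`` marks an
  inverted MDS);
* :class:`IesInterval` — the eliminated span between two MDSs of the
  same MAC contig that are adjacent in MIC order.

Coordinates are 1-based inclusive throughout, matching GFF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

FORWARD = "+"
INVERTED = "-"

_TOKEN_RE = re.compile(r"^(-?)M([0-9]+)$")


class ArrangementError(ValueError):
    """Malformed or inconsistent arrangement input."""


@dataclass(frozen=True)
class MdsRecord:
    """One MDS occurrence on a MIC contig.

    ``mds_index`` is the position of the segment in the final MAC
    product (1-based); ``orientation`` is ``"+"`` when the MIC copy
    reads in the same direction as the MAC product and ``"-"`` when it
    is inverted.
    """

    mic_contig_id: str
    mac_contig_id: str
    mds_index: int
    mic_start: int
    mic_end: int
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.mds_index < 1:
            raise ArrangementError(f"mds_index must be >= 1, got {self.mds_index}")
        if self.mic_start > self.mic_end:
            raise ArrangementError(
                f"mic_start > mic_end ({self.mic_start} > {self.mic_end}) "
                f"for {self.mac_contig_id} MDS {self.mds_index}"
            )
        if self.orientation not in (FORWARD, INVERTED):
            raise ArrangementError(f"orientation must be '+' or '-', got {self.orientation!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.mic_start, self.mic_end)


@dataclass(frozen=True)
class ArrangementMap:
    """Signed MDS sequence of one MAC contig in MIC-coordinate order.

    ``entries`` is an ordered tuple of ``(mds_index, orientation)``
    pairs.  A map is *complete* when the indices are exactly
    ``1..k`` for ``k = max(index)``; incomplete maps (e.g. a MAC contig
    whose MDSs are split over several MIC contigs) are flagged, not
    rejected.
    """

    mac_contig_id: str
    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for idx, orient in self.entries:
            if idx < 1:
                raise ArrangementError(f"MDS index must be >= 1, got {idx}")
            if orient not in (FORWARD, INVERTED):
                raise ArrangementError(f"bad orientation {orient!r}")
            if idx in seen:
                raise ArrangementError(
                    f"duplicate MDS index {idx} in map for {self.mac_contig_id!r}"
                )
            seen.add(idx)

    @property
    def k(self) -> int:
        """Total MDS count implied by the largest index."""
        return max((i for i, _ in self.entries), default=0)

    @property
    def complete(self) -> bool:
        return sorted(i for i, _ in self.entries) == list(range(1, self.k + 1))

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __str__(self) -> str:
        return format_arrangement(self)


@dataclass(frozen=True)
class IesInterval:
    """Eliminated span between two MIC-adjacent MDSs of one MAC contig.

    ``conventional`` is true when the flanking MDSs are consecutive in
    MAC order and co-oriented (a nonscrambled junction).
    """

    mac_contig_id: str
    mic_contig_id: str
    start: int
    end: int
    left_mds: int
    right_mds: int
    conventional: bool

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def parse_arrangement(text: str, mac_contig_id: str = "") -> ArrangementMap:
    """Parse whitespace-separated ``M<i>`` / ``-M<i>`` tokens.

    >>> parse_arrangement("M1 -M2 -M3").entries
    ((1, '+'), (2, '-'), (3, '-'))
    """
    entries: list[tuple[int, str]] = []
    for token in text.split():
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ArrangementError(f"malformed arrangement token {token!r}")
        sign = INVERTED if m.group(1) else FORWARD
        idx = int(m.group(2))
        if idx < 1:
            raise ArrangementError(f"MDS index must be positive in token {token!r}")
        entries.append((idx, sign))
    return ArrangementMap(mac_contig_id=mac_contig_id, entries=tuple(entries))


def format_arrangement(arrangement: ArrangementMap) -> str:
    """Inverse of :func:`parse_arrangement` (normalised spacing)."""
    return " ".join(
        ("-" if orient == INVERTED else "") + f"M{idx}" for idx, orient in arrangement.entries
    )


def is_scrambled(arrangement: ArrangementMap) -> bool:
    """True unless the map preserves MAC order and relative orientation.

    The two order-preserving cases are the identity ``M1..Mk`` (all
    forward) and the whole-locus inversion ``-Mk..-M1`` (all inverted);
    everything else requires descrambling.
    """
    if not arrangement.complete:
        raise ArrangementError(
            f"is_scrambled needs a complete map; {arrangement.mac_contig_id!r} "
            f"has indices {sorted(arrangement.indices)}"
        )
    k = arrangement.k
    identity = tuple((i, FORWARD) for i in range(1, k + 1))
    inverted = tuple((i, INVERTED) for i in range(k, 0, -1))
    return arrangement.entries not in (identity, inverted)


def arrangement_from_records(records: Sequence[MdsRecord]) -> ArrangementMap:
    """Build the MIC-order arrangement map of one (MIC, MAC) record group."""
    if not records:
        raise ArrangementError("no records given")
    mac_ids = {r.mac_contig_id for r in records}
    mic_ids = {r.mic_contig_id for r in records}
    if len(mac_ids) != 1 or len(mic_ids) != 1:
        raise ArrangementError(
            f"records span several contigs (MAC {sorted(mac_ids)}, MIC {sorted(mic_ids)})"
        )
    ordered = sorted(records, key=lambda r: (r.mic_start, r.mic_end))
    return ArrangementMap(
        mac_contig_id=records[0].mac_contig_id,
        entries=tuple((r.mds_index, r.orientation) for r in ordered),
    )


def ies_intervals(records: Sequence[MdsRecord]) -> list[IesInterval]:
    """IES intervals between MIC-adjacent MDSs of one MAC contig.

    Records must belong to one (MIC contig, MAC contig) pair and be
    non-overlapping; each adjacent pair in MIC-coordinate order yields
    one interval.  Overlapping or abutting records are rejected — no
    eliminated span exists between them.
    """
    if len(records) < 2:
        raise ArrangementError("need at least two MDS records to form an IES")
    mac_ids = {r.mac_contig_id for r in records}
    mic_ids = {r.mic_contig_id for r in records}
    if len(mac_ids) != 1 or len(mic_ids) != 1:
        raise ArrangementError("IES intervals are defined within one (MIC, MAC) contig pair")
    ordered = sorted(records, key=lambda r: (r.mic_start, r.mic_end))
    out: list[IesInterval] = []
    for left, right in zip(ordered, ordered[1:]):
        if right.mic_start <= left.mic_end + 1:
            raise ArrangementError(
                f"MDS records of {left.mac_contig_id!r} overlap or abut on "
                f"{left.mic_contig_id!r} at {left.interval} / {right.interval}"
            )
        conventional = (
            left.orientation == right.orientation
            and (
                (left.orientation == FORWARD and right.mds_index == left.mds_index + 1)
                or (left.orientation == INVERTED and left.mds_index == right.mds_index + 1)
            )
        )
        out.append(
            IesInterval(
                mac_contig_id=left.mac_contig_id,
                mic_contig_id=left.mic_contig_id,
                start=left.mic_end + 1,
                end=right.mic_start - 1,
                left_mds=left.mds_index,
                right_mds=right.mds_index,
                conventional=conventional,
            )
        )
    return out


def read_arrangements(path) -> list[ArrangementMap]:
    """Read one-map-per-line files of the form ``<mac_id>\\t<notation>``."""
    maps: list[ArrangementMap] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                mac_id, notation = line.split("\t", 1)
            except ValueError as exc:
                raise ArrangementError(f"{path}:{lineno}: expected '<mac_id>\\t<notation>'") from exc
            maps.append(parse_arrangement(notation, mac_contig_id=mac_id))
    return maps


def write_arrangements(maps: Iterable[ArrangementMap], path) -> None:
    with open(path, "w") as fh:
        for m in maps:
            fh.write(f"{m.mac_contig_id}\t{format_arrangement(m)}\n")
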