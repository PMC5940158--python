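"""Reading MDS annotation tables (GFF dialect) and writing reports.

Processed germline/somatic annotations arrive as 9-column GFF whose MDS
features carry the MAC contig identity and MDS index in the attribute
column.  The attribute schema varies between exports, so the mapping is
configurable (:class:`GffDialect`, optionally loaded from YAML).
Per-line parsing is delegated to :mod:`gffutils`; malformed lines are
skipped with a logged reason rather than aborting the load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml
from gffutils.feature import feature_from_line

from .arrangements import FORWARD, INVERTED, ArrangementError, MdsRecord
from .nesting import NestingReport

logger = logging.getLogger("scramblekit")


@dataclass(frozen=True)
class GffDialect:
    """Attribute-key mapping of an MDS annotation dialect.

    ``orientation_attr`` is consulted first when set; otherwise the
    strand column decides (``-`` means inverted, anything else forward).
    """

    feature_types: tuple[str, ...] = ("MDS",)
    mac_attr: str = "mac_contig"
    index_attr: str = "mds_index"
    orientation_attr: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "GffDialect":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        if "feature_types" in data:
            kwargs["feature_types"] = tuple(data["feature_types"])
        for key in ("mac_attr", "index_attr", "orientation_attr"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


DEFAULT_DIALECT = GffDialect()


@dataclass
class AnnotationFile:
    records: list[MdsRecord]
    source_dialect: str = "default"
    skipped_lines: list[tuple[int, str]] = field(default_factory=list)


def read_gff(path, dialect: GffDialect | None = None) -> AnnotationFile:
    """Load MDS records from a GFF file.

    Non-MDS feature types are ignored silently; MDS lines missing a
    mandatory attribute or with malformed coordinates are skipped and
    the (line number, reason) pair recorded in ``skipped_lines``.
    """
    dialect = dialect or DEFAULT_DIALECT
    records: list[MdsRecord] = []
    skipped: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed line
                skipped.append((lineno, f"unparseable line: {exc}"))
                logger.warning("%s:%d skipped: %s", path, lineno, exc)
                continue
            if feat.featuretype not in dialect.feature_types:
                continue
            try:
                mac = feat.attributes[dialect.mac_attr][0]
                idx = int(feat.attributes[dialect.index_attr][0])
            except (KeyError, IndexError, ValueError) as exc:
                skipped.append((lineno, f"missing/bad attribute: {exc}"))
                logger.warning("%s:%d skipped: %s", path, lineno, exc)
                continue
            orientation = None
            if dialect.orientation_attr and dialect.orientation_attr in feat.attributes:
                val = feat.attributes[dialect.orientation_attr][0].lower()
                orientation = INVERTED if val in ("-", "inverted", "reverse") else FORWARD
            if orientation is None:
                orientation = INVERTED if feat.strand == "-" else FORWARD
            try:
                records.append(
                    MdsRecord(
                        mic_contig_id=feat.seqid,
                        mac_contig_id=mac,
                        mds_index=idx,
                        mic_start=int(feat.start),
                        mic_end=int(feat.end),
                        orientation=orientation,
                    )
                )
            except (ArrangementError, TypeError, ValueError) as exc:
                skipped.append((lineno, f"bad coordinates: {exc}"))
                logger.warning("%s:%d skipped: %s", path, lineno, exc)
    # deterministic analysis order
    records.sort(key=lambda r: (r.mic_contig_id, r.mic_start, r.mic_end, r.mac_contig_id))
    return AnnotationFile(records=records, source_dialect=repr(dialect), skipped_lines=skipped)


def write_gff(records: Sequence[MdsRecord], path, source: str = "scramblekit") -> None:
    """Write records in the default dialect (stable order, byte-stable)."""
    ordered = sorted(records, key=lambda r: (r.mic_contig_id, r.mic_start, r.mic_end, r.mac_contig_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in ordered:
            attrs = (
                f"ID=mds-{r.mac_contig_id}-{r.mds_index};"
                f"mac_contig={r.mac_contig_id};mds_index={r.mds_index}"
            )
            fh.write(
                "\t".join(
                    [
                        r.mic_contig_id,
                        source,
                        "MDS",
                        str(r.mic_start),
                        str(r.mic_end),
                        ".",
                        r.orientation,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


REPORT_COLUMNS = [
    "mac_contig_id",
    "idi",
    "ei",
    "relationship_class",
    "scrambled",
    "mds_count",
    "excluded",
    "complete",
]


def reports_to_frame(reports: Iterable[NestingReport]) -> pd.DataFrame:
    rows = sorted(reports, key=lambda r: r.mac_contig_id)
    return pd.DataFrame(
        [
            {
                "mac_contig_id": r.mac_contig_id,
                "idi": r.idi,
                "ei": r.ei,
                "relationship_class": r.relationship_class,
                "scrambled": r.scrambled,
                "mds_count": r.mds_count,
                "excluded": r.excluded,
                "complete": r.complete,
            }
            for r in rows
        ],
        columns=REPORT_COLUMNS,
    )


def read_reports(path) -> list[NestingReport]:
    df = pd.read_csv(path, sep="\t")
    return [
        NestingReport(
            mac_contig_id=str(row.mac_contig_id),
            idi=int(row.idi),
            ei=int(row.ei),
            relationship_class=str(row.relationship_class),
            scrambled=bool(row.scrambled),
            mds_count=int(row.mds_count),
            excluded=bool(row.excluded),
            complete=bool(row.complete),
        )
        for row in df.itertuples()
    ]


def trace_to_frame(mac_id: str, trace) -> pd.DataFrame:
    """TSV-friendly view of a reduction trace (step, kind, u, before, after)."""
    from .dow import format_word

    rows = [
        {
            "mac_contig_id": mac_id,
            "step": i + 1,
            "kind": step.hit.kind,
            "u": format_word(step.hit.u) if step.hit.u else "ε",
            "before": format_word(step.word_before),
            "after": format_word(step.word_after),
        }
        for i, step in enumerate(trace.steps)
    ]
    return pd.DataFrame(
        rows, columns=["mac_contig_id", "step", "kind", "u", "before", "after"]
    )


def write_reports(reports, traces=None, path_prefix="scramblekit") -> list[str]:
    """Write nesting reports (and optional reduction traces) as TSV.

    Returns the list of files written.  ``traces`` maps MAC contig id to
    a :class:`~scramblekit.dow.ReductionTrace`.
    """
    written: list[str] = []
    report_path = f"{path_prefix}.nesting.tsv"
    reports_to_frame(reports).to_csv(report_path, sep="\t", index=False)
    written.append(report_path)
    if traces:
        frames = [trace_to_frame(mac, tr) for mac, tr in sorted(traces.items())]
        trace_path = f"{path_prefix}.traces.tsv"
        pd.concat(frames, ignore_index=True).to_csv(trace_path, sep="\t", index=False)
        written.append(trace_path)
    return written
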