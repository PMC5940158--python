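import math
import warnings

import numpy as np
import pytest

from scramblekit.arrangements import MdsRecord
from scramblekit.nesting import (
    analyze,
    classify_pair,
    ei_of_contig,
    enrichment_stats,
    idi_of_contig,
    relationship_class,
    spearman_by_class,
    summarize,
    terminal_overlap_filter,
)
from scramblekit.simulate import LocusSpec, SimConfig, generate, realize


class TestIndices:
    def test_fig1a_layout(self, fig1a_records):
        assert [idi_of_contig(m, fig1a_records) for m in ("red", "blue", "orange")] == [2, 1, 0]
        assert [ei_of_contig(m, fig1a_records) for m in ("red", "blue", "orange")] == [0, 1, 2]

    def test_three_layer_contig_example(self, fig2_records):
        names = ("Contig6331.0", "Contig9583.0", "Contig6683.0")
        assert [idi_of_contig(m, fig2_records) for m in names] == [2, 1, 0]
        assert [ei_of_contig(m, fig2_records) for m in names] == [0, 1, 2]

    def test_isolated_contig_scores_zero(self):
        records = realize("mic", [LocusSpec("solo", "M1 M2 M3")])
        assert idi_of_contig("solo", records) == 0
        assert ei_of_contig("solo", records) == 0

    @pytest.mark.parametrize("depth", [1, 2, 4])
    def test_doll_chain_depth(self, doll_chain_records, depth):
        records = doll_chain_records(depth)
        assert idi_of_contig("doll0", records) == depth
        assert ei_of_contig(f"doll{depth}", records) == depth
        # intermediate layers interpolate
        for layer in range(depth + 1):
            assert idi_of_contig(f"doll{layer}", records) == depth - layer
            assert ei_of_contig(f"doll{layer}", records) == layer

    def test_idi_terminates_on_mutual_interleave(self, interleaved_records):
        assert idi_of_contig("A", interleaved_records) == 1
        assert idi_of_contig("B", interleaved_records) == 1

    def test_removing_a_contig_never_increases_ei(self):
        cfg = SimConfig(
            seed=5,
            n_mic_contigs=1,
            loci_per_contig=4,
            nesting_depth_distribution={0: 0.3, 1: 0.4, 2: 0.3},
            fraction_interleaved=0.3,
        )
        annotation, _ = generate(cfg)
        macs = sorted({r.mac_contig_id for r in annotation.records})
        base = {m: ei_of_contig(m, annotation.records) for m in macs}
        for removed in macs:
            rest = [r for r in annotation.records if r.mac_contig_id != removed]
            for m in macs:
                if m != removed:
                    assert ei_of_contig(m, rest) <= base[m]


class TestClassification:
    def test_fig1a_pairs(self, fig1a_records):
        assert classify_pair("blue", "red", fig1a_records) == "a_embedded_in_b"
        assert classify_pair("orange", "blue", fig1a_records) == "a_embedded_in_b"
        assert classify_pair("orange", "red", fig1a_records) == "a_embedded_in_b"
        assert classify_pair("red", "blue", fig1a_records) == "b_embedded_in_a"

    def test_interleaved_pair(self, interleaved_records):
        assert classify_pair("A", "B", interleaved_records) == "interleaved"
        assert relationship_class("A", interleaved_records) == "interleaved_only"

    def test_disjoint_loci_are_unrelated(self):
        records = realize("mic", [LocusSpec("a", "M1 M2"), LocusSpec("b", "M1 M2")])
        assert classify_pair("a", "b", records) == "none"
        assert relationship_class("a", records) == "none"

    def test_fig1a_relationship_classes(self, fig1a_records):
        assert relationship_class("orange", fig1a_records) == "embedded_only"
        assert relationship_class("blue", fig1a_records) == "embedded_only"
        assert relationship_class("red", fig1a_records) == "none"

    def test_embedded_and_interleaved_partner_gives_both(self):
        # A's IES hosts T1 B1 T2 B2: T embedded in A, interleaved with B
        rows = [
            MdsRecord("mic", "A", 1, 1, 100, "+"),
            MdsRecord("mic", "T", 1, 201, 300, "+"),
            MdsRecord("mic", "B", 1, 401, 500, "+"),
            MdsRecord("mic", "T", 2, 601, 700, "+"),
            MdsRecord("mic", "B", 2, 801, 900, "+"),
            MdsRecord("mic", "A", 2, 1001, 1100, "+"),
        ]
        assert classify_pair("T", "A", rows) == "a_embedded_in_b"
        assert classify_pair("T", "B", rows) == "interleaved"
        assert relationship_class("T", rows) == "both"


class TestTerminalOverlapFilter:
    @staticmethod
    def _pair(overlap: int) -> list[MdsRecord]:
        return [
            MdsRecord("mic", "a", 1, 1, 200, "+"),
            MdsRecord("mic", "b", 1, 201 - overlap, 400, "+"),
        ]

    def test_large_overlap_excludes_both(self):
        assert terminal_overlap_filter(self._pair(100)) == {"a", "b"}

    def test_abutting_and_pointer_scale_overlap_kept(self):
        assert terminal_overlap_filter(self._pair(0)) == set()
        assert terminal_overlap_filter(self._pair(5)) == set()

    def test_threshold_is_configurable(self):
        assert terminal_overlap_filter(self._pair(5), overlap_bp=3) == {"a", "b"}

    def test_excluded_contigs_do_not_shape_metrics(self, fig1a_records):
        # an overlapping intruder knocks out blue but not the others
        intruder_start = next(
            r.mic_start for r in fig1a_records if r.mac_contig_id == "blue"
        )
        rows = fig1a_records + [
            MdsRecord("mic_fig1a", "intruder", 1, intruder_start, intruder_start + 99, "+")
        ]
        reports = {r.mac_contig_id: r for r in analyze(rows)}
        assert reports["blue"].excluded and reports["intruder"].excluded
        # orange is still nested in red's IES, but the blue layer is gone
        assert reports["orange"].ei == 1
        assert reports["red"].idi == 1


class TestAnalyze:
    def test_fig1a_reports(self, fig1a_records):
        reports = {r.mac_contig_id: r for r in analyze(fig1a_records)}
        assert (reports["red"].idi, reports["blue"].idi, reports["orange"].idi) == (2, 1, 0)
        assert (reports["red"].ei, reports["blue"].ei, reports["orange"].ei) == (0, 1, 2)
        assert reports["red"].scrambled and reports["blue"].scrambled
        assert not reports["orange"].scrambled
        assert reports["orange"].mds_count == 3

    def test_split_contig_flagged_incomplete(self):
        rows = [
            MdsRecord("micA", "split", 1, 1, 100, "+"),
            MdsRecord("micB", "split", 2, 1, 100, "+"),
        ]
        with pytest.warns(UserWarning, match="incomplete"):
            reports = analyze(rows)
        assert len(reports) == 1 and not reports[0].complete


class TestStatistics:
    def test_rho_of_printed_idi_proportions_is_one(self):
        rho, _ = spearman_by_class([1, 2, 3, 4], [62.3, 74.4, 90.9, 100.0])
        assert rho == 1.0

    def test_planted_enrichment_detected(self):
        """Cohorts where scrambling concentrates in nested loci must give
        a small chi-square p-value in nearly every simulation."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            from scramblekit.nesting import NestingReport

            reports = []
            for i in range(400):
                nested = rng.random() < 0.3
                p_scr = 0.6 if nested else 0.1
                reports.append(
                    NestingReport(
                        f"c{i}", int(nested), 0, "none", bool(rng.random() < p_scr), 5
                    )
                )
            stats = enrichment_stats(reports)
            if stats.chi2_p < 0.05:
                hits += 1
        assert hits >= 0.95 * n_sim

    def test_degenerate_classes_flagged_not_zeroed(self):
        from scramblekit.nesting import NestingReport

        reports = [NestingReport(f"c{i}", 0, 0, "none", i % 2 == 0, 5) for i in range(10)]
        stats = enrichment_stats(reports)
        assert math.isnan(stats.rho)
        assert any("fewer than 2 IDI classes" in w for w in stats.warnings)


class TestSummaries:
    def test_fig1a_idi_classes(self, fig1a_records):
        table1, table2 = summarize(analyze(fig1a_records))
        idi_rows = table1[table1.group == "IDI"].set_index("level")
        assert idi_rows.loc[1, "n_contigs"] == 1
        assert idi_rows.loc[2, "n_contigs"] == 1
        emb = table2[table2.group == "embedded_only"].iloc[0]
        assert emb.n_contigs == 2

    def test_empty_cohort_gives_zero_table(self):
        table1, table2 = summarize([])
        assert table1.iloc[0].n_contigs == 0
        assert (table2.n_contigs == 0).all()

    def test_generator_cohort_counts_recovered_exactly(self):
        cfg = SimConfig(
            seed=11,
            n_mic_contigs=2,
            loci_per_contig=5,
            nesting_depth_distribution={0: 0.5, 1: 0.3, 2: 0.2},
            fraction_interleaved=0.25,
        )
        annotation, truth = generate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table1, _ = summarize(analyze(annotation.records))
        truth_frame = truth.to_frame()
        for level in sorted(set(truth_frame.idi)):
            expected = int((truth_frame.idi == level).sum())
            if level == 0:
                continue
            row = table1[(table1.group == "IDI") & (table1.level == level)]
            assert int(row.n_contigs.iloc[0]) == expected
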