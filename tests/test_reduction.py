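import random

import pytest

import oracles
from scramblekit.dow import (
    Dow,
    contains_tangled_cord,
    find_patterns,
    format_word,
    parse_word,
    reduce_word,
    remove_hit,
    scrambled_pointer_count,
    tangled_cord,
)


class TestFindPatterns:
    def test_repeat_and_return_in_blue_locus_word(self):
        hits = find_patterns(parse_word("12341243"))
        by_kind = {(h.kind, h.u, h.positions) for h in hits}
        assert ("repeat", (1, 2), (0, 4)) in by_kind
        assert ("return", (3, 4), (2, 6)) in by_kind
        assert all(h.maximal for h in hits)

    def test_return_word_3443(self):
        hits = find_patterns(parse_word("3443"))
        assert [(h.kind, h.u, h.positions) for h in hits] == [("return", (3, 4), (0, 2))]

    def test_whole_word_patterns_are_single_maximal_hits(self):
        assert [(h.kind, h.u) for h in find_patterns(parse_word("12341234"))] == [
            ("repeat", (1, 2, 3, 4))
        ]
        assert [(h.kind, h.u) for h in find_patterns(parse_word("123456654321"))] == [
            ("return", (1, 2, 3, 4, 5, 6))
        ]

    @pytest.mark.parametrize("word", ["121323", "4,10,11,8,12,11,9,8,4,9,10,12"])
    def test_irreducible_words_have_no_hits(self, word):
        w = parse_word(word)
        assert find_patterns(w) == []
        # cross-check with the enumeration oracle: every factor pair overlaps
        assert oracles.factor_pair_hits(tuple(w)) == []

    def test_trivial_pairs_reported_separately(self):
        w = parse_word("1122")
        assert find_patterns(w) == []
        trivial = find_patterns(w, include_trivial=True)
        assert [(h.kind, h.u, h.positions) for h in trivial] == [
            ("trivial_pair", (1,), (0, 1)),
            ("trivial_pair", (2,), (2, 3)),
        ]


class TestReduce:
    def test_blue_locus_reduces_in_two_steps(self):
        trace = reduce_word(parse_word("12341243"), "greedy")
        assert trace.fully_reduced
        assert [(s.hit.kind, s.hit.u) for s in trace.steps] == [
            ("repeat", (1, 2)),
            ("return", (3, 4)),
        ]

    def test_nested_return_inside_repeat(self):
        """5665 sits inside 3434; removing both leaves 1212, which is
        itself a repeat word, so the word reduces to ε."""
        trace = reduce_word(parse_word("121342566534"), "greedy")
        assert [format_word(s.word_after) for s in trace.steps] == ["12134234", "1212", "ε"]
        assert {tuple(s.hit.u) for s in trace.steps[:2]} == {(5, 6), (3, 4)}
        assert trace.fully_reduced

    def test_irreducible_residual_reports_six_pointers(self):
        w = parse_word("4,10,11,8,12,11,9,8,4,9,10,12")
        trace = reduce_word(w, "exhaustive")
        assert trace.steps == () and trace.residual == w and not trace.fully_reduced
        assert scrambled_pointer_count(trace.residual) == 6

    def test_stranded_trivial_pairs_are_removed(self):
        trace = reduce_word(parse_word("1122"), "greedy")
        assert trace.fully_reduced
        assert all(s.hit.kind == "trivial_pair" for s in trace.steps)

    def test_greedy_can_miss_orders_needing_non_maximal_hits(self):
        """Known counterexample: the only maximal hit of 535426131426 is
        repeat 426, a dead end; ε is reachable only by removing the
        non-maximal repeat 42 first.  Greedy is sound but incomplete;
        exhaustive finds the order."""
        w = parse_word("535426131426")
        greedy = reduce_word(w, "greedy")
        exhaustive = reduce_word(w, "exhaustive")
        assert not greedy.fully_reduced
        assert exhaustive.fully_reduced
        assert oracles.reducible(w)

    def test_symbol_budget_falls_back_to_greedy(self):
        w = Dow([p for i in range(1, 42) for p in (i, i)])
        with pytest.warns(UserWarning, match="falling back to greedy"):
            trace = reduce_word(w, "exhaustive", max_symbols=40)
        assert trace.strategy == "greedy" and trace.fully_reduced

    @pytest.mark.parametrize("strategy", ["greedy", "exhaustive"])
    def test_every_intermediate_word_is_a_valid_dow(self, strategy):
        rng = random.Random(4242)
        for _ in range(50):
            w = Dow(oracles.random_dow(rng))
            trace = reduce_word(w, strategy)
            for step in trace.steps:
                Dow(step.word_before)  # raises DowError if invalid
                Dow(step.word_after)
                assert step.word_after == remove_hit(step.word_before, step.hit)
            expected_last = trace.steps[-1].word_after if trace.steps else w
            assert trace.residual == expected_last

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = random.Random(77)
        for _ in range(300):
            w = Dow(oracles.random_dow(rng))
            assert reduce_word(w, "exhaustive").fully_reduced == oracles.reducible(w)

    def test_greedy_is_sound(self):
        """Greedy never claims reducibility that the oracle refutes."""
        rng = random.Random(78)
        for _ in range(300):
            w = Dow(oracles.random_dow(rng))
            if reduce_word(w, "greedy").fully_reduced:
                assert oracles.reducible(w)


class TestTangledCord:
    def test_recursion_reproduces_printed_family(self):
        assert format_word(tangled_cord(1)) == "1212"
        assert format_word(tangled_cord(2)) == "121323"
        assert format_word(tangled_cord(3)) == "12132434"

    @pytest.mark.parametrize("n", range(1, 8))
    def test_shape(self, n):
        tc = tangled_cord(n)
        assert len(tc) == 2 * n + 2
        assert scrambled_pointer_count(tc) == n + 1

    def test_index_below_one_rejected(self):
        with pytest.raises(ValueError):
            tangled_cord(0)

    def test_tc1_reducible_but_higher_cords_irreducible(self):
        assert reduce_word(tangled_cord(1), "exhaustive").fully_reduced
        for n in range(2, 7):
            trace = reduce_word(tangled_cord(n), "exhaustive")
            assert trace.steps == () and not trace.fully_reduced

    @pytest.mark.parametrize(
        "word,expected",
        [
            ("12413234", 2),  # delete label 4 -> 121323
            ("12132434", 3),  # is TC(3) itself
            ("1122", 0),
            ("1212", 0),  # TC(1) below default min_n
        ],
    )
    def test_contains_tangled_cord(self, word, expected):
        assert contains_tangled_cord(parse_word(word)) == expected

    def test_min_n_one_accepts_repeat_words(self):
        assert contains_tangled_cord(parse_word("1212"), min_n=1) == 1

    def test_subset_restriction_only_not_scattered(self):
        """The cord must appear as the full restriction to a label
        subset; TC(n) contains every smaller cord this way."""
        assert contains_tangled_cord(tangled_cord(5)) == 5
        w = parse_word("11223344")
        assert contains_tangled_cord(w) == 0
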