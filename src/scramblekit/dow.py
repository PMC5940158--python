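"""Pointer double-occurrence words and the repeat/return reduction algebra.

MDSs recombine at short repeats ("pointers"): pointer *i* is shared by
the end of MDS *i* and the start of MDS *i+1*.  Listing pointer labels
in MIC order gives a *double occurrence word* (DOW) — every label
occurs exactly twice.  Scrambled-locus complexity is characterised by
iteratively deleting two kinds of factor patterns:

* a *repeat word* — two disjoint factor occurrences ``u ... u``;
* a *return word* — disjoint occurrences ``u ... reverse(u)``.

Adjacent identical pairs (``i i``) mark conventional, nonscrambled IES
junctions and are removed through a separate channel
(:func:`strip_trivial_pairs`).  Words reducing to the empty word are
explained by layered odd-even patterns; irreducible residuals mark
atypical architectures such as the *tangled cord* family
``1212, 121323, 12132434, ...``.

The reduction order is a descriptive device: it need not reflect the
developmental descrambling pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Literal, Sequence

__all__ = [
    "Dow",
    "DowError",
    "PatternHit",
    "ReductionStep",
    "ReductionTrace",
    "parse_word",
    "format_word",
    "pointer_word",
    "strip_trivial_pairs",
    "renumber_by_rank",
    "find_patterns",
    "remove_hit",
    "reduce_word",
    "scrambled_pointer_count",
    "tangled_cord",
    "contains_tangled_cord",
    "canonical_form",
    "dow_isomorphic",
]


class DowError(ValueError):
    """Input is not a valid double occurrence word."""


class Dow(tuple):
    """A double occurrence word: each label occurs exactly twice.

    Thin immutable sequence of positive integer labels; the empty word
    is valid.  ``str()`` gives the compact serialisation: concatenated
    digits when every label is a single digit (``"12413234"``),
    comma-separated otherwise (``"4,10,11,8,12,11,9,8,4,9,10,12"``).
    """

    def __new__(cls, symbols: Iterable[int] = ()) -> "Dow":
        syms = tuple(int(s) for s in symbols)
        counts: dict[int, int] = {}
        for s in syms:
            if s < 1:
                raise DowError(f"pointer labels must be positive, got {s}")
            counts[s] = counts.get(s, 0) + 1
        bad = {s: c for s, c in counts.items() if c != 2}
        if bad:
            raise DowError(f"labels must occur exactly twice; offending counts: {bad}")
        return super().__new__(cls, syms)

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(sorted(set(self)))

    def __str__(self) -> str:
        return format_word(self)

    def __repr__(self) -> str:
        return f"Dow({format_word(self)!r})"


EMPTY = Dow()


def format_word(w: Sequence[int]) -> str:
    """Serialise a word: digit string if all labels <= 9, else comma-separated."""
    if not w:
        return "ε"
    if max(w) <= 9:
        return "".join(str(s) for s in w)
    return ",".join(str(s) for s in w)


def parse_word(text: str) -> Dow:
    """Parse either serialised dialect (``"1212"`` or ``"4,10,8,..."``).

    A digit string may not contain ``0``; labels >= 10 require the
    comma-separated form.
    """
    text = text.strip()
    if text in ("", "ε", "e"):
        return EMPTY
    if "," in text:
        return Dow(int(tok) for tok in text.split(","))
    if not text.isdigit():
        raise DowError(f"cannot parse word {text!r}")
    if "0" in text:
        raise DowError(
            f"digit-string {text!r} contains '0'; labels >= 10 must be comma-separated"
        )
    return Dow(int(ch) for ch in text)


# ---------------------------------------------------------------------------
# construction from arrangements
# ---------------------------------------------------------------------------

def pointer_word(arrangement) -> Dow:
    """Pointer DOW of a complete arrangement map.

    Scanning MDSs in MIC order, a forward MDS with MAC index *i* emits
    pointers ``(i-1, i)`` and an inverted one ``(i, i-1)``; the terminal
    indices 1 and *k* emit their single pointer only.  The result is a
    DOW over labels ``1..k-1``.

    >>> from scramblekit.arrangements import parse_arrangement
    >>> str(pointer_word(parse_arrangement("M1 M2 M3")))
    '1122'
    """
    from .arrangements import INVERTED, ArrangementError

    if not arrangement.complete:
        raise ArrangementError(
            f"pointer_word needs a complete map; got indices {sorted(arrangement.indices)}"
        )
    k = arrangement.k
    if k < 2:
        warnings.warn("arrangement has fewer than 2 MDSs; pointer word is empty", stacklevel=2)
        return EMPTY
    out: list[int] = []
    for idx, orient in arrangement.entries:
        pair = (idx, idx - 1) if orient == INVERTED else (idx - 1, idx)
        out.extend(p for p in pair if 1 <= p <= k - 1)
    return Dow(out)


# ---------------------------------------------------------------------------
# elementary word operations
# ---------------------------------------------------------------------------

def strip_trivial_pairs(w: Sequence[int]) -> tuple[Dow, int]:
    """Cascading deletion of adjacent identical pairs.

    Deletions may create new adjacent pairs, which are deleted too
    (stack scan = leftmost-first cascade).  Returns the residual word
    and the number of pairs removed.
    """
    stack: list[int] = []
    removed = 0
    for s in w:
        if stack and stack[-1] == s:
            stack.pop()
            removed += 1
        else:
            stack.append(s)
    return Dow(stack), removed


def renumber_by_rank(w: Sequence[int]) -> Dow:
    """Relabel to ``1..n`` preserving the numeric order of the labels."""
    rank = {label: i + 1 for i, label in enumerate(sorted(set(w)))}
    return Dow(rank[s] for s in w)


def scrambled_pointer_count(w: Sequence[int]) -> int:
    """Number of distinct pointer labels in the word."""
    return len(set(w))


def canonical_form(w: Sequence[int]) -> Dow:
    """Relabel in order of first occurrence (the pattern-matching normal form)."""
    mapping: dict[int, int] = {}
    out: list[int] = []
    for s in w:
        if s not in mapping:
            mapping[s] = len(mapping) + 1
        out.append(mapping[s])
    return Dow(out)


def dow_isomorphic(w1: Sequence[int], w2: Sequence[int]) -> bool:
    """True iff the words are equal up to relabelling."""
    return canonical_form(w1) == canonical_form(w2)


# ---------------------------------------------------------------------------
# repeat / return pattern detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternHit:
    """One occurrence pair of a repeat/return word (or a trivial pair).

    ``positions`` holds the start offsets of the two disjoint spans;
    for ``repeat`` the second span equals ``u``, for ``return`` it
    equals ``u`` reversed, and for ``trivial_pair`` both spans are the
    two adjacent copies of a single label.
    """

    kind: Literal["repeat", "return", "trivial_pair"]
    u: tuple[int, ...]
    positions: tuple[int, int]
    maximal: bool = True

    @property
    def extent(self) -> int:
        """Width of the region covered from first span start to second span end."""
        return self.positions[1] + len(self.u) - self.positions[0]


def _repeat_maximal(w: Sequence[int], i: int, j: int, length: int) -> bool:
    n = len(w)
    if j + length < n and i + length + 1 <= j and w[i + length] == w[j + length]:
        return False
    if i >= 1 and i + length <= j - 1 and w[i - 1] == w[j - 1]:
        return False
    return True


def _return_maximal(w: Sequence[int], i: int, j: int, length: int) -> bool:
    n = len(w)
    # growing u on the right prepends to its reversed copy
    if i + length + 1 <= j - 1 and w[i + length] == w[j - 1]:
        return False
    # growing u on the left appends to its reversed copy
    if i >= 1 and j + length < n and i + length <= j and w[i - 1] == w[j + length]:
        return False
    return True


def find_patterns(
    w: Sequence[int],
    *,
    maximal_only: bool = True,
    include_trivial: bool = False,
) -> list[PatternHit]:
    """All repeat/return occurrence pairs with ``|u| >= 2`` on disjoint factors.

    With ``maximal_only`` (the default) only hits extendable in neither
    direction are returned.  Trivial adjacent pairs (``|u| = 1``) are a
    separate channel and only reported when ``include_trivial`` is set.
    Hits are ordered by the greedy preference: longest ``u`` first,
    then narrowest extent, then leftmost.
    """
    n = len(w)
    hits: list[PatternHit] = []
    for length in range(2, n // 2 + 1):
        for i in range(0, n - 2 * length + 1):
            u = tuple(w[i : i + length])
            ru = u[::-1]
            for j in range(i + length, n - length + 1):
                occ = tuple(w[j : j + length])
                if occ == u and (not maximal_only or _repeat_maximal(w, i, j, length)):
                    hits.append(
                        PatternHit("repeat", u, (i, j), maximal=_repeat_maximal(w, i, j, length))
                    )
                if occ == ru and (not maximal_only or _return_maximal(w, i, j, length)):
                    hits.append(
                        PatternHit("return", u, (i, j), maximal=_return_maximal(w, i, j, length))
                    )
    if include_trivial:
        for i in range(n - 1):
            if w[i] == w[i + 1]:
                hits.append(PatternHit("trivial_pair", (w[i],), (i, i + 1)))
    hits.sort(key=lambda h: (-len(h.u), h.extent, h.positions[0], h.positions[1]))
    return hits


def remove_hit(w: Sequence[int], hit: PatternHit) -> Dow:
    """Delete both occurrence spans of a hit from the word."""
    i, j = hit.positions
    length = len(hit.u)
    keep = [
        s
        for pos, s in enumerate(w)
        if not (i <= pos < i + length or j <= pos < j + length)
    ]
    return Dow(keep)


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionStep:
    hit: PatternHit
    word_before: Dow
    word_after: Dow


@dataclass(frozen=True)
class ReductionTrace:
    """Ordered record of removals ending in a residual word."""

    steps: tuple[ReductionStep, ...]
    residual: Dow
    fully_reduced: bool
    strategy: str
    warnings: tuple[str, ...] = field(default=())

    @property
    def pattern_steps(self) -> tuple[ReductionStep, ...]:
        """Steps that removed a repeat or return word (not trivial pairs)."""
        return tuple(s for s in self.steps if s.hit.kind != "trivial_pair")


def _trivial_hits(w: Sequence[int]) -> list[PatternHit]:
    return [
        PatternHit("trivial_pair", (w[i],), (i, i + 1))
        for i in range(len(w) - 1)
        if w[i] == w[i + 1]
    ]


def _greedy_steps(w: Dow) -> list[ReductionStep]:
    """Deterministic reduction: longest u, narrowest extent, leftmost.

    Repeat/return hits take precedence; adjacent identical pairs are
    only stripped (leftmost-first) when no pattern hit applies.
    """
    steps: list[ReductionStep] = []
    cur = Dow(w)
    while True:
        hits = find_patterns(cur)
        if not hits:
            trivial = _trivial_hits(cur)
            if not trivial:
                break
            hits = trivial
        hit = hits[0]
        nxt = remove_hit(cur, hit)
        steps.append(ReductionStep(hit, cur, nxt))
        cur = nxt
    return steps


def _all_moves(w: Dow) -> list[PatternHit]:
    moves = find_patterns(w, maximal_only=False)
    moves.extend(_trivial_hits(w))
    return moves


def _exhaustive_search(
    w: Dow, memo: dict[tuple[int, ...], tuple[int, tuple]]
) -> tuple[int, tuple]:
    """Minimal reachable residual length over every removal order.

    Branches over *all* repeat/return occurrence pairs (maximal or not)
    and trivial adjacent pairs; memoised on the exact word.  Returns the
    best residual length and the step path reaching it.
    """
    key = tuple(w)
    cached = memo.get(key)
    if cached is not None:
        return cached
    best_len, best_path = len(w), ()
    for hit in _all_moves(w):
        nxt = remove_hit(w, hit)
        sub_len, sub_path = _exhaustive_search(nxt, memo)
        if sub_len < best_len:
            best_len = sub_len
            best_path = ((hit, w, nxt),) + sub_path
            if best_len == 0:
                break
    memo[key] = (best_len, best_path)
    return best_len, best_path


def reduce_word(
    w: Sequence[int],
    strategy: Literal["exhaustive", "greedy"] = "exhaustive",
    *,
    max_symbols: int = 40,
) -> ReductionTrace:
    """Recursively remove repeat/return patterns (and stranded trivial pairs).

    ``greedy`` applies the deterministic preference order and reports
    its residual; ``exhaustive`` searches every removal order (bounded
    backtracking with memoisation) and returns a trace reaching the
    empty word whenever some order does, otherwise a trace to a
    minimal-length residual.  Above ``max_symbols`` distinct labels the
    exhaustive search falls back to greedy with a warning.
    """
    word = Dow(w)
    notes: tuple[str, ...] = ()
    if strategy == "exhaustive" and scrambled_pointer_count(word) > max_symbols:
        notes = (
            f"word has {scrambled_pointer_count(word)} labels > budget "
            f"{max_symbols}; falling back to greedy",
        )
        warnings.warn(notes[0], stacklevel=2)
        strategy = "greedy"

    if strategy == "greedy":
        steps = _greedy_steps(word)
        residual = steps[-1].word_after if steps else word
        return ReductionTrace(
            steps=tuple(steps),
            residual=residual,
            fully_reduced=len(residual) == 0,
            strategy="greedy",
            warnings=notes,
        )
    if strategy != "exhaustive":
        raise ValueError(f"unknown strategy {strategy!r}")

    # Prefer the deterministic greedy path when it already reaches ε.
    greedy_steps = _greedy_steps(word)
    if greedy_steps and len(greedy_steps[-1].word_after) == 0:
        return ReductionTrace(
            steps=tuple(greedy_steps),
            residual=greedy_steps[-1].word_after,
            fully_reduced=True,
            strategy="exhaustive",
            warnings=notes,
        )
    memo: dict[tuple[int, ...], tuple[int, tuple]] = {}
    _, path = _exhaustive_search(word, memo)
    steps = tuple(ReductionStep(h, b, a) for h, b, a in path)
    residual = steps[-1].word_after if steps else word
    return ReductionTrace(
        steps=steps,
        residual=residual,
        fully_reduced=len(residual) == 0,
        strategy="exhaustive",
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# tangled cords
# ---------------------------------------------------------------------------

def tangled_cord(n: int) -> Dow:
    """The n-th tangled-cord word: 1212, 121323, 12132434, ...

    TC(1) = 1212; TC(n) inserts the new label ``n+1`` immediately after
    the penultimate and the last symbol of TC(n-1).  TC(n) has ``n+1``
    labels and length ``2n+2``; it is irreducible under repeat/return
    removal for n >= 2.
    """
    if n < 1:
        raise ValueError(f"tangled cord index must be >= 1, got {n}")
    word = [1, 2, 1, 2]
    for m in range(2, n + 1):
        label = m + 1
        word.insert(len(word) - 1, label)  # after the penultimate symbol
        word.append(label)  # after the (old) last symbol
    return Dow(word)


def _restrict(w: Sequence[int], keep: frozenset[int]) -> tuple[int, ...]:
    return tuple(s for s in w if s in keep)


def contains_tangled_cord(
    w: Sequence[int],
    min_n: int = 2,
    *,
    allow_reversal: bool = False,
    allow_rotation: bool = False,
) -> int:
    """Largest ``n >= min_n`` with a label subset reading as TC(n).

    Restricting the word to a subset of its labels (i.e. recombining or
    removing the other pointers first) must be order-isomorphic to the
    tangled cord; matching is linear by default, with optional reversal
    and cyclic-rotation readings.  Returns 0 when no cord is found.
    ``min_n`` defaults to 2 because TC(1) = 1212 is an ordinary repeat
    word that equally describes odd-even maps.
    """
    if min_n < 1:
        raise ValueError(f"min_n must be >= 1, got {min_n}")
    word = Dow(w)
    labels = word.labels
    for size in range(len(labels), min_n, -1):
        n = size - 1
        target = tuple(tangled_cord(n))
        for subset in combinations(labels, size):
            sub = _restrict(word, frozenset(subset))
            for cand in _readings(sub, allow_reversal, allow_rotation):
                if tuple(canonical_form(cand)) == target:
                    return n
    return 0


def _readings(
    sub: tuple[int, ...], allow_reversal: bool, allow_rotation: bool
) -> Iterator[tuple[int, ...]]:
    base = [sub]
    if allow_reversal:
        base.append(sub[::-1])
    for cand in base:
        yield cand
        if allow_rotation:
            for r in range(1, len(cand)):
                yield cand[r:] + cand[:r]
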