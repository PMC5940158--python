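"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive results from first principles (exhaustive
enumeration, geometry) without calling the code paths they check.
"""

from __future__ import annotations

import math
from functools import lru_cache


def factor_pair_hits(word: tuple[int, ...], min_len: int = 2) -> list[tuple[int, int, int]]:
    """Every disjoint factor-pair occurrence (i, j, L) of a repeat or
    return word, by direct enumeration."""
    n = len(word)
    out = []
    for L in range(min_len, n // 2 + 1):
        for i in range(n - 2 * L + 1):
            u = word[i : i + L]
            for j in range(i + L, n - L + 1):
                occ = word[j : j + L]
                if occ == u or occ == u[::-1]:
                    out.append((i, j, L))
    return out


def reducible(word) -> bool:
    """True iff some sequence of removals (any repeat/return factor pair
    or adjacent identical pair) reaches the empty word."""

    @lru_cache(maxsize=None)
    def go(w: tuple[int, ...]) -> bool:
        if not w:
            return True
        n = len(w)
        moves = [(i, i + 1, 1) for i in range(n - 1) if w[i] == w[i + 1]]
        moves += factor_pair_hits(w)
        for i, j, L in moves:
            nxt = tuple(s for p, s in enumerate(w) if not (i <= p < i + L or j <= p < j + L))
            if go(nxt):
                return True
        return False

    return go(tuple(word))


def chord_endpoints(position: int, n: int) -> tuple[float, float]:
    theta = 2 * math.pi * position / n
    return (math.cos(theta), math.sin(theta))


def chords_cross_geometric(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    """Do the straight chords between circle positions intersect?

    Uses shapely segment intersection on unit-circle coordinates; chord
    endpoints are distinct positions so touching endpoints cannot occur.
    """
    from shapely.geometry import LineString

    seg_a = LineString([chord_endpoints(a[0], n), chord_endpoints(a[1], n)])
    seg_b = LineString([chord_endpoints(b[0], n), chord_endpoints(b[1], n)])
    return seg_a.intersects(seg_b)


def random_dow(rng, max_labels: int = 6) -> list[int]:
    """A uniform random shuffle of 1..L twice, L <= max_labels."""
    n_labels = rng.randint(1, max_labels)
    word = list(range(1, n_labels + 1)) * 2
    rng.shuffle(word)
    return word
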