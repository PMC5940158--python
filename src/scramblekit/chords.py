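"""Chord diagrams of pointer double-occurrence words.

The symbols of a DOW are placed clockwise on a circle from a reference
mark; a chord joins the two copies of each pointer.  Chords are
coloured by the role the pointer played in the reduction: removed in a
repeat word (blue), in a return word (green), as a trivial adjacent
pair / conventional IES (gray), or never removed (red, irreducible).
Rendering is deterministic: identical input yields byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .dow import Dow, PatternHit, ReductionTrace, reduce_word

CATEGORY_COLORS = {
    "repeat": "#1f77b4",  # blue
    "return": "#2ca02c",  # green
    "irreducible": "#d62728",  # red
    "plain": "#7f7f7f",  # gray
}

_CANVAS = 420
_RADIUS = 160.0
_CENTER = _CANVAS / 2.0


@dataclass(frozen=True)
class Chord:
    position_a: int
    position_b: int
    label: int
    category: str


@dataclass(frozen=True)
class ChordLayout:
    """Positions 0..n-1 clockwise from the reference mark at position 0."""

    n_positions: int
    chords: tuple[Chord, ...]
    word: tuple[int, ...]


def label_categories(trace: ReductionTrace) -> dict[int, str]:
    """Map each pointer label to the kind of step that removed it.

    Labels surviving in the residual are ``irreducible``; trivial-pair
    removals map to ``plain``.
    """
    cats: dict[int, str] = {}
    for step in trace.steps:
        kind = step.hit.kind
        cat = "plain" if kind == "trivial_pair" else kind
        for label in step.hit.u:
            cats.setdefault(label, cat)
    for label in set(trace.residual):
        cats.setdefault(label, "irreducible")
    return cats


def _categories_from_hits(w: Sequence[int], hits: Sequence[PatternHit]) -> dict[int, str]:
    cats: dict[int, str] = {}
    for hit in hits:
        cat = "plain" if hit.kind == "trivial_pair" else hit.kind
        for label in hit.u:
            cats.setdefault(label, cat)
    for label in set(w):
        cats.setdefault(label, "irreducible")
    return cats


def layout(
    w: Sequence[int],
    hits: Sequence[PatternHit] | None = None,
    *,
    categories: Mapping[int, str] | None = None,
) -> ChordLayout:
    """Build the chord layout of a word.

    By default labels are categorised from the deterministic greedy
    reduction of the word; pass ``hits`` (e.g. from
    :func:`scramblekit.dow.find_patterns`) or an explicit ``categories``
    mapping to override.
    """
    word = Dow(w)
    if categories is None:
        if hits is not None:
            categories = _categories_from_hits(word, hits)
        else:
            categories = label_categories(reduce_word(word, "greedy"))
    first: dict[int, int] = {}
    chords: list[Chord] = []
    for pos, label in enumerate(word):
        if label in first:
            chords.append(
                Chord(first.pop(label), pos, label, categories.get(label, "irreducible"))
            )
        else:
            first[label] = pos
    chords.sort(key=lambda c: c.position_a)
    return ChordLayout(n_positions=len(word), chords=tuple(chords), word=tuple(word))


def chords_cross(a: Chord, b: Chord) -> bool:
    """Two chords cross iff exactly one endpoint of one lies cyclically
    between the endpoints of the other."""
    a1, a2 = sorted((a.position_a, a.position_b))
    b1, b2 = sorted((b.position_a, b.position_b))
    return (a1 < b1 < a2 < b2) or (b1 < a1 < b2 < a2)


def crossing_count(lay: ChordLayout) -> int:
    cs = lay.chords
    return sum(
        1 for i in range(len(cs)) for j in range(i + 1, len(cs)) if chords_cross(cs[i], cs[j])
    )


def _point(position: int, n: int, radius: float = _RADIUS) -> tuple[float, float]:
    theta = -math.pi / 2 + 2 * math.pi * position / n
    return (_CENTER + radius * math.cos(theta), _CENTER + radius * math.sin(theta))


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def render_svg(lay: ChordLayout, path=None) -> str:
    """Deterministic SVG 1.1 of a chord layout.

    Fixed canvas and palette; the reference mark is a radial tick at
    position 0 (top).  Returns the SVG text; writes it to ``path`` when
    given.
    """
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_CANVAS}" height="{_CANVAS}" viewBox="0 0 {_CANVAS} {_CANVAS}">',
        f'<circle cx="{_fmt(_CENTER)}" cy="{_fmt(_CENTER)}" r="{_fmt(_RADIUS)}" '
        'fill="none" stroke="#000000" stroke-width="1.5"/>',
    ]
    n = lay.n_positions
    # reference mark: radial tick at the reading origin
    tick_angle = -math.pi / 2 if n == 0 else -math.pi / 2 - math.pi / max(n, 1)
    x1 = _CENTER + (_RADIUS - 8) * math.cos(tick_angle)
    y1 = _CENTER + (_RADIUS - 8) * math.sin(tick_angle)
    x2 = _CENTER + (_RADIUS + 8) * math.cos(tick_angle)
    y2 = _CENTER + (_RADIUS + 8) * math.sin(tick_angle)
    parts.append(
        f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
        'stroke="#000000" stroke-width="2.0"/>'
    )
    for chord in lay.chords:
        (xa, ya) = _point(chord.position_a, n)
        (xb, yb) = _point(chord.position_b, n)
        color = CATEGORY_COLORS[chord.category]
        parts.append(
            f'<line x1="{_fmt(xa)}" y1="{_fmt(ya)}" x2="{_fmt(xb)}" y2="{_fmt(yb)}" '
            f'stroke="{color}" stroke-width="1.5"/>'
        )
    for pos in range(n):
        (x, y) = _point(pos, n)
        parts.append(f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="3.0" fill="#000000"/>')
        (tx, ty) = _point(pos, n, _RADIUS + 18)
        parts.append(
            f'<text x="{_fmt(tx)}" y="{_fmt(ty)}" font-size="12" font-family="sans-serif" '
            f'text-anchor="middle" dominant-baseline="middle">{lay.word[pos]}</text>'
        )
    parts.append("</svg>\n")
    svg = "\n".join(parts)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(svg)
    return svg
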