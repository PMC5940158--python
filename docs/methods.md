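# Methods

## The model

A MAC nanochromosome with *k* MDSs is described by its **arrangement
map**: the signed sequence of MAC indices read along the MIC
chromosome, e.g. `M2 M3 -M8 -M7 -M1 -M4 M5 M6`. A map is
*nonscrambled* exactly when it is the identity `M1..Mk` (all forward)
or the whole-locus inversion `-Mk..-M1` (all inverted); the latter
counts as nonscrambled because order and relative orientation with
respect to the product are preserved.

**Pointer emission.** Pointer *i* is the repeat shared by the end of
MDS *i* and the start of MDS *i+1*, so MDS *i* carries pointers *i−1*
(its left end) and *i* (its right end), except that the terminal
indices 1 and *k* carry a single pointer. Scanning the map in MIC
order, a forward MDS emits *(i−1, i)*, an inverted one *(i, i−1)*;
concatenating the emissions yields a double occurrence word (DOW) over
labels `1..k−1`. Because terminal MDSs emit one symbol, their
orientation is invisible in the word (tested property). The empty word
ε is the DOW of a 1-MDS locus.

**Reduction.** Complexity is characterised by iterated deletion of

- *trivial pairs* — adjacent identical labels, the signature of a
  conventional IES between consecutive co-oriented MDSs; stripped as a
  cascade (deleting a pair may create a new adjacent pair, which is
  also deleted);
- *repeat words* — two disjoint factor occurrences `u…u`, `|u| ≥ 2`;
- *return words* — disjoint occurrences `u…reverse(u)`, `|u| ≥ 2`.

Occurrences are contiguous factors, never scattered subsequences: the
scattered reading would make the published irreducible residuals
reducible. Deleting an occurrence pair always leaves a valid DOW,
because in a DOW both copies of every label of `u` are covered by the
two spans.

A word is *reducible* when **some** order of removals reaches ε. Two
strategies are exposed:

- `greedy` — deterministic: repeat/return hits take precedence over
  trivial pairs; among maximal hits, longest `u` first, then the
  narrowest total extent (so a pattern nested inside another is removed
  first, matching the published worked reductions), then leftmost. The
  reported residual of a locus comes from this strategy.
- `exhaustive` — memoised backtracking over **all** factor-pair hits
  (maximal and non-maximal) plus trivial pairs; returns a trace to ε
  whenever one exists, otherwise to a minimal-length residual. Above 40
  distinct labels it falls back to greedy with a warning.

Greedy is *sound* (when it reaches ε the word is reducible) but not
*complete*: the word `535426131426` is reducible only by first removing
the non-maximal repeat `42` — its single maximal hit (`426`) is a dead
end. Such words are rare (≈0.05% of uniform random 6-label words) but
they exist, which is also why the exhaustive search must branch over
non-maximal hits. Reducibility decisions of the exhaustive strategy are
validated in the test suite against an independent enumeration oracle.

Trivial pairs are not deleted eagerly *during* reduction: a word like
`3443` that appears mid-reduction is treated as the return word it is
(one step), not as two cascading pair deletions. Eager stripping is the
right model only for the conventional-IES channel applied to the raw
pointer word, where the count of stripped pairs equals the number of
conventional IESs.

One asymmetry worth knowing: a nonscrambled map always strips to ε, but
a map whose word strips to ε is not necessarily nonscrambled —
`M1 M3 -M2` gives `1221`, which strips to ε although the locus is
scrambled (the inverted MDS is flanked symmetrically). Residual
scrambled pointers certify scrambling; their absence does not certify
its absence.

**Tangled cords.** TC(1) = `1212`; TC(n) inserts label *n+1* after the
penultimate and last symbols of TC(n−1). TC(n) has *n+1* labels and
length *2n+2*; TC(1) is an ordinary repeat word, and TC(n ≥ 2) is
irreducible (verified exhaustively for n = 2..6). Detection in a word
asks for the largest *n* such that restricting the word to some label
subset is order-isomorphic (first-occurrence canonical form) to TC(n) —
i.e. the cord appears after the other pointers are recombined or
removed. Matching is linear by default; reversal and cyclic-rotation
readings exist as flags but are off, since the published detections are
consistent with linear reading. The default `min_n = 2` avoids firing
on every repeat word via TC(1). Subset enumeration is exponential in
the label count but residual words are small (≲ 15 labels) in practice.

## Nesting metrics

IESs are the gaps between MDSs of the same MAC contig **adjacent in
MIC-coordinate order** (not MAC order); this is what makes "a gene
inside an IES of another gene" well defined for scrambled loci. An IES
is *conventional* when its flanking MDSs are consecutive in MAC order
and co-oriented (forward `i, i+1` or inverted `i+1, i`).

- **EI** of an MDS: the number of distinct foreign contigs having an
  IES that contains the MDS's interval; EI of a contig is the maximum
  over its MDSs. Non-recursive, reproduces the reference three-layer
  values 0/1/2.
- **IDI** of an IES: 0 if it contains no foreign MDS, else 1 plus the
  maximum, over foreign contigs with an MDS inside, of the deepest IDI
  among that contig's IESs *strictly* contained in the outer IES (0 if
  none). IDI of a contig is the maximum over its IESs. Descending only
  into strictly smaller intervals guarantees termination when loci
  interleave mutually; the interleaved fixtures in the test suite hit
  exactly this case.
- **Classification.** Contig *a* is *embedded* in *b* when all of *a*'s
  MDSs lie within a single IES of *b*; *a* and *b* are *interleaved*
  when each has at least one MDS inside an IES of the other. A contig's
  class aggregates its partners: `none`, `embedded_only`,
  `interleaved_only`, or `both`. A contig can in principle have an MDS
  in another's IES while satisfying neither definition (a straddling
  partial overlap without reciprocity); such a contig reports `none` —
  the genome-wide tabulations we mirror contain no such case, and the
  generator produces none.
- **Terminal-overlap filter.** Distinct MAC contigs whose MDSs overlap
  by more than `overlap_bp` on the MIC (default 20 bp, i.e. anything
  beyond pointer scale, 2–20 bp) are removed from the metrics entirely,
  mirroring the exclusion of contigs with overlapping terminal
  sequences. The threshold is a parameter because the published
  criterion is qualitative.

**Statistics.** Scrambling enrichment among nested contigs uses a 2×2
χ² (scrambled × IDI ≥ 1) with 1 df and no continuity correction
(intended cohorts number in the thousands). The IDI-gradient test is a
Spearman rank correlation of IDI class value against the class's
scrambled proportion — one point per class, exactly as the genome-wide
analysis reports it. With 4 classes a perfect ρ = 1 has a two-sided
exact p of 1/12 ≈ 0.083, so the p-value at that n is nominal at best;
the package reports it but the meaningful statistic at class level is ρ
itself. Degenerate inputs (one class, constant proportions) yield NaN
plus an explicit warning, never a silent zero.

MAC contigs split across several MIC contigs are flagged incomplete:
each portion is analysed on its own contig, IDI/EI aggregate by
maximum, the scrambled flag is judged from the observed portions (with
a warning), and such maps are excluded from pointer-word construction.

## Synthetic architectures

The generator plants architectures whose truth is known by
construction: Russian-doll chains (each child locus inserted wholly
inside one IES of its parent, so layer *i* of a depth-*d* chain has
IDI = d−i, EI = i, and inner layers are `embedded_only`), interleaved
pairs (strictly alternating MDSs, giving IDI = EI = 1 and
`interleaved_only` on both sides), and standalone loci. Arrangement
patterns: identity, odd-even (`M1 M3 M5 … M2 M4 …`, a repeat word that
reduces to ε), inverted odd-even (evens descending inverted, a return
word), tangled cords (realised as `M2 M1 -M3 … -M(n+1) M(n+2)`, whose
pointer word is TC(n)), and random signed permutations.

Defaults emulate the genome-wide conditions: MDS count per contig
2 + Poisson(7.7) (mean 9.7); scrambled fraction 12.8% split as
odd-even 6%, inverted odd-even 3%, tangled 2%, random permutation 1.8%;
doll-chain depth probabilities 0.90/0.08/0.015/0.004/0.001 for depths
0–4 (≈8% of loci nested, tail matching the observed 1163/125/11/2
counts); 3% interleaved. MDS lengths 30–600 bp and IES lengths
20–200 bp are realistic-scale uniform choices — lengths exist only to
make coordinates; no nucleotide sequence or pointer microhomology is
emulated. One `numpy` PCG64 generator seeded from the single config
seed drives everything; equal seeds give byte-identical GFF.

What passing on synthetic data does **not** show: robustness to real
annotation noise (overlapping MDS calls, missing MDSs, terminal-overlap
contigs are only exercised by dedicated fixtures), to paralogy, or to
genome-scale cohort sizes. Test cohorts use small configurations
(2 MIC contigs × 4 loci, 200 seeds; 1,000 random words for the
reduction oracle) chosen as the smallest sizes that exercise every
planted case class.

## Numerical and interface choices

- Coordinates are 1-based inclusive (GFF convention); containment tests
  use interval inclusion, with *strict* (proper-subset) inclusion in
  the IDI recursion's descent.
- Words serialise as concatenated digits when all labels ≤ 9 and
  comma-separated otherwise; a digit string containing `0` is rejected
  as ambiguous. ε prints as `ε`.
- Chord diagrams place the word's symbols clockwise from a reference
  tick; colours are fixed (repeat `#1f77b4`, return `#2ca02c`,
  irreducible `#d62728`, trivial `#7f7f7f`) and coordinates printed at
  fixed precision, so output is byte-identical across runs. Chord
  colours follow the greedy reduction trace by default; an explicit hit
  set can override.
- GFF parsing delegates per-line parsing to `gffutils`; the attribute
  keys for MAC contig, MDS index and orientation are configurable
  (YAML) because annotation exports differ; strand is the orientation
  fallback. Malformed lines are skipped with logged reasons.
- Reduction on words with more than 40 distinct labels is decided
  greedily (with a warning); the exhaustive search is exponential in
  the worst case and intended for residual-scale words.

## Known limitations

- Greedy reduction can misclassify a reducible word as irreducible in
  rare configurations (see above); use `exhaustive` when the
  reducibility verdict matters and the word is small.
- Pointers are symbolic labels; no sequence-level pointer alignment,
  recombination simulation, gene-function annotation or expression
  analysis is attempted.
- The embedded/interleaved dichotomy is not exhaustive for arbitrary
  interval layouts (see the classification note above).
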