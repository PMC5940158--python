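# scramblekit

Tools for analysing germline/somatic DNA rearrangement maps in ciliates
such as *Oxytricha trifallax*.

During development, a ciliate rebuilds its somatic macronucleus (MAC)
from a germline micronucleus (MIC) copy: each gene-sized MAC
nanochromosome is assembled from germline segments (**MDSs**,
macronuclear destined sequences) while the intervening spans (**IESs**,
internally eliminated sequences) are deleted. MDSs join by recombining
at short shared repeats called **pointers**. In scrambled loci the MDSs
lie out of order and/or inverted on the MIC chromosome, and whole loci
can be nested inside the IESs of other loci like Russian dolls.

`scramblekit` implements the combinatorial machinery for describing
these architectures:

- **Arrangement maps** — signed MDS orders such as
  `M2 M3 -M8 -M7 -M1 -M4 M5 M6`, parsed from compact notation or
  derived from GFF annotation tables.
- **Pointer double-occurrence words (DOWs)** — scanning MDSs in MIC
  order, a forward MDS *i* emits pointers *(i−1, i)* and an inverted
  one *(i, i−1)* (terminal indices emit a single pointer), giving a
  word in which every pointer label occurs exactly twice.
- **Repeat/return reduction** — iterative removal of repeat words
  (`u…u`) and return words (`u…reverse(u)`) on disjoint factors, after
  stripping the adjacent identical pairs contributed by conventional
  (nonscrambled) IESs. Words reducing to the empty word ε are explained
  by layered odd-even patterns; irreducible residuals mark atypical
  loci.
- **Tangled cords** — the recursive DOW family `1212, 121323,
  12132434, …` (irreducible from `121323` on), with subset-restriction
  detection of embedded cords.
- **Nesting metrics** — the insertion depth index (**IDI**, recursive
  count of nesting layers inside a contig's IESs) and embedding index
  (**EI**, layers of foreign contigs surrounding an MDS), plus
  embedded/interleaved classification, terminal-overlap filtering, and
  cohort enrichment statistics (χ², Spearman).
- **Chord diagrams** — deterministic SVG renderings with repeat (blue),
  return (green), trivial-pair (gray) and irreducible (red) pointers.
- **Synthetic architectures** — a seeded generator of MIC/MAC layouts
  with planted nesting depth, interleaving and scrambling patterns plus
  ground truth, so every stage is testable without a genome download.

## Worked example

The most compact highly scrambled locus has 8 MDSs in the order
`M2 M3 -M8 -M7 -M1 -M4 M5 M6`:

```text
$ scramblekit dow "M2 M3 -M8 -M7 -M1 -M4 M5 M6"
12237761434556
```

The three adjacent identical pairs (`22`, `77`, `55`) are conventional
IES junctions; stripping them and renumbering the surviving labels by
rank gives the scrambled pointer word `12413234`, which carries 4
scrambled pointers and contains the tangled cord `121323` once label 4
is removed:

```text
$ scramblekit tangled 12413234
2
```

A reducible word, traced step by step — the repeat `12·12` leaves the
return word `3443`, whose removal leaves ε:

```text
$ scramblekit reduce 12341243 --trace
step	kind	u	before	after
1	repeat	12	12341243	3443
2	return	34	3443	ε
ε
```

A synthetic cohort, analysed end to end:

```text
$ scramblekit simulate --seed 7 -o demo.gff --truth demo_truth.tsv
wrote demo.gff (328 MDS records)
wrote demo_truth.tsv
$ scramblekit summarize demo.gff
group	level	n_contigs	n_scrambled	pct_scrambled	avg_mds_count
processed	all	34	5	14.7	9.6
IDI	1	3	1	33.3	9.7
EI	1	3	1	33.3	11.7
...
```

34 MAC contigs were generated; 14.7% are scrambled and three carry a
nested locus (IDI = 1), matching the generator's genome-like defaults.
`scramblekit nesting demo.gff` prints the per-contig IDI/EI/class rows,
and `scramblekit chord <word> -o out.svg` draws any word's diagram.

The same operations are available as a library:

```python
>>> from scramblekit import parse_arrangement, pointer_word, reduce_word
>>> trace = reduce_word(pointer_word(parse_arrangement("M1 M3 M5 M2 -M4")))
>>> trace.fully_reduced, len(trace.steps)
(True, 2)
```

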