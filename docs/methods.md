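# Methods

## The workflow

phylocat builds a phylogenomic supermatrix in three stages.

**Split.** Each organism contributes one FASTA file; the gene key of a
record is the first whitespace-delimited token of its header (exact match by
default, lower-cased under `--case-fold`). Same-keyed records across
organisms form a gene family. With a user-supplied gene list, families
follow the list order and absences are tolerated (missing-data mode);
without one, only the intersection of all organisms' gene sets is used, in
lexicographic order (the gene order inside a supermatrix is arbitrary but
must be fixed; lexicographic is the deterministic choice). A listed gene
found in no organism yields an empty family that is excluded from alignment
and reported in the run summary — this is why the number of aligned genes
g′ can be smaller than the number requested g.

**Align.** Families with ≥2 members are aligned independently. The external
engine invokes any aligner honoring the MAFFT-style contract
`<exe> --auto --thread <T> <in.fasta>` → aligned FASTA on stdout, and its
output is validated rather than trusted: rows must be rectangular, the
member set complete, and every row must ungap byte-exactly to its input
sequence; a violation aborts the run naming the gene. The built-in engine is
a center-star progressive aligner over Needleman–Wunsch global pairwise
alignments with a linear gap penalty (defaults: match +1, mismatch −1, gap
−2). The center is the member maximizing the summed pairwise score to all
others (ties to the earliest organism in the run order); the remaining
members are merged into the growing alignment through their pairwise
alignment to the center under "once a gap, always a gap". Traceback ties
break diagonal > up > left, so the output is byte-deterministic and
independent of thread count. Singleton families skip alignment under either
engine.

The built-in engine exists so the whole workflow is runnable and exactly
reproducible with no external binary; it is a correct optimal-pairwise /
heuristic-multiple aligner, not a rival to MAFFT's accuracy on divergent
sequences. The pairwise DP fills its score matrix with vectorized row
recurrences (the within-row gap chain is a prefix-scan in gap-offset space)
and recomputes the traceback from the stored matrix; score-only queries —
center selection needs O(k²) of them per family — go through Biopython's C
`PairwiseAligner` configured to the identical objective, and a property test
pins the two routes to exact agreement.

**Concatenate.** Aligned families are concatenated organism by organism in
the fixed gene order. In missing-data mode an absent (organism, gene) cell
becomes a run of `?` spanning exactly that family's aligned width; `?`
(missing data) is deliberately distinct from `-` (alignment gap). In shared
mode every family covers every organism by construction and the matrix
contains no `?`. Partition coordinates are 1-based inclusive and contiguous;
the partition file tags each gene `DNA` or `WAG` by alphabet detection (≥90%
of non-gap residues in {A,C,G,T,U,N} ⇒ nucleotide), matching common RAxML
partition-file usage. Whether to emit a partition file at all was an open
design point; it is emitted because a supermatrix without one is rarely
usable downstream.

## Conventions and edge cases

- Organism id = FASTA basename without extension, whitespace replaced by
  `_` for tree-tool safety; duplicate ids abort the run. Relative entries in
  the organism list resolve against the list file's directory.
- Duplicate gene names within one organism file (e.g. IR-duplicated plastid
  genes): keep the first copy by default, `--duplicate-policy longest`
  as alternative; discarded copies are logged.
- An empty sequence body is treated as the gene being absent (warned).
- An empty FASTA file is an organism with zero genes — legal in
  missing-data mode, and it forces the shared-gene set empty otherwise.
- Zero shared genes in shared mode is an error that points the user to
  missing-data mode and the occupancy table, since the usual cause is
  inconsistent gene naming.
- Reports and supermatrix output are byte-deterministic given identical
  inputs; reruns of the pipeline with the built-in engine are
  byte-identical.

## The synthetic-data generator

`phylocat.synthfix` generates the study conditions every stage is tested
under: a set of organisms drawing on a common gene pool, with one random
ancestral sequence per gene, per-organism copies derived by per-site
substitutions and short indels, and each (organism, gene) pair dropped
independently with a fixed missingness probability. The written files are
exactly what the pipeline consumes, plus a ground-truth presence table.
Defaults: 50 organisms, 20 genes, gene lengths 60–120 nt, substitution rate
0.05/site, indel initiation 0.01/site with lengths 1–3, missingness 0.1,
seed 0. The 50 × 20 × 10% setting is the end-to-end test condition; gene
lengths are kept an order of magnitude below typical organellar genes so a
full 50-organism run with the pure-Python/numpy engine completes in seconds
while still exercising every code path — width-dependent behavior
(partition arithmetic, `?` spans, wrapping) is length-generic. A single seed
governs all randomness, generation order is fixed (genes outer, organisms
inner), and identical specs produce byte-identical files.

What the generator does *not* emulate: tree-structured evolution (every
organism diverges independently from the ancestor), rate heterogeneity,
codon structure, paralogy, or gene-name inconsistency. Passing tests
therefore demonstrate the bookkeeping — grouping, alignment invariants,
padding, coordinates, reports — on realistic-shaped data, not alignment
accuracy or phylogenetic signal on real sequences.

## Verification strategy

- Pairwise alignment scores are checked against exhaustive enumeration of
  all global alignments on short random pairs, against Biopython's
  independent global aligner on longer pairs, and against a naive greedy
  baseline they must dominate.
- Concatenation is checked against a hand-worked toy (two organisms, two
  genes, one absence) and, across randomized datasets, against the
  generator's truth table: a partition slice is all-`?` exactly when the
  generator dropped that pair, and every present slice ungaps to the
  written input sequence byte-exactly under both engines.
- Shared-gene logic is checked against brute-force set intersection, and
  occupancy-column sums against family sizes.
- GenBank extraction is checked on a hand-written flat file covering
  plus-strand, complement, and joined locations.

## Known limitations

- Gene-name identity is the join key; no synonym dictionaries or fuzzy
  matching.
- The built-in aligner's center-star heuristic has no refinement pass;
  for publication-grade alignments use `--engine external`.
- No codon-aware alignment, alignment trimming, per-partition model
  selection, or tree inference — the supermatrix and partition file are the
  hand-off to those tools.
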