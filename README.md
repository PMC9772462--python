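# phylocat

Split, align, and concatenate gene sequences from many organisms into a
phylogenomic **supermatrix**, with automatic missing-data handling.

## The problem

Joint phylogenetic inference from many genes is usually done on a
supermatrix: for *n* taxa and a set of genes, each gene is aligned
separately and the aligned blocks are concatenated into one rectangular
character matrix of *n* rows. Assembling that matrix by hand — regrouping
every gene across hundreds of per-organism FASTA files, aligning each group,
tracking which organism is missing which gene, and keeping the gene order
identical in every row — is slow and error-prone. phylocat automates the
whole path from "one FASTA of gene sequences per organism" to a supermatrix
ready for RAxML/IQ-TREE, for anyone doing organellar or multi-locus
phylogenomics.

## What it does

Given a list of *n* per-organism FASTA files (gene name = first token of
each header; nucleotide or amino acid):

1. **Split** — gather same-named genes across organisms into *g* gene
   families.
2. **Align** — align each family, either with an external aligner in its
   automatic mode (MAFFT's `--auto` interface) or with a built-in
   deterministic center-star progressive aligner (Needleman–Wunsch pairwise
   core, linear gap penalty).
3. **Concatenate** — join the *g′* aligned families (those with at least one
   sequence) organism by organism, in a fixed gene order, into a supermatrix.

Two modes, chosen by whether a gene list is supplied:

* **missing-data mode** (`--genes GENES.txt`): the listed genes define the
  matrix columns; an organism lacking a gene gets that gene's full aligned
  width filled with `?` (missing data), distinct from the alignment gap `-`.
* **shared mode** (no gene list): only genes present in *every* organism are
  used; the matrix contains no `?`.

Companion outputs: a RAxML-style partition file (`DNA, rbcL = 1-1428` lines,
1-based inclusive coordinates), a shared-gene report, an organisms × genes
occupancy table (TSV of 1/0 — the first place to look when a gene seems
missing because it was spelled differently), and a JSON run summary. Gene
FASTAs can also be extracted from GenBank flat files
(`phylocat.extract_genes_from_genbank`), including complement and joined
locations.

The one hard requirement is that gene names match exactly across organisms
(optionally case-folded with `--case-fold`); no synonym resolution is
attempted.

## Worked example

Generate a tiny seeded synthetic dataset (4 organisms, 3 genes, 20%
missingness) and run the pipeline on it:

```bash
python - <<'EOF'
from phylocat import SynthSpec, generate_dataset
spec = SynthSpec(n_organisms=4, gene_names=("matK","psbA","rbcL"),
                 gene_length_range=(30, 40), missing_rate=0.2, seed=42)
generate_dataset(spec, "data")
EOF
phylocat run --organisms data/organisms.txt --genes data/genes.txt --out out
```

The run summary printed to stdout:

```json
{
  "engine": "builtin",
  "genes_absent_everywhere": [],
  "genes_aligned": 3,
  "genes_requested": 3,
  "mode": "missing_data",
  "n_organisms": 4,
  "shared_genes": 2,
  "supermatrix_length": 110
}
```

4 organisms × 3 requested genes, all 3 aligned, total matrix width 110
columns; only 2 genes are shared by all four organisms. `out/partitions.txt`
gives each gene's column interval:

```
DNA, matK = 1-30
DNA, psbA = 31-73
DNA, rbcL = 74-110
```

and `out/gene_table.tsv` shows who has what — org002 lacks rbcL, so columns
74–110 of its supermatrix row are exactly 37 `?` characters:

```
organism	matK	psbA	rbcL
org001	1	1	1
org002	1	1	0
org003	1	1	1
org004	1	1	1
```

To use MAFFT instead of the built-in aligner:
`phylocat run ... --engine external --engine-path mafft --threads 4`.

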