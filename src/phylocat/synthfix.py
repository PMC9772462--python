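"""Seeded generator of synthetic multi-organism gene sets.

The generator emulates the pipeline's natural input — a set of organisms
drawing on a common gene pool, with per-gene sequence divergence
(substitutions and short indels relative to a random ancestral sequence)
and a controllable per-(organism, gene) missingness rate. It writes exactly
the files the pipeline consumes (per-organism FASTAs, an organism list
file, a gene list file) plus a ground-truth presence table, so every stage
of the pipeline can be checked against a known answer with no downloads.

Generation is a pure function of the spec: identical specs produce
byte-identical files. There is no tree-structured evolution — every
organism diverges independently from the ancestor — so the data exercise
the bookkeeping, not phylogenetic realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import write_fasta
from .splitter import PresenceMatrix

__all__ = ["SynthSpec", "SynthResult", "generate_dataset"]

_BASES = "ACGT"


def _default_gene_names() -> list[str]:
    return [f"gene{i:03d}" for i in range(1, 21)]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic dataset.

    Rates are per-site probabilities; ranges are inclusive. Defaults are a
    deliberately modest study: 50 organisms, 20 genes of 60–120 nt, 5%
    substitutions, 1% indel starts of 1–3 nt, and a 10% chance that any
    given organism is missing any given gene.
    """

    n_organisms: int = 50
    gene_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(_default_gene_names())
    )
    gene_length_range: tuple[int, int] = (60, 120)
    substitution_rate: float = 0.05
    indel_rate: float = 0.01
    indel_length_range: tuple[int, int] = (1, 3)
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organisms < 1:
            raise ValueError("need at least one organism")
        if not self.gene_names:
            raise ValueError("need at least one gene")
        for rate in (self.substitution_rate, self.indel_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        for lo, hi in (self.gene_length_range, self.indel_length_range):
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range ({lo}, {hi})")
        object.__setattr__(self, "gene_names", tuple(self.gene_names))

    @classmethod
    def from_json(cls, path) -> "SynthSpec":
        with open(path) as handle:
            raw = json.load(handle)
        for key in ("gene_length_range", "indel_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "gene_names" in raw:
            raw["gene_names"] = tuple(raw["gene_names"])
        return cls(**raw)


@dataclass
class SynthResult:
    """Paths written by :func:`generate_dataset` plus the ground truth."""

    organism_list_path: Path
    gene_list_path: Path
    organism_fasta_paths: list[Path]
    truth_path: Path
    truth: PresenceMatrix
    sequences: dict[str, dict[str, str]]  # organism -> gene -> written sequence


def _mutate(ancestor: str, spec: SynthSpec, rng: np.random.Generator) -> str:
    """Derive one organism's gene copy: substitutions, then indels.

    Indels are applied to the substituted copy; the written sequence (the
    post-indel one) is the truth downstream round-trips compare against.
    """
    seq = list(ancestor)
    sub_mask = rng.random(len(seq)) < spec.substitution_rate
    for pos in np.flatnonzero(sub_mask):
        alternatives = _BASES.replace(seq[pos], "") if seq[pos] in _BASES else _BASES
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    lo, hi = spec.indel_length_range
    out: list[str] = []
    for ch in seq:
        if rng.random() < spec.indel_rate:
            length = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:  # insertion before this site
                out.extend(_BASES[rng.integers(4)] for _ in range(length))
                out.append(ch)
            else:  # deletion starting here, handled one site at a time
                continue
        else:
            out.append(ch)
    if not out:  # pathological all-deleted case: keep one ancestral base
        out.append(ancestor[0])
    return "".join(out)


def generate_dataset(spec: SynthSpec, out_dir) -> SynthResult:
    """Write a complete synthetic input set under ``out_dir``.

    Emits one FASTA per organism (its present genes, in gene order), the
    organism list file, the gene list file, and ``truth_presence.tsv``
    recording which (organism, gene) pairs were generated. Iteration order
    is genes outer, organisms inner, so a fixed seed reproduces the same
    bytes everywhere.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    organisms = [f"org{i:03d}" for i in range(1, spec.n_organisms + 1)]
    genes = list(spec.gene_names)

    lo, hi = spec.gene_length_range
    per_org: dict[str, dict[str, str]] = {org: {} for org in organisms}
    presence = pd.DataFrame(False, index=organisms, columns=genes, dtype=bool)
    for gene in genes:
        length = int(rng.integers(lo, hi + 1))
        ancestor = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        for org in organisms:
            if rng.random() < spec.missing_rate:
                continue
            per_org[org][gene] = _mutate(ancestor, spec, rng)
            presence.loc[org, gene] = True

    fasta_paths: list[Path] = []
    for org in organisms:
        fasta_path = out_dir / f"{org}.fasta"
        write_fasta(
            [(gene, seq) for gene, seq in per_org[org].items()], fasta_path
        )
        fasta_paths.append(fasta_path)

    organism_list_path = out_dir / "organisms.txt"
    with open(organism_list_path, "w", newline="\n") as handle:
        for path in fasta_paths:
            handle.write(path.name + "\n")
    gene_list_path = out_dir / "genes.txt"
    with open(gene_list_path, "w", newline="\n") as handle:
        for gene in genes:
            handle.write(gene + "\n")

    truth = PresenceMatrix(organisms=organisms, genes=genes, table=presence)
    truth_path = out_dir / "truth_presence.tsv"
    presence.astype(int).to_csv(
        truth_path, sep="\t", index_label="organism", lineterminator="\n"
    )
    spec_path = out_dir / "spec.json"
    with open(spec_path, "w", newline="\n") as handle:
        json.dump(asdict(spec), handle, indent=2, default=list)
        handle.write("\n")

    return SynthResult(
        organism_list_path=organism_list_path,
        gene_list_path=gene_list_path,
        organism_fasta_paths=fasta_paths,
        truth_path=truth_path,
        truth=truth,
        sequences=per_org,
    )
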