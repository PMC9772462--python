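"""Concatenate aligned gene families into one rectangular supermatrix.

Each organism contributes one row: its aligned sequence for every gene, in
a fixed gene order. Where an organism lacks a gene, the gene's full aligned
width is filled with "?" — the conventional missing-data state, distinct
from the alignment gap "-". A partition table records each gene's column
interval in 1-based inclusive coordinates, the convention RAxML-style
partition files use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .aligner import AlignedGeneFamily, detect_alphabet
from .formats import write_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "Supermatrix",
    "missing_segment",
    "derive_partitions",
    "build_supermatrix",
    "write_supermatrix_fasta",
    "write_partition_file",
]

MISSING_CHAR = "?"


@dataclass(frozen=True)
class Partition:
    """One gene's contiguous column interval, 1-based inclusive."""

    gene_name: str
    start: int
    end: int
    kind: str  # "nucleotide" or "protein"

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    """The concatenated alignment: n organism rows × total aligned columns."""

    organisms: list[str]
    gene_order: list[str]
    rows: dict[str, str]
    partitions: list[Partition] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    def slice(self, organism_id: str, gene_name: str) -> str:
        """The row segment for one (organism, gene) cell."""
        for part in self.partitions:
            if part.gene_name == gene_name:
                return self.rows[organism_id][part.start - 1 : part.end]
        raise KeyError(gene_name)

    def missing_cells(self) -> set[tuple[str, str]]:
        """All (organism, gene) cells that are '?'-filled."""
        out = set()
        for part in self.partitions:
            for org in self.organisms:
                seg = self.rows[org][part.start - 1 : part.end]
                if seg == MISSING_CHAR * part.width:
                    out.add((org, part.gene_name))
        return out


def missing_segment(length: int) -> str:
    """The '?' filler standing in for an absent gene of aligned width ``length``."""
    if length < 1:
        raise ValueError(f"segment length must be positive, got {length}")
    return MISSING_CHAR * length


def derive_partitions(families: Sequence[AlignedGeneFamily]) -> list[Partition]:
    """Cumulative 1-based inclusive column intervals, one per family."""
    if not families:
        raise ValueError("no families given")
    parts: list[Partition] = []
    start = 1
    for fam in families:
        kind = detect_alphabet(fam.members.values())
        end = start + fam.aligned_length - 1
        parts.append(Partition(fam.gene_name, start, end, kind))
        start = end + 1
    return parts


def build_supermatrix(
    families: Sequence[AlignedGeneFamily],
    organisms: Sequence[str],
    mode: str = "missing_data",
) -> Supermatrix:
    """Concatenate aligned families into rows, one per organism.

    In ``missing_data`` mode an organism absent from a family gets a "?"
    segment of that family's aligned width. In ``shared_only`` mode every
    family must cover every organism (absences upstream are a caller bug)
    and the result contains no "?" at all.
    """
    if mode not in ("missing_data", "shared_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if not families:
        raise ValueError("no families to concatenate")
    organisms = list(organisms)
    if len(set(organisms)) != len(organisms):
        raise ValueError("duplicate organism ids in supermatrix")
    partitions = derive_partitions(families)
    rows: dict[str, str] = {}
    for org in organisms:
        segments: list[str] = []
        for fam in families:
            if org in fam.members:
                segments.append(fam.members[org])
            elif mode == "shared_only":
                raise ValueError(
                    f"shared_only mode but organism {org!r} lacks gene "
                    f"{fam.gene_name!r}"
                )
            else:
                segments.append(missing_segment(fam.aligned_length))
        rows[org] = "".join(segments)
    sm = Supermatrix(
        organisms=organisms,
        gene_order=[f.gene_name for f in families],
        rows=rows,
        partitions=partitions,
    )
    logger.info(
        "stage=concat organisms=%d genes=%d length=%d mode=%s",
        len(organisms), len(families), sm.length, mode,
    )
    return sm


def write_supermatrix_fasta(sm: Supermatrix, path, wrap: int = 60) -> None:
    """Write the supermatrix as FASTA; organism ids must be unique."""
    write_fasta(
        [(org, sm.rows[org]) for org in sm.organisms],
        path,
        wrap=wrap,
        allow_duplicate_ids=False,
    )


def write_partition_file(sm: Supermatrix, path) -> None:
    """Write one partition line per gene: ``DNA, rbcL = 1-1428`` style.

    The model keyword is DNA for nucleotide partitions and WAG for protein
    ones, matching common RAxML partition-file usage.
    """
    with open(path, "w", newline="\n") as handle:
        for part in sm.partitions:
            kind = "DNA" if part.kind == "nucleotide" else "WAG"
            handle.write(f"{kind}, {part.gene_name} = {part.start}-{part.end}\n")
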