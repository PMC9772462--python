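"""Gather same-named genes across organisms into per-gene families.

A gene family here is the unit of alignment: all sequences that carry the
same gene name, one per organism at most. Two modes exist. With a gene list
the families follow the list order and absences become missing data; without
one only the genes shared by every organism are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .formats import GeneRecord, OrganismGeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFamily",
    "PresenceMatrix",
    "split_by_gene",
    "compute_shared_genes",
    "build_presence_matrix",
]


@dataclass
class GeneFamily:
    """Same-named gene records gathered across organisms.

    ``members`` is ordered by the run's organism list; a family may be empty
    when a listed gene occurs in no organism (such families are excluded
    from alignment but reported).
    """

    gene_name: str
    members: dict[str, GeneRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for org, rec in self.members.items():
            if rec.gene_name != self.gene_name:
                raise ValueError(
                    f"family {self.gene_name!r} got record named {rec.gene_name!r} "
                    f"from organism {org!r}"
                )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PresenceMatrix:
    """Organisms × genes boolean occupancy table.

    Row order follows the input organism list, column order the requested
    gene order. The table is the per-organism gene report that lets a user
    spot genes hiding under divergent names.
    """

    organisms: list[str]
    genes: list[str]
    table: pd.DataFrame  # bool, index=organisms, columns=genes

    def column_sums(self) -> dict[str, int]:
        return {g: int(self.table[g].sum()) for g in self.genes}

    def shared_genes(self) -> list[str]:
        """Genes present in every organism, in column order."""
        return [g for g in self.genes if bool(self.table[g].all())]

    def occupancy(self) -> float:
        """Fraction of filled (organism, gene) cells."""
        return float(self.table.to_numpy().mean()) if self.table.size else 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return (
            self.organisms == other.organisms
            and self.genes == other.genes
            and self.table.equals(other.table)
        )


def _check_organism_sets(organism_sets: Sequence[OrganismGeneSet]) -> None:
    if not organism_sets:
        raise ValueError("no organisms given")
    ids = [o.organism_id for o in organism_sets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate organism ids: {dupes}")


def compute_shared_genes(organism_sets: Sequence[OrganismGeneSet]) -> list[str]:
    """Genes present in every organism, lexicographically sorted.

    An empty intersection is a valid result (warned) — it typically means
    the gene names are inconsistent across files and the occupancy table
    should be inspected.
    """
    _check_organism_sets(organism_sets)
    shared = set(organism_sets[0].records)
    for org_set in organism_sets[1:]:
        shared &= set(org_set.records)
    if not shared:
        logger.warning("stage=split action=no_shared_genes n_organisms=%d",
                       len(organism_sets))
    return sorted(shared)


def split_by_gene(
    organism_sets: Sequence[OrganismGeneSet],
    gene_list: Sequence[str] | None = None,
) -> list[GeneFamily]:
    """Regroup per-organism gene sets into per-gene families.

    With ``gene_list`` (missing-data mode) one family per listed gene is
    produced, in list order, possibly empty; organisms lacking the gene are
    simply not members. Without it (shared mode) only the genes present in
    every organism are used, in lexicographic order. Member order inside a
    family follows the organism order, never the gene order inside any one
    FASTA.
    """
    _check_organism_sets(organism_sets)
    if gene_list is not None:
        genes = list(dict.fromkeys(gene_list))
    else:
        genes = compute_shared_genes(organism_sets)
    families: list[GeneFamily] = []
    for gene in genes:
        members = {
            org_set.organism_id: org_set.records[gene]
            for org_set in organism_sets
            if gene in org_set.records
        }
        if not members:
            logger.warning("stage=split gene=%s action=absent_in_all_organisms", gene)
        families.append(GeneFamily(gene_name=gene, members=members))
    return families


def build_presence_matrix(
    organism_sets: Sequence[OrganismGeneSet],
    gene_order: Sequence[str],
) -> PresenceMatrix:
    """Build the occupancy table for ``gene_order`` over the given organisms."""
    _check_organism_sets(organism_sets)
    genes = list(dict.fromkeys(gene_order))
    if not genes:
        raise ValueError("empty gene order")
    organisms = [o.organism_id for o in organism_sets]
    data = {
        g: [g in org_set.records for org_set in organism_sets] for g in genes
    }
    table = pd.DataFrame(data, index=organisms, columns=genes, dtype=bool)
    return PresenceMatrix(organisms=organisms, genes=genes, table=table)
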