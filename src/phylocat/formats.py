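"""Reading and writing the file formats the pipeline consumes and emits.

Inputs are per-organism FASTA files (one record per gene, the gene name being
the first token of the header), plain-text list files (one entry per line),
and optionally GenBank flat files from which per-organism gene FASTAs are
extracted. The gene name printed in the header is the join key across
organisms, so the parsing rules here define what "the same gene" means for
the rest of the pipeline.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GeneRecord",
    "OrganismGeneSet",
    "read_fasta",
    "write_fasta",
    "parse_gene_name",
    "read_name_list",
    "load_organism_fasta",
    "extract_genes_from_genbank",
    "organism_id_from_path",
]


class FormatError(ValueError):
    """Malformed input file or header."""


@dataclass(frozen=True)
class GeneRecord:
    """One named gene sequence from one organism.

    ``sequence`` is upper-cased on construction and must be a non-empty
    whitespace-free string over A–Z and ``-``; empty sequences are rejected
    here because "gene with no residues" is represented upstream as the gene
    simply being absent.
    """

    gene_name: str
    organism_id: str
    sequence: str
    source_header: str = ""

    def __post_init__(self) -> None:
        if not self.gene_name or any(c.isspace() for c in self.gene_name):
            raise FormatError(f"invalid gene name {self.gene_name!r}")
        if not self.sequence:
            raise FormatError(
                f"empty sequence for gene {self.gene_name!r} "
                f"(organism {self.organism_id!r})"
            )
        if any(c.isspace() for c in self.sequence):
            raise FormatError(f"whitespace in sequence of gene {self.gene_name!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class OrganismGeneSet:
    """All gene records loaded from one organism's FASTA file.

    ``records`` preserves file order and holds at most one record per gene
    name (the duplicate policy is applied at load time).
    """

    organism_id: str
    records: dict[str, GeneRecord] = field(default_factory=dict)
    source_path: str = ""

    @property
    def gene_names(self) -> list[str]:
        return list(self.records)


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(header, sequence)`` pairs.

    Multi-line bodies are concatenated, sequences are upper-cased and
    stripped of internal whitespace, and record order is preserved. An empty
    file yields an empty list (the organism has no genes). Text before the
    first ``>`` or a header with an empty name is a :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as handle:
        text = handle.read()
    stripped = text.lstrip()
    if not stripped:
        return []
    if not stripped.startswith(">"):
        raise FormatError(f"{path}: content before first '>' header")
    out: list[tuple[str, str]] = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            if not title.strip():
                raise FormatError(f"{path}: FASTA header with empty name")
            out.append((title, "".join(seq.split()).upper()))
    return out


def write_fasta(
    records: Sequence[tuple[str, str]],
    path: str | os.PathLike,
    wrap: int = 60,
    allow_duplicate_ids: bool = True,
) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapping at ``wrap`` columns.

    Output bytes are deterministic for identical input. Duplicate ids are an
    error when ``allow_duplicate_ids`` is false (supermatrix rows are keyed
    by organism) and a logged warning otherwise (gene-family files may
    legitimately repeat a name).
    """
    if wrap < 1:
        raise ValueError(f"wrap must be positive, got {wrap}")
    seen: set[str] = set()
    for rid, _ in records:
        if not rid or any(c.isspace() for c in rid):
            raise FormatError(f"invalid FASTA id {rid!r}")
        if rid in seen:
            if not allow_duplicate_ids:
                raise FormatError(f"duplicate FASTA id {rid!r}")
            logger.warning("stage=write_fasta action=duplicate_id id=%s", rid)
        seen.add(rid)
    with open(path, "w", newline="\n") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                handle.write(seq[i : i + wrap] + "\n")


def parse_gene_name(header: str, case_fold: bool = False) -> str:
    """Return the gene key from a FASTA header (text after ``>``).

    The key is the first whitespace-delimited token; the rest of the header
    is description and ignored for matching. With ``case_fold`` the key is
    lower-cased so differently-cased spellings collapse to one gene.
    """
    token = header.split(None, 1)[0] if header.strip() else ""
    if not token:
        raise FormatError(f"empty gene name in header {header!r}")
    return token.lower() if case_fold else token


def read_name_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text list file: one entry per non-blank line.

    Lines starting with ``#`` are comments. Duplicates are dropped keeping
    the first occurrence, with a warning; an effectively empty list is an
    error.
    """
    entries: list[str] = []
    seen: set[str] = set()
    with open(path) as handle:
        for line in handle:
            entry = line.strip()
            if not entry or entry.startswith("#"):
                continue
            if entry in seen:
                logger.warning(
                    "stage=read_list action=duplicate_entry entry=%s file=%s",
                    entry, path,
                )
                continue
            seen.add(entry)
            entries.append(entry)
    if not entries:
        raise FormatError(f"{path}: list file contains no entries")
    return entries


def organism_id_from_path(path: str | os.PathLike) -> str:
    """Organism id = file basename without extension, whitespace → ``_``."""
    stem = Path(path).stem
    return "_".join(stem.split())


def load_organism_fasta(
    path: str | os.PathLike,
    case_fold: bool = False,
    duplicate_policy: str = "first",
    organism_id: str | None = None,
) -> OrganismGeneSet:
    """Load one organism's gene FASTA into an :class:`OrganismGeneSet`.

    Empty sequence bodies are treated as the gene being absent (warned, not
    fatal). Duplicate gene names within the file are resolved by
    ``duplicate_policy``: ``"first"`` keeps the first copy, ``"longest"``
    keeps the longest (ties to the earlier copy); either way the discarded
    copies are logged. IR-duplicated plastid genes are the typical source of
    such duplicates.
    """
    if duplicate_policy not in ("first", "longest"):
        raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    org = organism_id if organism_id is not None else organism_id_from_path(path)
    records: dict[str, GeneRecord] = {}
    for header, seq in read_fasta(path):
        gene = parse_gene_name(header, case_fold=case_fold)
        if not seq:
            logger.warning(
                "stage=load organism=%s gene=%s action=empty_sequence_treated_missing",
                org, gene,
            )
            continue
        rec = GeneRecord(gene, org, seq, source_header=header)
        if gene in records:
            keep_new = duplicate_policy == "longest" and len(rec.sequence) > len(
                records[gene].sequence
            )
            logger.warning(
                "stage=load organism=%s gene=%s action=duplicate_gene policy=%s kept=%s",
                org, gene, duplicate_policy, "new" if keep_new else "existing",
            )
            if keep_new:
                records[gene] = rec
            continue
        records[gene] = rec
    return OrganismGeneSet(organism_id=org, records=records, source_path=str(path))


def extract_genes_from_genbank(
    path: str | os.PathLike,
    feature_kind: str = "gene",
    name_qualifier: str = "gene",
) -> OrganismGeneSet:
    """Extract gene sequences from a GenBank flat file.

    For every feature of ``feature_kind`` carrying ``name_qualifier``, the
    feature span is sliced from the record sequence (GenBank coordinates are
    1-based inclusive), reverse-complemented on the minus strand, and joined
    parts concatenated in annotation order — all delegated to Biopython's
    feature extraction. The organism id is the record accession, falling
    back to the file basename; duplicate gene names keep the first copy.
    """
    path = Path(path)
    try:
        genbank_records = list(SeqIO.parse(path, "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FormatError(f"{path}: unparsable GenBank file: {exc}") from exc
    if not genbank_records:
        raise FormatError(f"{path}: no GenBank records found")
    first = genbank_records[0]
    org = first.id if first.id and first.id != "<unknown id>" else None
    if not org:
        org = organism_id_from_path(path)
    org = "_".join(org.split())
    out: dict[str, GeneRecord] = {}
    for gb_rec in genbank_records:
        for feature in gb_rec.features:
            if feature.type != feature_kind:
                continue
            names = feature.qualifiers.get(name_qualifier)
            if not names:
                continue
            gene = str(names[0]).strip()
            if not gene:
                continue
            seq = str(feature.extract(gb_rec.seq)).upper()
            if not seq:
                logger.warning(
                    "stage=genbank organism=%s gene=%s action=empty_feature_skipped",
                    org, gene,
                )
                continue
            if gene in out:
                logger.warning(
                    "stage=genbank organism=%s gene=%s action=duplicate_feature_kept_first",
                    org, gene,
                )
                continue
            out[gene] = GeneRecord(gene, org, seq, source_header=f"{gene} {gb_rec.id}")
    if not out:
        logger.warning(
            "stage=genbank file=%s action=no_qualifying_features kind=%s qualifier=%s",
            path, feature_kind, name_qualifier,
        )
    return OrganismGeneSet(organism_id=org, records=out, source_path=str(path))
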