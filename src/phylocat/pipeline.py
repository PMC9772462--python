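"""Single-command orchestration: split → align → concatenate → report.

The run is configured once (:class:`RunConfig`) and executed by
:func:`run_pipeline`, which wires the stages together:

1. read the organism list and load each organism's gene FASTA;
2. regroup records into per-gene families (gene-list order when a gene
   list is given, otherwise shared genes only);
3. align every non-empty family (external auto-mode aligner or the
   built-in engine);
4. concatenate into the supermatrix, padding absences with "?" in
   missing-data mode;
5. write the supermatrix FASTA, partition file, shared-gene report,
   occupancy table and a JSON run summary.

Mode is implied by the gene list: providing one enables missing-data
handling; omitting it restricts the analysis to shared genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import formats, reports, splitter, supermatrix as sm_mod
from .aligner import ScoringScheme, align_families

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed in a way that should abort the run."""


@dataclass
class RunConfig:
    """Everything one run needs; the pipeline itself is deterministic."""

    organism_list_path: str
    gene_list_path: str | None = None
    engine: str = "builtin"  # "builtin" or "external"
    engine_path: str = "mafft"
    threads: int = 1
    output_dir: str = "phylocat_out"
    keep_intermediates: bool = False
    case_fold: bool = False
    duplicate_policy: str = "first"
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    @property
    def mode(self) -> str:
        return "missing_data" if self.gene_list_path else "shared_only"


def _resolve(entry: str, list_path: Path) -> Path:
    path = Path(entry)
    return path if path.is_absolute() else list_path.parent / path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow; returns the machine-readable run summary.

    The summary reports n (organisms), g (genes requested), g´ (genes that
    had at least one sequence and were aligned), the supermatrix length L,
    and the paths of every output file.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    list_path = Path(config.organism_list_path)
    fasta_entries = formats.read_name_list(list_path)
    organism_sets = []
    seen_ids: set[str] = set()
    for entry in fasta_entries:
        org_set = formats.load_organism_fasta(
            _resolve(entry, list_path),
            case_fold=config.case_fold,
            duplicate_policy=config.duplicate_policy,
        )
        if org_set.organism_id in seen_ids:
            raise PipelineError(
                f"duplicate organism id {org_set.organism_id!r} "
                f"(from {entry!r}); rename the input file"
            )
        seen_ids.add(org_set.organism_id)
        organism_sets.append(org_set)
    organisms = [o.organism_id for o in organism_sets]
    logger.info("stage=load organisms=%d", len(organisms))

    gene_list = None
    if config.gene_list_path:
        gene_list = formats.read_name_list(config.gene_list_path)
        if config.case_fold:
            gene_list = list(dict.fromkeys(g.lower() for g in gene_list))

    shared = splitter.compute_shared_genes(organism_sets)
    if config.mode == "shared_only" and not shared:
        raise PipelineError(
            "no genes are shared by all organisms; rerun with a gene list "
            "(missing-data mode) or check the gene table for name mismatches"
        )

    families = splitter.split_by_gene(organism_sets, gene_list)
    empty_genes = [f.gene_name for f in families if len(f) == 0]
    nonempty = [f for f in families if len(f) > 0]
    genes_requested = len(families)

    observed = sorted({g for o in organism_sets for g in o.records})
    if gene_list is not None:
        extras = [g for g in observed if g not in set(gene_list)]
        presence_order = list(gene_list) + extras
    else:
        presence_order = observed
    presence = splitter.build_presence_matrix(organism_sets, presence_order)

    aligned = align_families(
        nonempty,
        engine=config.engine,
        engine_path=config.engine_path,
        threads=config.threads,
        scoring=config.scoring,
    )
    if config.keep_intermediates:
        fam_dir = out_dir / "families"
        aln_dir = out_dir / "aligned_families"
        fam_dir.mkdir(exist_ok=True)
        aln_dir.mkdir(exist_ok=True)
        for fam, aln in zip(nonempty, aligned):
            formats.write_fasta(
                [(org, rec.sequence) for org, rec in fam.members.items()],
                fam_dir / f"{fam.gene_name}.fasta",
            )
            formats.write_fasta(
                list(aln.members.items()), aln_dir / f"{fam.gene_name}.fasta"
            )

    matrix = sm_mod.build_supermatrix(aligned, organisms, mode=config.mode)

    supermatrix_path = out_dir / "supermatrix.fasta"
    partition_path = out_dir / "partitions.txt"
    shared_path = out_dir / "shared_genes.txt"
    table_path = out_dir / "gene_table.tsv"
    summary_path = out_dir / "run_summary.json"
    sm_mod.write_supermatrix_fasta(matrix, supermatrix_path)
    sm_mod.write_partition_file(matrix, partition_path)
    reports.write_shared_report(shared, shared_path)
    reports.write_gene_table(presence, table_path)

    summary: dict[str, Any] = {
        "mode": config.mode,
        "engine": config.engine,
        "n_organisms": len(organisms),
        "genes_requested": genes_requested,
        "genes_aligned": len(aligned),
        "genes_absent_everywhere": empty_genes,
        "shared_genes": len(shared),
        "supermatrix_length": matrix.length,
        "outputs": {
            "supermatrix": str(supermatrix_path),
            "partitions": str(partition_path),
            "shared_report": str(shared_path),
            "gene_table": str(table_path),
            "summary": str(summary_path),
        },
    }
    with open(summary_path, "w", newline="\n") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    logger.info(
        "stage=done n=%d g=%d g_aligned=%d L=%d",
        len(organisms), genes_requested, len(aligned), matrix.length,
    )
    return summary
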