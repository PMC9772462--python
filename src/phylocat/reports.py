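"""End-of-run reports: the shared-gene list and the per-organism gene table.

The gene table (occupancy matrix as TSV, cells 1/0) is the primary
diagnostic for the pipeline's one hard requirement — that gene names match
across organisms. A gene present everywhere except one organism usually
means a spelling variant, and the table makes that visible at a glance.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .splitter import PresenceMatrix

__all__ = ["write_shared_report", "write_gene_table", "read_gene_table"]


def write_shared_report(shared: Sequence[str], path) -> None:
    """Write the shared-gene list, one gene per line, with a count header."""
    with open(path, "w", newline="\n") as handle:
        handle.write(f"# shared_genes: {len(shared)}\n")
        for gene in shared:
            handle.write(f"{gene}\n")


def write_gene_table(matrix: PresenceMatrix, path) -> None:
    """Write the occupancy matrix as TSV with 1/0 cells.

    Row and column order are preserved exactly, so
    ``read_gene_table(write_gene_table(m)) == m``.
    """
    matrix.table.astype(int).to_csv(
        path, sep="\t", index_label="organism", lineterminator="\n"
    )


def read_gene_table(path) -> PresenceMatrix:
    """Re-parse a gene table TSV into a PresenceMatrix."""
    frame = pd.read_csv(path, sep="\t", index_col="organism", dtype=str)
    table = frame.astype(int).astype(bool)
    table.index = table.index.astype(str)
    table.index.name = None
    return PresenceMatrix(
        organisms=[str(o) for o in table.index],
        genes=[str(g) for g in table.columns],
        table=table,
    )
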