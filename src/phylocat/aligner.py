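"""Per-family multiple sequence alignment.

Each gene family is aligned independently, either by an external aligner in
its automatic mode (MAFFT's ``--auto`` contract: reads a FASTA argument,
writes aligned FASTA to stdout) or by a built-in deterministic center-star
progressive aligner so the pipeline runs with no external dependency.

The built-in engine is intentionally simple science: global Needleman–Wunsch
pairwise alignment under a linear gap penalty, a center sequence chosen to
maximize the summed pairwise scores, and "once a gap, always a gap" merging.
It is not a substitute for a modern MSA program's accuracy; it exists to
make every downstream contract (rectangularity, ungap round-trip, missing
data bookkeeping) testable and byte-reproducible.
"""

from __future__ import annotations

import functools
import io
import logging
import subprocess
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .formats import write_fasta
from .splitter import GeneFamily

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentError",
    "ScoringScheme",
    "AlignedGeneFamily",
    "pairwise_align_global",
    "pairwise_score",
    "progressive_align_family",
    "align_family",
    "align_families",
    "detect_alphabet",
]

_NUC_RESIDUES = set("ACGTUN")


class AlignmentError(RuntimeError):
    """Alignment engine failure or invalid engine output."""


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/linear-gap scores for the built-in engine.

    Defaults (+1/−1/−2) are a conventional transversion-blind toy scheme;
    the external engine ignores them entirely.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclass
class AlignedGeneFamily:
    """A gene family after alignment: rectangular rows over residues and '-'.

    Invariants: every member has length ``aligned_length``; removing gaps
    from a member reproduces its input sequence; no member is all-gap.
    """

    gene_name: str
    members: dict[str, str] = field(default_factory=dict)
    aligned_length: int = 0

    def __post_init__(self) -> None:
        if self.members and self.aligned_length == 0:
            self.aligned_length = len(next(iter(self.members.values())))
        for org, row in self.members.items():
            if len(row) != self.aligned_length:
                raise AlignmentError(
                    f"gene {self.gene_name}: member {org} has length {len(row)}, "
                    f"expected {self.aligned_length}"
                )
            if row and not row.strip("-"):
                raise AlignmentError(f"gene {self.gene_name}: member {org} is all gaps")


def _close(x: float, y: float) -> bool:
    return abs(x - y) <= 1e-9 * (1.0 + abs(x) + abs(y))


def _fill_dp(a: str, b: str, s: ScoringScheme) -> np.ndarray:
    """Needleman–Wunsch score matrix, rows vectorized.

    The within-row left-gap dependency is a running max, solved with a
    prefix-scan in gap-offset space so each row is a handful of numpy ops.
    """
    m, n = len(a), len(b)
    gap = float(s.gap)
    a_arr = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    H = np.empty((m + 1, n + 1))
    H[0] = gap * np.arange(n + 1)
    offs = gap * np.arange(1, n + 1)
    for i in range(1, m + 1):
        sub = np.where(b_arr == a_arr[i - 1], s.match, s.mismatch)
        prev = H[i - 1]
        cand = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        u = np.maximum.accumulate(np.concatenate(([i * gap], cand - offs)))
        H[i, 0] = i * gap
        H[i, 1:] = u[1:] + offs
    return H


def pairwise_align_global(
    a: str, b: str, s: ScoringScheme = ScoringScheme()
) -> tuple[str, str, float]:
    """Global pairwise alignment under a linear gap penalty.

    Returns ``(aligned_a, aligned_b, score)`` where the score is optimal.
    Traceback ties are broken diagonal > up > left, so the alignment (not
    just the score) is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    H = _fill_dp(a, b, s)
    gap = float(s.gap)
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = s.match if a[i - 1] == b[j - 1] else s.mismatch
            if _close(H[i, j], H[i - 1, j - 1] + sub):
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and _close(H[i, j], H[i - 1, j] + gap):
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
            continue
        ra.append("-")
        rb.append(b[j - 1])
        j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), float(H[len(a), len(b)])


@functools.lru_cache(maxsize=8)
def _make_scorer(s: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = s.match
    aligner.mismatch_score = s.mismatch
    aligner.open_gap_score = s.gap
    aligner.extend_gap_score = s.gap
    return aligner


def pairwise_score(a: str, b: str, s: ScoringScheme = ScoringScheme()) -> float:
    """Optimal global alignment score, without a traceback.

    Score-only queries (center selection does O(k²) of them) go through
    Biopython's C pairwise engine configured to the same objective as
    :func:`pairwise_align_global`; the two agree by construction and a
    property test holds them to it.
    """
    if not a or not b:
        raise ValueError("cannot score an empty sequence")
    return float(_make_scorer(s).score(a, b))


def _merge_once_a_gap(
    master: str,
    rows: dict[str, str],
    c_aln: str,
    s_aln: str,
    new_org: str,
) -> tuple[str, dict[str, str]]:
    """Merge a new (center, member) pairwise alignment into the growing MSA.

    ``master`` and ``c_aln`` both ungap to the center sequence; columns are
    reconciled left to right and gaps already placed are never removed.
    """
    ops: list[str] = []  # B: column in both, M: master-only, C: pairwise-only
    i = j = 0
    while i < len(master) or j < len(c_aln):
        mi = master[i] if i < len(master) else None
        cj = c_aln[j] if j < len(c_aln) else None
        if mi is not None and cj is not None and (mi == "-") == (cj == "-"):
            ops.append("B")
            i += 1
            j += 1
        elif mi == "-" or cj is None:
            ops.append("M")
            i += 1
        else:  # cj == "-" or master exhausted: column only in the pairwise aln
            ops.append("C")
            j += 1

    def expand(row: str, keep: str) -> str:
        out = []
        p = 0
        for op in ops:
            if op in keep:
                out.append(row[p])
                p += 1
            else:
                out.append("-")
        assert p == len(row)
        return "".join(out)

    new_master = expand(master, "BM")
    new_rows = {org: expand(row, "BM") for org, row in rows.items()}
    new_rows[new_org] = expand(s_aln, "BC")
    return new_master, new_rows


def progressive_align_family(
    family: GeneFamily, s: ScoringScheme = ScoringScheme()
) -> AlignedGeneFamily:
    """Center-star progressive alignment of one gene family.

    The center is the member with the greatest summed pairwise score against
    all others (ties go to the earliest organism in the run order); every
    other member is merged in via its pairwise alignment to the center.
    """
    if len(family) == 0:
        raise ValueError(f"gene {family.gene_name}: cannot align an empty family")
    orgs = list(family.members)
    seqs = {org: family.members[org].sequence for org in orgs}
    if len(orgs) == 1:
        only = orgs[0]
        return AlignedGeneFamily(family.gene_name, {only: seqs[only]})

    totals = {org: 0.0 for org in orgs}
    for ia in range(len(orgs)):
        for ib in range(ia + 1, len(orgs)):
            sc = pairwise_score(seqs[orgs[ia]], seqs[orgs[ib]], s)
            totals[orgs[ia]] += sc
            totals[orgs[ib]] += sc
    center = orgs[0]
    for org in orgs[1:]:
        if totals[org] > totals[center]:
            center = org

    master = seqs[center]
    rows: dict[str, str] = {center: master}
    for org in orgs:
        if org == center:
            continue
        c_aln, s_aln, _ = pairwise_align_global(seqs[center], seqs[org], s)
        master, rows = _merge_once_a_gap(master, rows, c_aln, s_aln, org)

    ordered = {org: rows[org] for org in orgs}
    aligned = AlignedGeneFamily(family.gene_name, ordered)
    _validate_against_inputs(aligned, family)
    return aligned


def _validate_against_inputs(aligned: AlignedGeneFamily, family: GeneFamily) -> None:
    if set(aligned.members) != set(family.members):
        raise AlignmentError(
            f"gene {family.gene_name}: aligned member set differs from input"
        )
    for org, row in aligned.members.items():
        if row.replace("-", "") != family.members[org].sequence:
            raise AlignmentError(
                f"gene {family.gene_name}: member {org} does not ungap to its input"
            )


def _run_external(
    family: GeneFamily, engine_path: str, threads: int
) -> AlignedGeneFamily:
    with tempfile.TemporaryDirectory(prefix="phylocat_aln_") as tmp:
        in_path = Path(tmp) / f"{family.gene_name}.fasta"
        write_fasta(
            [(org, rec.sequence) for org, rec in family.members.items()], in_path
        )
        cmd = [engine_path, "--auto", "--thread", str(threads), str(in_path)]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True)
        except FileNotFoundError as exc:
            raise AlignmentError(
                f"external aligner {engine_path!r} not found; "
                f"install it or rerun with engine='builtin'"
            ) from exc
        if proc.returncode != 0:
            raise AlignmentError(
                f"gene {family.gene_name}: external aligner failed "
                f"(exit {proc.returncode}): {proc.stderr.strip()[-500:]}"
            )
        pairs = list(SimpleFastaParser(io.StringIO(proc.stdout)))
    members = {org: seq.upper() for org, seq in pairs}
    lengths = {len(row) for row in members.values()}
    if len(lengths) > 1:
        raise AlignmentError(
            f"gene {family.gene_name}: external aligner produced ragged rows"
        )
    ordered = {org: members[org] for org in family.members if org in members}
    aligned = AlignedGeneFamily(family.gene_name, ordered)
    _validate_against_inputs(aligned, family)
    return aligned


def align_family(
    family: GeneFamily,
    engine: str = "builtin",
    engine_path: str = "mafft",
    threads: int = 1,
    scoring: ScoringScheme = ScoringScheme(),
) -> AlignedGeneFamily:
    """Align one family with the chosen engine, validating the result.

    Singleton families skip alignment under either engine. External output
    is validated against the same invariants the built-in engine guarantees
    (rectangular rows, exact ungap round-trip, complete member set); a
    violation is a hard error naming the gene rather than silent corruption
    of the supermatrix.
    """
    if engine not in ("builtin", "external"):
        raise ValueError(f"unknown engine {engine!r}")
    if len(family) == 0:
        raise ValueError(f"gene {family.gene_name}: cannot align an empty family")
    alphabet = detect_alphabet(rec.sequence for rec in family.members.values())
    logger.info(
        "stage=align gene=%s members=%d alphabet=%s engine=%s",
        family.gene_name, len(family), alphabet,
        "none(singleton)" if len(family) == 1 else engine,
    )
    if len(family) == 1:
        org, rec = next(iter(family.members.items()))
        return AlignedGeneFamily(family.gene_name, {org: rec.sequence})
    if engine == "external":
        return _run_external(family, engine_path, threads)
    return progressive_align_family(family, scoring)


def align_families(
    families: Sequence[GeneFamily],
    engine: str = "builtin",
    engine_path: str = "mafft",
    threads: int = 1,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[AlignedGeneFamily]:
    """Align families, possibly concurrently; output order follows input.

    The external engine is I/O/subprocess-bound, so families are dispatched
    to a thread pool; results are collected in input order so reports and
    the supermatrix are independent of scheduling. The built-in engine is
    deterministic and single-threaded regardless of ``threads``.
    """
    if engine == "external" and threads > 1 and len(families) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            futures = [
                pool.submit(align_family, fam, engine, engine_path, 1, scoring)
                for fam in families
            ]
            return [f.result() for f in futures]
    return [
        align_family(fam, engine, engine_path, threads, scoring) for fam in families
    ]


def detect_alphabet(sequences: Iterable[str]) -> str:
    """Classify sequences as nucleotide or protein.

    Nucleotide if at least 90% of non-gap, non-missing residues fall in
    {A, C, G, T, U, N}; amino-acid alphabets fail that test quickly.
    """
    nuc = total = 0
    for seq in sequences:
        for ch in seq:
            if ch in "-?":
                continue
            total += 1
            if ch in _NUC_RESIDUES:
                nuc += 1
    if total == 0:
        return "nucleotide"
    return "nucleotide" if nuc / total >= 0.9 else "protein"
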