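"""Built-in alignment engine: pairwise optimality, center-star invariants,
and the external-engine contract."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylocat.aligner import (
    AlignedGeneFamily,
    AlignmentError,
    ScoringScheme,
    align_family,
    detect_alphabet,
    pairwise_align_global,
    pairwise_score,
    progressive_align_family,
)

from .conftest import make_family, random_dna

S = ScoringScheme()


def brute_force_best_score(a: str, b: str, s: ScoringScheme = S) -> float:
    """Enumerate every global alignment of a and b and return the best score.

    Exponential; only usable for short sequences, which is the point — it is
    independent of any dynamic-programming shortcut.
    """
    best = -math.inf

    def rec(i: int, j: int, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (s.match if a[i] == b[j] else s.mismatch))
        if i < len(a):
            rec(i + 1, j, score + s.gap)
        if j < len(b):
            rec(i, j + 1, score + s.gap)

    rec(0, 0, 0.0)
    return best


def greedy_left_align_score(a: str, b: str, s: ScoringScheme = S) -> float:
    """Naive baseline: pair positions left to right, pad the tail with gaps."""
    k = min(len(a), len(b))
    score = sum(s.match if a[i] == b[i] else s.mismatch for i in range(k))
    return score + s.gap * (len(a) + len(b) - 2 * k)


class TestPairwise:
    def test_identity_alignment(self):
        assert pairwise_align_global("ACGT", "ACGT", S) == ("ACGT", "ACGT", 4.0)

    def test_substitution_beats_two_gaps(self):
        a, b, score = pairwise_align_global("A", "G", S)
        assert (a, b, score) == ("A", "G", -1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align_global("", "ACGT", S)

    def test_score_matches_brute_force(self, rng):
        """DP optimum equals exhaustive enumeration on 220 short random pairs."""
        for _ in range(220):
            a = random_dna(rng, rng.randint(1, 6))
            b = random_dna(rng, rng.randint(1, 6))
            _, _, score = pairwise_align_global(a, b, S)
            assert score == brute_force_best_score(a, b, S)

    def test_alignment_scores_its_own_score(self, rng):
        """The returned aligned pair re-scores to the reported optimum."""
        for _ in range(100):
            a = random_dna(rng, rng.randint(1, 12))
            b = random_dna(rng, rng.randint(1, 12))
            ra, rb, score = pairwise_align_global(a, b, S)
            assert len(ra) == len(rb)
            assert ra.replace("-", "") == a and rb.replace("-", "") == b
            rescored = sum(
                S.gap if "-" in (x, y) else (S.match if x == y else S.mismatch)
                for x, y in zip(ra, rb)
            )
            assert rescored == score

    def test_beats_greedy_baseline(self, rng):
        for _ in range(200):
            a = random_dna(rng, rng.randint(1, 6))
            b = random_dna(rng, rng.randint(1, 6))
            _, _, score = pairwise_align_global(a, b, S)
            assert score >= greedy_left_align_score(a, b, S)

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=40),
        st.text(alphabet="ACGT", min_size=1, max_size=40),
    )
    def test_score_only_route_agrees_with_dp(self, a, b):
        """pairwise_score (Biopython global engine) and our DP optimize the
        same objective, so the two routes must agree exactly."""
        _, _, dp_score = pairwise_align_global(a, b, S)
        assert pairwise_score(a, b, S) == dp_score

    def test_deterministic_traceback(self, rng):
        for _ in range(50):
            a = random_dna(rng, rng.randint(1, 15))
            b = random_dna(rng, rng.randint(1, 15))
            assert pairwise_align_global(a, b, S) == pairwise_align_global(a, b, S)

    def test_nonint_scoring_scheme(self):
        s = ScoringScheme(match=1.5, mismatch=-0.5, gap=-1.25)
        ra, rb, score = pairwise_align_global("ACGTA", "AGTA", s)
        assert ra.replace("-", "") == "ACGTA" and rb.replace("-", "") == "AGTA"
        assert score == pytest.approx(pairwise_score("ACGTA", "AGTA", s))


class TestProgressive:
    def test_singleton_passthrough(self):
        aln = progressive_align_family(make_family("g", {"A": "ATG"}))
        assert aln.members == {"A": "ATG"} and aln.aligned_length == 3

    def test_identical_sequences_gap_free(self):
        fam = make_family("g", {o: "ATGCATGC" for o in "ABC"})
        aln = progressive_align_family(fam)
        assert aln.aligned_length == 8
        assert all("-" not in row for row in aln.members.values())

    def test_toy_three_way(self):
        fam = make_family("g", {"A": "ACGT", "B": "AGT", "C": "ACT"})
        aln = progressive_align_family(fam)
        assert aln.aligned_length == 4
        for org, row in aln.members.items():
            assert row.replace("-", "") == fam.members[org].sequence

    def test_invariants_on_random_families(self, rng):
        """Rectangularity + ungap round-trip + member order, random families."""
        for _ in range(25):
            base = random_dna(rng, rng.randint(10, 30))
            members = {}
            for i in range(rng.randint(2, 6)):
                seq = list(base)
                for _ in range(rng.randint(0, 4)):
                    pos = rng.randrange(len(seq))
                    op = rng.choice("sid")
                    if op == "s":
                        seq[pos] = rng.choice("ACGT")
                    elif op == "i":
                        seq.insert(pos, rng.choice("ACGT"))
                    elif len(seq) > 1:
                        del seq[pos]
                members[f"org{i}"] = "".join(seq)
            fam = make_family("g", members)
            aln = progressive_align_family(fam)
            lengths = {len(r) for r in aln.members.values()}
            assert lengths == {aln.aligned_length}
            assert list(aln.members) == list(fam.members)
            for org, row in aln.members.items():
                assert row.replace("-", "") == members[org]

    def test_byte_deterministic(self, rng):
        fam = make_family("g", {"A": "ACGTACGT", "B": "ACTTACG", "C": "AGGTACGTT"})
        assert (
            progressive_align_family(fam).members
            == progressive_align_family(fam).members
        )


class TestAlignFamily:
    def test_singleton_engine_independent(self):
        fam = make_family("g", {"A": "ATGATG"})
        builtin = align_family(fam, engine="builtin")
        external = align_family(fam, engine="external", engine_path="mafft")
        assert builtin.members == external.members == {"A": "ATGATG"}

    def test_identical_family_both_engines(self):
        fam = make_family("g", {f"o{i}": "ATGCCGTA" for i in range(5)})
        builtin = align_family(fam, engine="builtin")
        external = align_family(fam, engine="external")
        assert builtin.members == external.members
        assert builtin.aligned_length == 8

    def test_external_engine_round_trips(self, rng):
        base = random_dna(rng, 40)
        members = {
            f"o{i}": base[: rng.randint(30, 40)] for i in range(4)
        }
        fam = make_family("g", members)
        aln = align_family(fam, engine="external")
        for org, row in aln.members.items():
            assert row.replace("-", "") == members[org]

    def test_missing_executable_is_informative(self):
        fam = make_family("g", {"A": "ATG", "B": "ATC"})
        with pytest.raises(AlignmentError, match="builtin"):
            align_family(fam, engine="external", engine_path="/nonexistent/aln")

    def test_ragged_rows_rejected(self):
        with pytest.raises(AlignmentError):
            AlignedGeneFamily("g", {"A": "AC-G", "B": "ACG"})

    def test_all_gap_member_rejected(self):
        with pytest.raises(AlignmentError):
            AlignedGeneFamily("g", {"A": "----", "B": "ACGT"})


class TestDetectAlphabet:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT-N", "acgu".upper()], "nucleotide"),
            (["MKVLLIAGGEE", "MKVWWPPQQRR"], "protein"),
            (["??--"], "nucleotide"),  # no residues: harmless default
        ],
    )
    def test_classification(self, seqs, expected):
        assert detect_alphabet(seqs) == expected
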