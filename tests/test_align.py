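import numpy as np
import pytest

from agios.align import (
    Alignment,
    ScoringScheme,
    alignment_score,
    global_align,
    percent_identity,
)
from oracles import brute_force_global_score, nucleotide_score

NT = ScoringScheme.nucleotide_default()
AA = ScoringScheme.protein_default()


def random_seq(rng, alphabet, n):
    return "".join(rng.choice(list(alphabet), size=n))


class TestGlobalAlign:
    def test_identity_case(self):
        aln = global_align("ACGT", "ACGT", NT)
        assert aln.score == 20.0
        assert (aln.n_matches, aln.n_mismatches, aln.n_gap_columns) == (4, 0, 0)

    def test_single_deletion_matches_oracle(self):
        aln = global_align("ACGT", "ACT", NT)
        expected = brute_force_global_score(
            "ACGT", "ACT", nucleotide_score(), NT.gap_open, NT.gap_extend
        )
        assert aln.score == pytest.approx(expected)

    def test_self_alignment_properties(self, rng):
        x = random_seq(rng, "ACGT", 50)
        aln = global_align(x, x, NT)
        assert percent_identity(aln) == 100.0
        assert aln.n_gap_columns == 0
        assert aln.score == 5.0 * 50  # match score times length

    def test_rows_reproduce_inputs(self, rng):
        for _ in range(5):
            a = random_seq(rng, "ACGT", int(rng.integers(5, 60)))
            b = random_seq(rng, "ACGT", int(rng.integers(5, 60)))
            aln = global_align(a, b, NT)
            assert aln.row_a.replace("-", "") == a
            assert aln.row_b.replace("-", "") == b
            # no double-gap columns
            assert all(x != "-" or y != "-" for x, y in zip(aln.row_a, aln.row_b))

    def test_score_symmetry(self, rng):
        for _ in range(5):
            a = random_seq(rng, "ACGT", int(rng.integers(5, 40)))
            b = random_seq(rng, "ACGT", int(rng.integers(5, 40)))
            assert alignment_score(a, b, NT) == pytest.approx(alignment_score(b, a, NT))
            aln_ab, aln_ba = global_align(a, b, NT), global_align(b, a, NT)
            assert percent_identity(aln_ab) == pytest.approx(percent_identity(aln_ba))

    def test_oracle_sweep_short_pairs(self, rng):
        """DP score equals exhaustive enumeration on short random pairs."""
        score_fn = nucleotide_score()
        for _ in range(60):
            la, lb = rng.integers(1, 9, size=2)
            a = random_seq(rng, "ACGT", int(la))
            b = random_seq(rng, "ACGT", int(lb))
            got = alignment_score(a, b, NT)
            want = brute_force_global_score(a, b, score_fn, NT.gap_open, NT.gap_extend)
            assert got == pytest.approx(want), (a, b)

    def test_score_only_agrees_with_traceback_score(self, rng):
        for _ in range(10):
            a = random_seq(rng, "ACGT", int(rng.integers(3, 80)))
            b = random_seq(rng, "ACGT", int(rng.integers(3, 80)))
            assert alignment_score(a, b, NT) == pytest.approx(global_align(a, b, NT).score)

    def test_cross_check_against_biopython(self, rng):
        """Independent C implementation agrees on both scoring modes."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        for scheme, alphabet in ((NT, "ACGT"), (AA, "ACDEFGHIKLMNPQRSTVWY")):
            aligner = Align.PairwiseAligner()
            aligner.mode = "global"
            if scheme.mode == "nucleotide":
                m = substitution_matrices.Array("ACGT", dims=2)
                for x in "ACGT":
                    for y in "ACGT":
                        m[x, y] = scheme.match if x == y else scheme.mismatch
                aligner.substitution_matrix = m
            else:
                aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
            aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
            aligner.extend_gap_score = -scheme.gap_extend
            for _ in range(20):
                a = random_seq(rng, alphabet, int(rng.integers(5, 100)))
                b = random_seq(rng, alphabet, int(rng.integers(5, 100)))
                assert alignment_score(a, b, scheme) == pytest.approx(aligner.score(a, b))

    def test_deterministic_traceback(self, rng):
        a = random_seq(rng, "ACGT", 30)
        b = random_seq(rng, "ACGT", 25)
        first = global_align(a, b, NT)
        second = global_align(a, b, NT)
        assert (first.row_a, first.row_b) == (second.row_a, second.row_b)

    def test_substitution_monotonicity(self, rng):
        """Each fresh substitution away from a can only lower identity."""
        a = random_seq(rng, "ACGT", 60)
        b = list(a)
        prev = 100.0
        positions = rng.permutation(60)[:20]
        for pos in positions:
            choices = [c for c in "ACGT" if c != a[pos]]
            b[pos] = choices[int(rng.integers(0, 3))]
            ident = percent_identity(global_align(a, "".join(b), NT))
            assert ident <= prev + 1e-9
            prev = ident

    def test_errors(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT", NT)
        with pytest.raises(ValueError):
            alignment_score("MEV", "MEV", NT)  # E is no nucleotide code


class TestIdentityConventions:
    def test_formula_on_constructed_alignment(self):
        aln = Alignment("ACGTACG", "ACGTACC", 26.0, 6, 1, 0)
        assert percent_identity(aln) == pytest.approx(100 * 6 / 7)

    def test_terminal_gap_convention(self):
        # b can only match the tail block, so the gap run is terminal
        aln = global_align("AAAACCCC", "CCCC", NT)
        assert percent_identity(aln) == pytest.approx(50.0)
        assert percent_identity(aln, include_terminal_gaps=False) == pytest.approx(100.0)

    def test_ambiguous_bases_never_match(self):
        aln = global_align("ACGN", "ACGN", NT)
        assert aln.n_matches == 3
        assert aln.n_mismatches == 1
        assert percent_identity(aln) == pytest.approx(75.0)


class TestScoringScheme:
    def test_gap_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=0.5, gap_extend=2.0)

    def test_defaults(self):
        assert (NT.match, NT.mismatch, NT.gap_open, NT.gap_extend) == (5, -4, 10, 0.5)
        assert (AA.substitution_matrix, AA.gap_open, AA.gap_extend) == ("BLOSUM62", 11, 1)
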