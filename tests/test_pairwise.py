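from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    oracle_global_score,
    oracle_lcs_length,
    oracle_local_best_score,
)
from conftest import random_protein
from graphmsa import ProteinSequence, global_align, lcs_align, local_align_topk
from graphmsa.io import AMINO_ACIDS

short_protein = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=6)


class TestGlobalAlign:
    def test_identical_sequences_single_full_match(self, params):
        a, b = ProteinSequence("s1", "ACDE"), ProteinSequence("s2", "ACDE")
        res = global_align(a, b, params)
        assert res.score == sum(params.score(c, c) for c in "ACDE")
        assert res.identity == 1.0
        (m,) = res.matches
        assert (m.begin_a, m.begin_b, m.length) == (0, 0, 4)

    def test_empty_sequence_forces_all_gap(self, params):
        res = global_align(ProteinSequence("s1", "A"), ProteinSequence("s2", ""), params)
        assert res.matches == []
        assert res.score == -13 + 1 * -1
        assert res.identity == 0.0

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(a=short_protein, b=short_protein)
    def test_score_matches_enumeration_oracle(self, params, a, b):
        got = global_align(
            ProteinSequence("s1", a), ProteinSequence("s2", b), params
        ).score
        want = oracle_global_score(a, b, params.matrix, params.gap_open,
                                   params.gap_extend)
        assert got == want

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=short_protein, b=short_protein)
    def test_matches_are_consistent_with_score(self, params, a, b):
        """The reported blocks realize the optimal score when re-scored
        (substitutions from the blocks, affine gaps from the gap runs)."""
        pa, pb = ProteinSequence("s1", a), ProteinSequence("s2", b)
        res = global_align(pa, pb, params)
        pairs = [(i, j) for m in res.matches for i, j in m.pairs()]
        sub = sum(params.score(a[i], b[j]) for i, j in pairs)
        # reconstruct gap runs from the pair path
        gaps = []
        prev = (-1, -1)
        for i, j in pairs + [(len(a), len(b))]:
            di, dj = i - prev[0] - 1, j - prev[1] - 1
            if di:
                gaps.append(di)
            if dj:
                gaps.append(dj)
            prev = (i, j)
        gap_cost = sum(params.gap_open + L * params.gap_extend for L in gaps)
        assert sub + gap_cost == res.score


class TestLocalAlign:
    def test_identical_sequences_best_is_full_diagonal(self, params):
        a, b = ProteinSequence("s1", "WYKW"), ProteinSequence("s2", "WYKW")
        res = local_align_topk(a, b, params)
        assert res.score == global_align(a, b, params).score
        assert res.matches[0].length == 4

    def test_all_negative_scores_empty_result(self, params):
        res = local_align_topk(
            ProteinSequence("s1", "WWWW"), ProteinSequence("s2", "PPPP"), params
        )
        assert res.matches == [] and res.all_scores == []

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(a=short_protein, b=short_protein)
    def test_best_score_matches_substring_oracle(self, params, a, b):
        res = local_align_topk(
            ProteinSequence("s1", a), ProteinSequence("s2", b), params
        )
        want = oracle_local_best_score(a, b, params.matrix, params.gap_open,
                                       params.gap_extend)
        got = res.score if res.all_scores else 0.0
        assert got == want

    def test_declumped_scores_non_increasing_and_positive(self, params, rng):
        for _ in range(20):
            a = random_protein(rng, "s1", rng.randrange(4, 12))
            b = random_protein(rng, "s2", rng.randrange(4, 12))
            res = local_align_topk(a, b, params, k=4)
            assert all(s > 0 for s in res.all_scores)
            assert res.all_scores == sorted(res.all_scores, reverse=True)

    def test_repeated_motif_yields_overlapping_suboptimals(self, params):
        a = ProteinSequence("s1", "WYKWWYKW")
        b = ProteinSequence("s2", "WYKW")
        res = local_align_topk(a, b, params, k=4)
        assert len(res.all_scores) >= 2
        assert res.all_scores[0] >= res.all_scores[1] > 0


class TestLcs:
    def test_identical(self):
        res = lcs_align(ProteinSequence("s1", "ACD"), ProteinSequence("s2", "ACD"))
        assert res.score == 3
        assert [(m.begin_a, m.begin_b, m.length) for m in res.matches] == [(0, 0, 3)]

    def test_reversed_string_shares_one_letter(self):
        assert lcs_align(
            ProteinSequence("s1", "ACD"), ProteinSequence("s2", "DCA")
        ).score == 1

    def test_empty_input(self):
        res = lcs_align(ProteinSequence("s1", "ACDE"), ProteinSequence("s2", ""))
        assert res.score == 0 and res.matches == []

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(a=short_protein, b=short_protein)
    def test_length_matches_subsequence_enumeration(self, a, b):
        got = lcs_align(ProteinSequence("s1", a), ProteinSequence("s2", b)).score
        assert got == oracle_lcs_length(a, b)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=short_protein, b=short_protein)
    def test_symmetric_and_bounded(self, a, b):
        fwd = lcs_align(ProteinSequence("s1", a), ProteinSequence("s2", b)).score
        rev = lcs_align(ProteinSequence("s1", b), ProteinSequence("s2", a)).score
        assert fwd == rev <= min(len(a), len(b))
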