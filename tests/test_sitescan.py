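"""Sliding-window scanning: brute-force oracles, additivity, coordinate maps."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_matrix, random_sequence
from trimerfit.sitescan import (
    AMINO_ACIDS, OFFSETS, WINDOW, BindingSite, ScoreProfile, ScoringMatrix,
    window_scores, call_sites, count_sites_in_range, count_runs_in_range,
    rescore_variant,
)


def brute_force_scan(sequence, matrix, threshold):
    """Oracle: score every window by explicit lookups, then find threshold runs
    by scanning every center position independently."""
    L = len(sequence)
    scores = {}
    for center in range(7, L - 5):
        scores[center] = sum(
            matrix.lookup(sequence[center - 1 + off], off) for off in OFFSETS)
    sites = []
    centers = sorted(scores)
    i = 0
    while i < len(centers):
        if scores[centers[i]] <= threshold:
            j = i
            while j + 1 < len(centers) and scores[centers[j + 1]] <= threshold:
                j += 1
            run = centers[i:j + 1]
            sites.append((run[0], run[-1], min(scores[c] for c in run)))
            i = j + 1
        else:
            i += 1
    return scores, sites


class TestWindowScores:
    def test_zero_matrix(self, zero_matrix):
        profile = window_scores("A" * 20, zero_matrix)
        assert np.all(profile.scores == 0)
        assert list(profile.centers) == list(range(7, 15))

    def test_constant_matrix_sums_window(self, const_neg_matrix):
        profile = window_scores("ACDEFGHIKLMNPQRSTVWY", const_neg_matrix)
        assert np.all(profile.scores == -13.0)

    def test_single_entry_matrix(self, zero_matrix):
        df = zero_matrix.entries.copy()
        df.at["L", 0] = -7.0
        matrix = ScoringMatrix(df)
        profile = window_scores("AAAAAALAAAAAA", matrix)
        assert list(profile.centers) == [7]
        assert profile.scores[0] == -7.0

    def test_short_sequence_rejected(self, zero_matrix):
        with pytest.raises(ValueError, match="shorter than window"):
            window_scores("A" * 12, zero_matrix)

    def test_matrix_validation(self):
        df = pd.DataFrame(0.0, index=list(AMINO_ACIDS[:-1]), columns=list(OFFSETS))
        with pytest.raises(ValueError, match="missing residues"):
            ScoringMatrix(df)


class TestCallSites:
    def _profile(self, scores, start_center=7):
        centers = np.arange(start_center, start_center + len(scores))
        return ScoreProfile("x", centers, np.asarray(scores, dtype=float))

    def test_no_sites(self):
        assert call_sites(self._profile([0, -1, -4.9, 0])) == []

    def test_run_merging(self):
        sites = call_sites(self._profile([-4, -6, -6, -4]))
        assert sites == [BindingSite(8, 9, -6.0)]

    def test_threshold_boundary_inclusive(self):
        sites = call_sites(self._profile([0, -5.0, 0]))
        assert sites == [BindingSite(8, 8, -5.0)]

    def test_agrees_with_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            seq = random_sequence(rng, int(rng.integers(13, 60)))
            matrix = random_matrix(rng, low=-2.0, high=1.0)
            threshold = float(rng.uniform(-9, -3))
            profile = window_scores(seq, matrix)
            oracle_scores, oracle_sites = brute_force_scan(seq, matrix, threshold)
            assert profile.scores == pytest.approx(
                [oracle_scores[c] for c in profile.centers], abs=1e-9)
            got = [(s.start, s.end, s.min_score)
                   for s in call_sites(profile, threshold)]
            assert len(got) == len(oracle_sites)
            for g, o in zip(got, oracle_sites):
                assert g[:2] == o[:2]
                assert g[2] == pytest.approx(o[2], abs=1e-9)


class TestCounting:
    def test_zero_matrix_counts_nothing(self, zero_matrix):
        profile = window_scores("A" * 40, zero_matrix)
        assert count_sites_in_range(profile, (7, 34)) == 0

    def test_constant_matrix_counts_all_centers(self, const_neg_matrix):
        profile = window_scores("A" * 40, const_neg_matrix)
        assert count_sites_in_range(profile, (10, 19)) == 10

    def test_counts_by_rule(self):
        centers = np.arange(180, 211)
        scores = np.zeros(centers.size)
        for c in (182, 190, 205):
            scores[centers == c] = -6.0
        profile = ScoreProfile("x", centers, scores)
        assert count_sites_in_range(profile, (180, 200)) == 2
        assert count_sites_in_range(profile, (201, 214)) == 1

    def test_empty_overlap_warns_and_returns_zero(self, const_neg_matrix):
        profile = window_scores("A" * 20, const_neg_matrix)
        with pytest.warns(UserWarning):
            assert count_sites_in_range(profile, (100, 110)) == 0

    def test_run_counting(self):
        centers = np.arange(7, 17)
        scores = np.array([0, -6, -6, 0, -6, 0, 0, -6, -6, -6], dtype=float)
        profile = ScoreProfile("x", centers, scores)
        assert count_runs_in_range(profile, (7, 16)) == 3
        assert count_sites_in_range(profile, (7, 16)) == 6


class TestRescoreVariant:
    def test_identity_without_changes(self, const_neg_matrix):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        base = window_scores(seq, const_neg_matrix)
        var = rescore_variant(seq, [], const_neg_matrix)
        assert var.scores == pytest.approx(base.scores)
        assert list(var.centers) == list(base.centers)

    def test_same_residue_substitution_is_identity(self, zero_matrix):
        rng = np.random.default_rng(5)
        matrix = random_matrix(rng)
        seq = random_sequence(rng, 30)
        base = window_scores(seq, matrix)
        var = rescore_variant(seq, [(10, seq[9])], matrix)
        assert var.scores == pytest.approx(base.scores)

    def test_serine_substitution_linearity(self, zero_matrix):
        # toy matrix: S scores +2 and I/L/V score -2 at every offset, so a
        # triple I->S substitution raises each overlapping window by 12
        df = zero_matrix.entries.copy()
        df.loc["S"] = 2.0
        df.loc[["I", "L", "V"]] = -2.0
        matrix = ScoringMatrix(df)
        seq = "AAAAAAIAAIAAIAAAAAA"
        base = window_scores(seq, matrix)
        var = rescore_variant(seq, [(7, "S"), (10, "S"), (13, "S")], matrix)
        overlap = (base.centers >= 13 - 6) & (base.centers <= 7 + 6)
        assert np.all(var.scores[overlap] - base.scores[overlap] == 12.0)

    def test_additivity_of_single_substitution(self):
        rng = np.random.default_rng(6)
        matrix = random_matrix(rng)
        seq = random_sequence(rng, 40)
        pos = 20
        new = "W" if seq[pos - 1] != "W" else "Y"
        base = window_scores(seq, matrix)
        var = rescore_variant(seq, [(pos, new)], matrix)
        delta = var.scores - base.scores
        for c, d in zip(base.centers, delta):
            off = pos - c
            if -6 <= off <= 6:
                expected = matrix.lookup(new, off) - matrix.lookup(seq[pos - 1], off)
                assert d == pytest.approx(expected, abs=1e-9)
            else:
                assert d == pytest.approx(0.0, abs=1e-12)

    def test_deletion_keeps_original_numbering(self, const_neg_matrix):
        seq = "A" * 30
        var = rescore_variant(seq, [], const_neg_matrix, deletions=[(11, 14)])
        # 26 residues remain -> centers 7..20 in variant coordinates
        assert var.centers[0] == 7
        # positions past the excision map back to original numbering (+4)
        assert var.coordinate_map[11] == 15
        assert var.centers[-1] == 24  # variant center 20 -> original residue 24

    def test_out_of_range_substitution(self, zero_matrix):
        with pytest.raises(ValueError):
            rescore_variant("A" * 20, [(21, "S")], zero_matrix)


class TestReversalSymmetry:
    def test_holds_iff_matrix_offset_symmetric(self):
        rng = np.random.default_rng(9)
        seq = random_sequence(rng, 25)
        asym = random_matrix(rng)
        sym_df = (asym.entries.to_numpy() + asym.entries.to_numpy()[:, ::-1]) / 2
        sym = ScoringMatrix(pd.DataFrame(sym_df, index=list(AMINO_ACIDS),
                                         columns=list(OFFSETS)))
        fwd = window_scores(seq, sym).scores
        rev = window_scores(seq[::-1], sym).scores
        assert fwd == pytest.approx(rev[::-1])
        fwd_a = window_scores(seq, asym).scores
        rev_a = window_scores(seq[::-1], asym).scores
        assert not np.allclose(fwd_a, rev_a[::-1])
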