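import numpy as np
import pytest

import orthoplace as op
from orthoplace.errors import CalibrationError
from orthoplace.hmm import evalue_from_bits, position_weights, random_null_sequence
from orthoplace.msa import AMINO_ACIDS, BACKGROUND

from .oracles import enumerate_forward_bits


def _masked(rows, ids=None, occupancy=0.5):
    aln = op.FamilyAlignment(ids or [f"r{i}" for i in range(len(rows))], rows)
    aln.match_mask = op.select_match_columns(aln, occupancy)
    return aln


def _random_alignment(rng, n_rows, n_cols, gap_p=0.25, max_match=3):
    rows = [
        "".join(
            "-" if rng.random() < gap_p else AMINO_ACIDS[i]
            for i in rng.choice(20, n_cols)
        )
        for _ in range(n_rows)
    ]
    aln = op.FamilyAlignment([f"r{i}" for i in range(n_rows)], rows)
    mask = op.select_match_columns(aln, 0.5)
    if mask.sum() > max_match:
        mask = mask & (np.cumsum(mask) <= max_match)
    aln.match_mask = mask
    return aln


class TestMatchColumns:
    def test_occupancy_rule(self):
        aln = op.FamilyAlignment(
            ["a", "b", "c", "d"], ["AAAA", "AAA-", "A---", "A---"]
        )
        # occupancies: 1.0, 0.5, 0.5, 0.25; the 0.5 columns match at the boundary
        mask = op.select_match_columns(aln, 0.5)
        assert mask.tolist() == [True, True, True, False]
        mask = op.select_match_columns(aln, 0.75)
        assert mask.tolist() == [True, False, False, False]

    def test_all_gap_column_never_matches(self):
        aln = op.FamilyAlignment(["a", "b"], ["A-C", "A-C"])
        assert op.select_match_columns(aln, 0.5).tolist() == [True, False, True]

    def test_empty_mask_is_configuration_error(self):
        aln = op.FamilyAlignment(["a", "b"], ["A-", "-A"])
        with pytest.raises(op.ConfigurationError, match="occupancy"):
            op.select_match_columns(aln, 0.9)


class TestBuild:
    def test_single_row_viterbi_is_all_match(self, warm_kernels):
        aln = _masked(["ACD"], ids=["only"])
        hmm = op.build_profile_hmm(aln)
        bits, qspan, mspan = op.viterbi_bits(hmm, "ACD")
        assert qspan == (1, 3) and mspan == (1, 3)

    def test_large_alpha_converges_to_background(self, warm_kernels):
        aln = _masked(["ACD"])
        hmm = op.build_profile_hmm(aln, pseudocount_alpha=1e7)
        assert np.abs(hmm.match_emissions - BACKGROUND).max() < 1e-6

    def test_duplicate_rows_share_weight(self):
        one = op.build_profile_hmm(_masked(["ACDEF"]))
        two = op.build_profile_hmm(_masked(["ACDEF", "ACDEF"]))
        np.testing.assert_allclose(one.match_emissions, two.match_emissions)

    def test_unknown_row_id_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="zz"):
            op.build_profile_hmm(toy_alignment, ["s1", "zz"])

    def test_normalization(self, rng):
        """Every emission and per-source transition distribution sums to one."""
        for _ in range(10):
            aln = _random_alignment(rng, int(rng.integers(1, 5)), 8, max_match=8)
            hmm = op.build_profile_hmm(aln)
            np.testing.assert_allclose(hmm.match_emissions.sum(axis=1), 1.0)
            k = hmm.n_match
            for j in range(k):
                t = hmm.transitions[j]
                assert abs(t[[0, 1, 2]].sum() - 1) < 1e-9  # from M_j
                if 1 <= j <= k - 1:
                    assert abs(t[[3, 4, 5]].sum() - 1) < 1e-9  # from I_j
                if j >= 1:
                    assert abs(t[[6, 7, 8]].sum() - 1) < 1e-9  # from D_j

    def test_position_weights_henikoff(self):
        # two identical rows split weight; a divergent row gets more
        aln = _masked(["ACD", "ACD", "GHK"])
        w = position_weights(aln.encoded, aln.match_mask)
        assert w[0] == pytest.approx(w[1])
        assert w[2] > w[0]
        assert w.sum() == pytest.approx(1.0)


class TestScoring:
    def test_forward_matches_path_enumeration(self, rng, warm_kernels):
        """Forward score equals explicit sum over all state paths (<=3 states)."""
        for trial in range(12):
            aln = _random_alignment(rng, int(rng.integers(2, 4)), int(rng.integers(3, 6)))
            hmm = op.build_profile_hmm(aln)
            q = "".join(AMINO_ACIDS[i] for i in rng.choice(20, int(rng.integers(1, 4))))
            for mode in ("glocal", "local"):
                got = op.forward_bits(hmm, q, mode)
                want = enumerate_forward_bits(hmm, q, mode)
                assert got == pytest.approx(want, abs=1e-9)

    def test_forward_at_least_viterbi(self, rng, warm_kernels):
        for _ in range(15):
            aln = _random_alignment(rng, int(rng.integers(1, 5)), 10, max_match=6)
            hmm = op.build_profile_hmm(aln)
            q = "".join(AMINO_ACIDS[i] for i in rng.choice(20, int(rng.integers(2, 9))))
            for mode in ("glocal", "local"):
                fwd = op.forward_bits(hmm, q, mode)
                vit, _, _ = op.viterbi_bits(hmm, q, mode)
                assert fwd >= vit - 1e-9

    def test_background_model_scores_zero(self, warm_kernels):
        """Match emissions equal to the null with forced transitions -> 0 bits."""
        aln = _masked(["ACD"])
        hmm = op.build_profile_hmm(aln)
        hmm.match_emissions = np.tile(BACKGROUND, (hmm.n_match, 1))
        trans = np.zeros_like(hmm.transitions)
        trans[:, 0] = 1.0  # M->M always
        hmm.transitions = trans
        hmm._em_lo = None
        bits, _, _ = op.viterbi_bits(hmm, "WWW")
        assert bits == pytest.approx(0.0, abs=1e-9)

    def test_true_sequence_beats_permutations(self, rng, warm_kernels):
        seq = "".join(AMINO_ACIDS[i] for i in rng.choice(20, 40))
        hmm = op.build_profile_hmm(_masked([seq]))
        true_bits = op.forward_bits(hmm, seq)
        chars = np.array(list(seq))
        for _ in range(100):
            perm = "".join(chars[rng.permutation(len(chars))])
            assert true_bits >= op.forward_bits(hmm, perm)

    def test_unknown_residues_score_finite(self, warm_kernels):
        hmm = op.build_profile_hmm(_masked(["ACDEF"]))
        score = op.score_sequence(hmm, "XXXXX")
        assert np.isfinite(score.bit_score)

    def test_spans_and_coverage_bounds(self, sim_small, warm_kernels):
        families, _ = sim_small
        family = families[0]
        if family.alignment.match_mask is None:
            family.alignment.match_mask = op.select_match_columns(family.alignment)
        hmm = op.build_profile_hmm(family.alignment)
        q = family.sequences[family.alignment.row_ids[0]].residues
        score = op.score_sequence(hmm, q)
        assert 0.0 <= score.query_coverage <= 1.0
        assert 0.0 <= score.model_coverage <= 1.0
        assert 1 <= score.query_span[0] <= score.query_span[1] <= len(q)
        assert 1 <= score.model_span[0] <= score.model_span[1] <= hmm.n_match


class TestCalibration:
    @pytest.fixture()
    def calibrated(self, warm_kernels):
        rng = np.random.default_rng(3)
        seq = "".join(AMINO_ACIDS[i] for i in rng.choice(20, 30))
        hmm = op.build_profile_hmm(_masked([seq]))
        return op.calibrate_evalue(hmm, n_random=1000, seed=42, db_size=100)

    def test_median_null_evalue(self, calibrated):
        """E-value of the median null score is about half the database size."""
        rng = np.random.default_rng(7)
        scores = sorted(
            op.forward_bits(calibrated, random_null_sequence(rng, 30))
            for _ in range(301)
        )
        median = scores[150]
        ev = evalue_from_bits(calibrated, median)
        assert 0.8 * 50 <= ev <= 1.2 * 50

    def test_evalue_monotone_in_bits(self, calibrated):
        bits = np.linspace(-20, 60, 30)
        evs = [evalue_from_bits(calibrated, b) for b in bits]
        assert all(a >= b for a, b in zip(evs, evs[1:]))

    def test_same_seed_same_fit(self, warm_kernels):
        hmm1 = op.build_profile_hmm(_masked(["ACDEFGHIKLMNPQRST"]))
        hmm2 = op.build_profile_hmm(_masked(["ACDEFGHIKLMNPQRST"]))
        op.calibrate_evalue(hmm1, n_random=100, seed=9, db_size=10)
        op.calibrate_evalue(hmm2, n_random=100, seed=9, db_size=10)
        assert (hmm1.evd_mu, hmm1.evd_lambda) == (hmm2.evd_mu, hmm2.evd_lambda)

    def test_n_random_floor(self, warm_kernels):
        hmm = op.build_profile_hmm(_masked(["ACDEF"]))
        with pytest.raises(ValueError):
            op.calibrate_evalue(hmm, n_random=50, seed=1)

    def test_uncalibrated_evalue_raises(self):
        hmm = op.build_profile_hmm(_masked(["ACDEF"]))
        with pytest.raises(CalibrationError):
            evalue_from_bits(hmm, 10.0)


class TestSerialization:
    def test_json_round_trip(self, toy_alignment):
        hmm = op.build_profile_hmm(toy_alignment)
        op.calibrate_evalue(hmm, n_random=100, seed=1, db_size=5)
        again = op.ProfileHMM.from_json(hmm.to_json())
        assert again == hmm
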