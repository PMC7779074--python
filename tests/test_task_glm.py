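import numpy as np
import pytest

import cortflow as cf
from cortflow.task_glm import (
    ActivationResult,
    build_condition_regressors,
    build_fir_design,
    canonical_hrf,
    fir_regress,
    fit_activation_glm,
    group_activation_magnitude,
)
from conftest import make_design


def _ts(data, tr=1.0):
    return cf.ParcelTimeSeries(np.asarray(data, dtype=float), tr)


class TestCanonicalHrf:
    def test_zero_at_time_zero(self):
        assert canonical_hrf(0.5)[0] == 0.0

    def test_peak_near_five_seconds(self):
        # dense sampling: the double-gamma mode sits just under 5 s
        h = canonical_hrf(0.01)
        t_peak = np.argmax(h) * 0.01
        assert 4.5 < t_peak < 5.5

    def test_kernel_length(self):
        assert canonical_hrf(0.72, duration_s=32).size == int(np.ceil(32 / 0.72))

    def test_peak_scaled_to_one(self):
        assert np.max(canonical_hrf(0.5)) == pytest.approx(1.0)


class TestConditionRegressors:
    def test_absent_condition_not_included_and_unknown_rejected(self):
        d = make_design([(2, 3, "a")], tr_s=1.0, n_tr=30)
        with pytest.raises(ValueError, match="unknown condition"):
            d.block_intervals("zzz")

    def test_single_tr_event_equals_shifted_hrf(self):
        d = make_design([(5, 1, "a")], tr_s=1.0, n_tr=40)
        hrf = canonical_hrf(1.0)
        regs = build_condition_regressors(d, hrf)
        expected = np.zeros(40)
        expected[5 : 5 + hrf.size] = hrf[: 40 - 5]
        np.testing.assert_allclose(regs[:, 0], expected)

    def test_two_blocks_equal_sum_of_shifted_kernels(self):
        d = make_design([(2, 1, "a"), (20, 1, "a")], tr_s=1.0, n_tr=60)
        hrf = canonical_hrf(1.0)
        regs = build_condition_regressors(d, hrf)
        # direct summation oracle
        expected = np.zeros(60)
        for onset in (2, 20):
            n = min(hrf.size, 60 - onset)
            expected[onset : onset + n] += hrf[:n]
        np.testing.assert_allclose(regs[:, 0], expected, atol=1e-12)


class TestActivationGlm:
    def test_noiseless_beta_recovery(self, rng):
        d = make_design([(5, 5, "a"), (25, 5, "a")], tr_s=1.0, n_tr=60)
        regs = build_condition_regressors(d, canonical_hrf(1.0))
        ts = _ts(2.5 * regs[:, [0]])
        result = fit_activation_glm(ts, regs, d.conditions)
        assert result.betas[0, 0] == pytest.approx(2.5, abs=1e-10)

    def test_pure_noise_mean_beta_near_zero(self, rng):
        d = make_design([(5, 5, "a"), (25, 5, "a")], tr_s=1.0, n_tr=60)
        regs = build_condition_regressors(d, canonical_hrf(1.0))
        betas = [
            fit_activation_glm(_ts(rng.normal(size=(60, 1))), regs, d.conditions).betas[0, 0]
            for _ in range(200)
        ]
        assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas))

    def test_matches_pseudoinverse_oracle(self, rng):
        d = make_design([(3, 4, "a"), (15, 4, "b")], tr_s=1.0, n_tr=40)
        regs = build_condition_regressors(d, canonical_hrf(1.0))
        Y = rng.normal(size=(40, 5))
        result = fit_activation_glm(_ts(Y), regs, d.conditions)
        X = np.hstack([np.ones((40, 1)), regs])
        oracle = (np.linalg.pinv(X) @ Y)[1:].T
        np.testing.assert_allclose(result.betas, oracle, atol=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        d = make_design([(3, 4, "a")], tr_s=1.0, n_tr=40)
        regs = build_condition_regressors(d, canonical_hrf(1.0))
        dup = np.hstack([regs, regs])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_activation_glm(_ts(rng.normal(size=(40, 2))), dup, ["a", "a_copy"])


class TestGroupActivationMagnitude:
    def test_matches_hand_computed_t(self):
        # four subjects, one parcel, one condition: betas 1, 2, 3, 4
        betas = [1.0, 2.0, 3.0, 4.0]
        results = [ActivationResult(np.array([[b]]), ["c"], f"s{i}") for i, b in enumerate(betas)]
        out = group_activation_magnitude(results)
        expected_t = np.mean(betas) / (np.std(betas, ddof=1) / 2.0)
        assert out.values[0] == pytest.approx(abs(expected_t))

    def test_all_zero_betas_give_zero_magnitude(self):
        results = [ActivationResult(np.zeros((3, 2)), ["a", "b"], f"s{i}") for i in range(4)]
        out = group_activation_magnitude(results)
        np.testing.assert_allclose(out.values, 0.0)

    def test_sign_flip_invariance(self, rng):
        stack = rng.normal(size=(5, 4, 3))
        res_a = [ActivationResult(s, ["a", "b", "c"], "") for s in stack]
        flipped = stack.copy()
        flipped[:, :, 1] *= -1
        res_b = [ActivationResult(s, ["a", "b", "c"], "") for s in flipped]
        np.testing.assert_allclose(
            group_activation_magnitude(res_a).values, group_activation_magnitude(res_b).values
        )

    def test_zero_variance_nonzero_mean_flagged(self):
        results = [ActivationResult(np.array([[1.0]]), ["c"], "") for _ in range(4)]
        out = group_activation_magnitude(results)
        assert out.flagged[0]


class TestFirRegression:
    def test_block_triggered_average_vanishes_for_arbitrary_shape(self, rng):
        # evoked response deliberately NOT an HRF: sawtooth per block
        d = make_design([(10, 8, "a"), (40, 8, "a"), (70, 8, "a")], tr_s=1.0, n_tr=120)
        shape = np.concatenate([np.linspace(0, 1, 8), np.linspace(1, 0, 10)])
        signal = np.zeros(120)
        for onset in (10, 40, 70):
            signal[onset : onset + 18] += shape
        noise = rng.normal(size=120)
        residual = fir_regress(_ts((signal + noise)[:, None]), d, post_offset_lags=25)
        # block-triggered average of the residual
        trig = np.mean([residual.data[o : o + 18, 0] for o in (10, 40, 70)], axis=0)
        pre = np.mean([signal[o : o + 18] for o in (10, 40, 70)], axis=0)
        assert np.max(np.abs(trig)) < 1e-8 * np.max(np.abs(pre))

    def test_orthogonal_series_unchanged_up_to_demeaning(self, rng):
        d = make_design([(5, 3, "a")], tr_s=1.0, n_tr=200)
        F = build_fir_design(d, post_offset_lags=5)
        X = np.hstack([np.ones((200, 1)), F])
        y = rng.normal(size=200)
        y -= X @ np.linalg.pinv(X) @ y  # orthogonalize to the FIR space
        residual = fir_regress(_ts(y[:, None]), d, post_offset_lags=5)
        np.testing.assert_allclose(residual.data[:, 0], y, atol=1e-10)

    def test_default_post_offset_lag_is_25(self):
        d = make_design([(5, 4, "a")], tr_s=1.0, n_tr=100)
        F = build_fir_design(d)
        assert F.shape[1] == 4 + 25  # onset..offset plus 25 TRs

    def test_extra_regressors_also_projected_out(self, rng):
        d = make_design([(5, 4, "a")], tr_s=1.0, n_tr=100)
        extra = rng.normal(size=(100, 3))
        residual = fir_regress(_ts(rng.normal(size=(100, 2))), d, extra_regressors=extra)
        for j in range(3):
            c = np.corrcoef(residual.data.T, extra[:, j])[:-1, -1]
            assert np.max(np.abs(c)) < 1e-8
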