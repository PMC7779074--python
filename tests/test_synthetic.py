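import numpy as np
import pytest
from scipy.stats import spearmanr

import cortflow as cf
from cortflow.task_glm import build_condition_regressors, canonical_hrf


class TestGeometry:
    def test_zero_diagonal_and_symmetry(self):
        geom = cf.generate_geometry(3, seed=0)
        np.testing.assert_allclose(np.diag(geom.distance_matrix), 0.0)
        np.testing.assert_allclose(geom.distance_matrix, geom.distance_matrix.T)

    def test_seeded_determinism(self):
        a = cf.generate_geometry(360, seed=1)
        b = cf.generate_geometry(360, seed=1)
        assert np.array_equal(a.distance_matrix, b.distance_matrix)

    def test_great_circle_bound_exhaustive(self):
        geom = cf.generate_geometry(100, seed=2)
        # brute force over all pairs: arc distance on the unit sphere <= pi
        for i in range(100):
            for j in range(100):
                assert geom.distance_matrix[i, j] <= np.pi + 1e-12

    def test_triangle_inequality(self):
        geom = cf.generate_geometry(25, seed=3)
        D = geom.distance_matrix
        for i in range(25):
            for j in range(25):
                assert np.all(D[i, j] <= D[i] + D[j] + 1e-9)

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ValueError):
            cf.generate_geometry(2, seed=0)


class TestGroundTruth:
    def test_planted_correlations_near_targets(self):
        gt = cf.generate_ground_truth(360, 24, seed=0)
        assert 0.5 <= spearmanr(gt.hierarchy, gt.tau_true).statistic <= 0.7
        assert -0.7 <= spearmanr(gt.hierarchy, gt.myelin_true).statistic <= -0.5
        assert -0.7 <= spearmanr(gt.hierarchy, gt.mean_abs_amp()).statistic <= -0.5

    def test_noiseless_target_gives_exact_rank_correlation(self):
        cfg = cf.EffectConfig(
            rho_hierarchy_tau=1.0, rho_tau_amp=None, rho_tau_myelin=None, rho_myelin_amp=None
        )
        gt = cf.generate_ground_truth(180, 4, cfg, seed=5)
        assert spearmanr(gt.hierarchy, gt.tau_true).statistic == pytest.approx(1.0, abs=1e-9)

    def test_seeded_determinism(self):
        a = cf.generate_ground_truth(60, 4, seed=3)
        b = cf.generate_ground_truth(60, 4, seed=3)
        assert np.array_equal(a.tau_true, b.tau_true)
        assert np.array_equal(a.evoked_amp, b.evoked_amp)

    def test_infeasible_correlation_structure_rejected(self):
        # hierarchy strongly + correlated with both, which are strongly
        # anti-correlated with each other: not a valid correlation matrix
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = 0.9
        bad[1, 2] = bad[2, 1] = -0.9
        with pytest.raises(ValueError, match="positive semidefinite"):
            cf.generate_ground_truth(60, 4, cf.EffectConfig(target_matrix=bad), seed=0)

    def test_tau_positive_and_scale_in_unit_interval(self, ground_truth_small):
        gt = ground_truth_small
        assert np.all(gt.tau_true > 0)
        assert np.all(gt.task_coupling_scale > 0) and np.all(gt.task_coupling_scale <= 1)


class TestRestSimulation:
    def test_lag1_autocorrelation_matches_ar1(self):
        # tau = 1.44 s at TR 0.72 s: phi = exp(-0.5) ~ 0.6065
        cfg = cf.EffectConfig(tau_range_s=(1.44, 1.44), coupling_strength=0.0)
        gt = cf.generate_ground_truth(8, 2, cfg, seed=0)
        ts = cf.simulate_rest_timeseries(gt, 20000, 0.72, seed=1)
        for i in range(8):
            r1 = np.corrcoef(ts.data[:-1, i], ts.data[1:, i])[0, 1]
            assert r1 == pytest.approx(np.exp(-0.5), abs=0.03)

    def test_near_zero_tau_gives_white_noise(self):
        cfg = cf.EffectConfig(tau_range_s=(1e-4, 1e-4), coupling_strength=0.0)
        gt = cf.generate_ground_truth(8, 2, cfg, seed=0)
        ts = cf.simulate_rest_timeseries(gt, 5000, 0.72, seed=1)
        r1 = np.corrcoef(ts.data[:-1, 0], ts.data[1:, 0])[0, 1]
        assert abs(r1) < 0.05

    def test_zero_coupling_gives_near_zero_fc(self):
        cfg = cf.EffectConfig(coupling_strength=0.0)
        gt = cf.generate_ground_truth(20, 2, cfg, seed=0)
        ts = cf.simulate_rest_timeseries(gt, 10000, 0.72, seed=1)
        fc = np.corrcoef(ts.data.T)
        off = fc[np.triu_indices(20, 1)]
        assert abs(off.mean()) < 0.02

    def test_invalid_tau_rejected(self, ground_truth_small):
        gt = ground_truth_small
        bad = cf.GroundTruth(
            gt.hierarchy, np.zeros_like(gt.tau_true), gt.myelin_true, gt.evoked_amp,
            gt.rest_coupling, gt.task_coupling_scale, gt.geometry, gt.conditions,
            gt.driver_loadings, gt.coupling_strength, gt.config,
        )
        with pytest.raises(ValueError, match="tau"):
            cf.simulate_rest_timeseries(bad, 300, 0.72, seed=0)


class TestTaskSimulation:
    def test_zero_amplitudes_reproduce_rest_stream(self, ground_truth_small, design_small):
        gt = ground_truth_small
        null = cf.GroundTruth(
            gt.hierarchy, gt.tau_true, gt.myelin_true, np.zeros_like(gt.evoked_amp),
            gt.rest_coupling, np.ones(gt.n_parcels), gt.geometry, gt.conditions,
            gt.driver_loadings, gt.coupling_strength, gt.config,
        )
        task = cf.simulate_task_timeseries(null, design_small, seed=9)
        rest = cf.simulate_rest_timeseries(null, design_small.n_tr, design_small.tr_s, seed=9)
        np.testing.assert_allclose(task.data, rest.data, atol=1e-12)

    def test_noiseless_single_parcel_equals_hrf_boxcar(self, ground_truth_small, design_small):
        gt = ground_truth_small
        amp = np.zeros_like(gt.evoked_amp)
        amp[3, :] = 1.0
        one = cf.GroundTruth(
            gt.hierarchy, gt.tau_true, gt.myelin_true, amp,
            gt.rest_coupling, gt.task_coupling_scale, gt.geometry, gt.conditions,
            gt.driver_loadings, gt.coupling_strength, gt.config,
        )
        ts = cf.simulate_task_timeseries(one, design_small, seed=0, noise_scale=0.0)
        regs = build_condition_regressors(design_small, canonical_hrf(design_small.tr_s))
        np.testing.assert_allclose(ts.data[:, 3], regs.sum(axis=1), atol=1e-12)
        np.testing.assert_allclose(ts.data[:, :3], 0.0)


class TestBlockDesign:
    def test_basic_layout(self):
        d = cf.generate_block_design(1, 2, 10.0, 10.0, 0.72)
        assert d.n_blocks == 2
        assert (d.events["onset"] >= 0).all()

    def test_block_count_is_conditions_times_blocks(self):
        d = cf.generate_block_design(24, 3, 10.0, 5.0, 0.72)
        assert d.n_blocks == 24 * 3
        assert len(d.conditions) == 24

    def test_degenerate_block_length_rejected(self):
        with pytest.raises(ValueError):
            cf.generate_block_design(2, 2, 0.0, 10.0, 0.72)

    def test_run_too_short_rejected(self):
        with pytest.raises(ValueError, match="TRs"):
            cf.generate_block_design(4, 2, 10.0, 10.0, 0.72, run_n_tr=50)


class TestConfounds:
    def test_motion_has_six_columns(self):
        conf = cf.generate_confounds(100, seed=0)
        assert conf.motion.shape == (100, 6)

    def test_seeded_determinism(self):
        a = cf.generate_confounds(50, seed=4)
        b = cf.generate_confounds(50, seed=4)
        assert np.array_equal(a.wm_ts, b.wm_ts)

    def test_minimal_length_shape_contract(self):
        conf = cf.generate_confounds(10, seed=0)
        assert conf.motion.shape[0] == 10
        assert conf.wm_ts.shape[0] == 10
        assert conf.ventricle_ts.shape[0] == 10

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cf.generate_confounds(5, seed=0)
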