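import numpy as np
import pytest

from lvmar.models import (MARParameters, SingularMatrixError, Trajectory,
                          mar_steady_state, simulate_mar)
from lvmar.smoothing import Dataset
from lvmar.mar_inference import (back_transform, fit_mar, predict_mar,
                                 prediction_interval, prepare_transform)


def dataset_from(traj: Trajectory) -> Dataset:
    return Dataset(times=traj.times, values=traj.values, species=traj.species)


class TestPrepareTransform:
    def test_all_off_is_replicate_average(self):
        d = Dataset(times=[0.0, 1.0, 0.0, 1.0], values=[1.0, 2.0, 3.0, 4.0],
                    replicate=[0, 0, 1, 1])
        out, record = prepare_transform(d)
        np.testing.assert_allclose(out.values[:, 0], [2.0, 3.0])
        assert not record.log_applied and not record.zscore_applied

    def test_zeros_replaced_before_log(self):
        d = Dataset(times=[0.0, 1.0, 2.0], values=[0.0, 1.0, np.e])
        out, record = prepare_transform(d, log=True)
        assert out.values[0, 0] == pytest.approx(np.log(1e-5))
        assert out.values[2, 0] == pytest.approx(1.0)
        assert record.log_applied

    def test_negative_data_with_log_rejected(self):
        d = Dataset(times=[0.0, 1.0], values=[-1.0, 2.0])
        with pytest.raises(ValueError, match="negative"):
            prepare_transform(d, log=True)

    def test_zscore_standardizes_columns(self):
        rng = np.random.default_rng(0)
        d = Dataset(times=np.arange(20.0), values=rng.uniform(1, 5, (20, 3)))
        out, record = prepare_transform(d, zscore=True)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-10)
        assert record.zscore_applied

    def test_round_trip_restores_positive_data(self):
        rng = np.random.default_rng(1)
        d = Dataset(times=np.arange(10.0), values=rng.uniform(0.5, 4, (10, 2)))
        out, record = prepare_transform(d, log=True, zscore=True)
        traj = Trajectory(times=out.times, values=out.values)
        back = back_transform(traj, record)
        np.testing.assert_allclose(back.values, d.values, atol=1e-10)


class TestFitMar:
    def test_exact_recovery_on_deterministic_recursion(self, mar_benchmark):
        p = mar_benchmark.mar_params
        clean = MARParameters(p.intercepts, p.transition)  # delta = 0
        traj = simulate_mar(clean, mar_benchmark.x0, 30, deterministic=True)
        est = fit_mar(dataset_from(traj))
        np.testing.assert_allclose(est.intercepts, p.intercepts, atol=1e-10)
        np.testing.assert_allclose(est.transition, p.transition, atol=1e-10)
        assert np.max(np.abs(est.process_covariance)) < 1e-20

    def test_constant_series_is_collinear(self):
        d = Dataset(times=np.arange(10.0), values=np.full(10, 2.0))
        with pytest.raises(SingularMatrixError, match="collinear"):
            fit_mar(d)

    def test_too_few_pairs_rejected(self):
        d = Dataset(times=np.arange(4.0), values=np.arange(4.0).reshape(-1, 1)
                    * np.ones((1, 3)) + [[0, 1, 2]])
        with pytest.raises(ValueError, match="consecutive-pair"):
            fit_mar(d)

    def test_cls_consistency_one_species(self):
        # T = 500 simulation: estimates within 3 regression SEs of the truth
        p = MARParameters(np.array([1.0]), np.array([[0.5]]),
                          np.array([[0.01]]))
        traj = simulate_mar(p, [2.0], 500, seed=7)
        est = fit_mar(dataset_from(traj))
        x = traj.values[:-1, 0]
        design = np.column_stack([np.ones(x.size), x])
        cov = np.linalg.inv(design.T @ design) * est.process_covariance[0, 0]
        se = np.sqrt(np.diag(cov))
        assert abs(est.intercepts[0] - 1.0) < 3 * se[0]
        assert abs(est.transition[0, 0] - 0.5) < 3 * se[1]
        assert est.process_covariance[0, 0] == pytest.approx(0.01, rel=0.3)

    def test_unbiasedness_over_replicates(self):
        # mean CLS estimate over 200 seeded T=500 runs sits on the truth
        alpha = np.array([0.5, 0.2])
        beta = np.array([[0.6, 0.1], [-0.2, 0.5]])
        p = MARParameters(alpha, beta, 0.01 * np.eye(2))
        alphas, betas = [], []
        for r in range(200):
            traj = simulate_mar(p, [1.0, 1.0], 500, seed=20_000 + r)
            est = fit_mar(dataset_from(traj))
            alphas.append(est.intercepts)
            betas.append(est.transition)
        np.testing.assert_allclose(np.mean(alphas, axis=0), alpha, atol=0.01)
        np.testing.assert_allclose(np.mean(betas, axis=0), beta, atol=0.01)

    def test_gaps_contribute_no_pairs(self, mar_benchmark):
        p = mar_benchmark.mar_params
        traj = simulate_mar(p, mar_benchmark.x0, 40, seed=3)
        full = dataset_from(traj)
        keep = np.setdiff1d(np.arange(41), [5, 6, 20])
        gappy = Dataset(times=traj.times[keep], values=traj.values[keep])
        est = fit_mar(gappy)  # must still fit from the remaining pairs
        assert est.transition.shape == (4, 4)


class TestPredictMar:
    def test_free_run_reproduces_deterministic_training_data(self, mar_benchmark):
        p = mar_benchmark.mar_params
        clean = MARParameters(p.intercepts, p.transition)
        traj = simulate_mar(clean, mar_benchmark.x0, 25, deterministic=True)
        pred = predict_mar(clean, dataset_from(traj), mode="free_run")
        np.testing.assert_allclose(pred.values, traj.values, atol=1e-10)

    def test_free_run_converges_to_fixed_point(self):
        p = MARParameters(np.array([1.0, 0.5]),
                          np.array([[0.4, 0.1], [0.0, 0.3]]))
        start = Dataset(times=np.arange(200.0),
                        values=np.zeros((200, 2)) + [5.0, 5.0])
        pred = predict_mar(p, start, mode="free_run")
        np.testing.assert_allclose(pred.values[-1], mar_steady_state(p),
                                   atol=1e-10)

    def test_one_step_zero_residuals_on_noise_free_data(self, mar_benchmark):
        p = mar_benchmark.mar_params
        clean = MARParameters(p.intercepts, p.transition)
        traj = simulate_mar(clean, mar_benchmark.x0, 25, deterministic=True)
        pred = predict_mar(clean, dataset_from(traj), mode="one_step")
        np.testing.assert_allclose(pred.values[1:], traj.values[1:], atol=1e-10)


class TestBackTransform:
    def test_identity_record(self):
        traj = Trajectory(times=[0.0, 1.0], values=np.array([[1.0], [2.0]]))
        from lvmar.mar_inference import TransformRecord
        out = back_transform(traj, TransformRecord())
        np.testing.assert_array_equal(out.values, traj.values)

    def test_log_zero_maps_to_one(self):
        traj = Trajectory(times=[0.0, 1.0], values=np.array([[0.0], [1.0]]))
        from lvmar.mar_inference import TransformRecord
        out = back_transform(traj, TransformRecord(log_applied=True))
        assert out.values[0, 0] == pytest.approx(1.0)

    def test_incomplete_record_rejected(self):
        traj = Trajectory(times=[0.0, 1.0], values=np.array([[0.0], [1.0]]))
        from lvmar.mar_inference import TransformRecord
        with pytest.raises(ValueError, match="incomplete"):
            back_transform(traj, TransformRecord(zscore_applied=True))


class TestPredictionInterval:
    def test_zero_covariance_zero_width(self, mar_benchmark):
        p = mar_benchmark.mar_params
        clean = MARParameters(p.intercepts, p.transition)
        traj = simulate_mar(clean, mar_benchmark.x0, 10, deterministic=True)
        lo, hi = prediction_interval(clean, traj, 0.95)
        np.testing.assert_array_equal(lo, hi)

    def test_width_monotone_in_noise_scale(self):
        traj = Trajectory(times=np.arange(10.0), values=np.zeros((10, 1)))
        widths = []
        for scale in (0.5, 1.0, 2.0):
            p = MARParameters(np.zeros(1), 0.5 * np.eye(1),
                              scale * np.eye(1))
            lo, hi = prediction_interval(p, traj, 0.9)
            widths.append(hi - lo)
        assert np.all(widths[0] <= widths[1] + 1e-12)
        assert np.all(widths[1] <= widths[2] + 1e-12)

    def test_beta_zero_half_width_is_z_sigma(self):
        sigma = 0.3
        p = MARParameters(np.zeros(1), np.zeros((1, 1)),
                          np.array([[sigma ** 2]]))
        traj = Trajectory(times=np.arange(6.0), values=np.zeros((6, 1)))
        lo, hi = prediction_interval(p, traj, 0.95)
        half = (hi - lo)[1:, 0] / 2
        np.testing.assert_allclose(half, 1.959963985 * sigma, rtol=1e-6)

    def test_bad_level_rejected(self, mar_benchmark):
        traj = Trajectory(times=[0.0, 1.0], values=np.zeros((2, 4)))
        with pytest.raises(ValueError, match="level"):
            prediction_interval(mar_benchmark.mar_params, traj, 1.5)


class TestZScoreEquivariance:
    def test_fit_in_zscored_space_matches_raw_free_run(self, mar_benchmark):
        # fitting after z-scoring then back-transforming the free run equals
        # fitting the raw series directly (noise-free data)
        p = mar_benchmark.mar_params
        clean = MARParameters(p.intercepts, p.transition)
        traj = simulate_mar(clean, mar_benchmark.x0, 30, deterministic=True)
        raw = dataset_from(traj)

        direct = predict_mar(fit_mar(raw), raw, mode="free_run")

        scaled, record = prepare_transform(raw, zscore=True)
        est = fit_mar(scaled)
        back = back_transform(predict_mar(est, scaled, mode="free_run"),
                              record)
        np.testing.assert_allclose(back.values, direct.values, atol=1e-8)
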