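"""Log-quadratic fitting, prediction, shape calibration and monotone repair."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from u5logquad import (
    AgeGrid,
    AgeSchedule,
    CalibrationError,
    FitError,
    LogQuadFit,
    calibrate_k,
    enforce_monotone,
    fit_logquad,
    predict_pattern,
)

from conftest import make_set


def ols_normal_equations(X, y):
    """Independent oracle: explicit solve of the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFit:
    def test_identity_schedule_fits_exactly(self, identity_set):
        fit = fit_logquad(identity_set, cause="all", degree=2)
        for lab in identity_set.grid.labels:
            a, b, c = fit.coeffs[lab]
            assert abs(a) < 1e-10 and abs(b - 1.0) < 1e-10 and abs(c) < 1e-10
            assert fit.v[lab] == 0.0
            assert fit.sigma[lab] == 0.0

    @pytest.mark.parametrize("degree", [1, 2])
    def test_ols_matches_normal_equation_oracle(self, grid, degree):
        rng = np.random.default_rng(7)
        q5s = rng.uniform(0.004, 0.06, 8)
        rows = []
        for q5 in q5s:
            frac = np.sort(rng.uniform(0.1, 0.95, 5))
            rows.append(list(frac * q5) + [q5])
        lts = make_set(rows, grid=grid)
        fit = fit_logquad(lts, cause="all", degree=degree)
        L = np.log(q5s)
        cols = [np.ones_like(L), L] + ([L**2] if degree == 2 else [])
        X = np.column_stack(cols)
        for j, lab in enumerate(grid.labels):
            y = np.log([r.q[lab] for r in lts.records])
            beta = ols_normal_equations(X, y)
            got = np.array(fit.coeffs[lab][: degree + 1])
            assert np.allclose(got, beta, atol=1e-8)

    def test_ols_matches_statsmodels(self, grid):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        q5s = rng.uniform(0.004, 0.06, 9)
        rows = [list(np.sort(rng.uniform(0.1, 0.95, 5)) * q5) + [q5] for q5 in q5s]
        lts = make_set(rows, grid=grid)
        fit = fit_logquad(lts, cause="all", degree=2)
        L = np.log(q5s)
        X = np.column_stack([np.ones_like(L), L, L**2])
        lab = grid.labels[2]
        res = sm.OLS(np.log([r.q[lab] for r in lts.records]), X).fit()
        assert np.allclose(fit.coeffs[lab], res.params, atol=1e-8)

    def test_rank1_recovery_of_v_and_k(self, rank1_set, rank1_truth, rank1_fit):
        _, _, ks = rank1_set
        a, b, v = rank1_truth
        fit = rank1_fit
        assert np.allclose(fit.v_vector(), v, atol=1e-8)
        got_k = [fit.training_k[r.key] for r in rank1_set[0].records]
        assert np.allclose(got_k, ks, atol=1e-8)
        assert np.allclose(fit.coeff_arrays()[0], a, atol=1e-8)
        assert np.allclose(fit.coeff_arrays()[1], b, atol=1e-8)
        assert np.all(fit.sigma_vector() == 0.0)

    def test_v_unit_norm_and_sign_convention(self, pneumonia_fit):
        v = pneumonia_fit.v_vector()
        assert abs(np.linalg.norm(v) - 1.0) < 1e-10
        assert v[0] >= 0.0

    def test_angular_error_of_v_decreases_with_noise(self, grid, rank1_truth):
        a, b, v = rank1_truth
        rng = np.random.default_rng(3)
        n = 60
        q5s = rng.uniform(0.004, 0.05, n)
        ks = rng.standard_normal(n)
        Z = rng.standard_normal((n, 6))
        Z[:, -1] = 0.0  # terminal age exact, as in the model
        angles = []
        for sigma in (0.2, 0.05, 0.01):
            rows = [
                np.exp(a + b * np.log(q5) + v * k + sigma * z)
                for q5, k, z in zip(q5s, ks, Z)
            ]
            rows = [np.concatenate([r[:-1], [q5]]) for r, q5 in zip(rows, q5s)]
            fit = fit_logquad(make_set(rows, grid=grid), cause="all", degree=1)
            vhat = fit.v_vector()
            angles.append(np.arccos(np.clip(abs(v @ vhat), 0, 1)))
        assert angles[0] > angles[1] > angles[2]

    def test_zero_cells_excluded_from_ols_and_svd(self, grid):
        rng = np.random.default_rng(5)
        q5s = rng.uniform(0.01, 0.05, 8)
        rows = [list(np.sort(rng.uniform(0.2, 0.95, 5)) * q5) + [q5] for q5 in q5s]
        rows[0][0] = 0.0  # one zero cell at the youngest age
        lts = make_set(rows, grid=grid)
        fit = fit_logquad(lts, cause="all", degree=2)
        assert fit.n_fit["0-6d"] == 7
        assert fit.n_fit["0-27d"] == 8
        # the zero-cell record is complete-case-excluded from training_k
        assert len(fit.training_k) == 7

    def test_preconditions_enforced(self, grid):
        tiny = make_set([[0.002, 0.004, 0.006, 0.008, 0.009, 0.010]] * 3, grid=grid)
        with pytest.raises(FitError):
            fit_logquad(tiny, cause="all", degree=2)
        with pytest.raises(FitError):
            fit_logquad(tiny, cause="missing-cause")

    def test_serialization_round_trip_exact(self, pneumonia_fit):
        again = LogQuadFit.from_json(pneumonia_fit.to_json())
        assert again.coeffs == pneumonia_fit.coeffs
        assert again.v == pneumonia_fit.v
        assert again.sigma == pneumonia_fit.sigma
        assert again.training_k == pneumonia_fit.training_k
        assert again.grid == pneumonia_fit.grid


class TestPredict:
    def test_identity_fit_predicts_flat_schedule(self, identity_set):
        fit = fit_logquad(identity_set, cause="all", degree=2)
        sched = predict_pattern(fit, 0.01, k=0.0)
        assert np.allclose(sched.q_vector(), 0.01, atol=1e-12)

    def test_in_sample_round_trip_noise_free(self, rank1_set, rank1_fit):
        lts, q5s, ks = rank1_set
        for rec, q5, k in zip(lts.records, q5s, ks):
            sched = predict_pattern(rank1_fit, q5, k=k)
            assert np.allclose(sched.q_vector(), rec.q_vector(lts.grid), atol=1e-8)

    def test_k_enters_linearly_through_v(self, rank1_fit):
        s0 = predict_pattern(rank1_fit, 0.02, k=0.0)
        s1 = predict_pattern(rank1_fit, 0.02, k=1.0)
        assert not s0.repaired and not s1.repaired
        dlog = np.log(s1.q_vector()[:-1]) - np.log(s0.q_vector()[:-1])
        assert np.allclose(dlog, rank1_fit.v_vector()[:-1], atol=1e-10)

    def test_terminal_pinned_to_q5(self, pneumonia_fit):
        for q5 in (0.0015, 0.004, 0.02, 0.039):
            sched = predict_pattern(pneumonia_fit, q5, k=0.7)
            assert sched.q["0-59m"] == q5

    def test_invalid_q5_rejected(self, pneumonia_fit):
        for q5 in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                predict_pattern(pneumonia_fit, q5)


class TestCalibrate:
    def test_zero_residual_anchor_gives_zero_k(self, pneumonia_fit):
        base = predict_pattern(pneumonia_fit, 0.01, k=0.0)
        assert "0-27d" not in base.repaired
        k = calibrate_k(pneumonia_fit, 0.01, "0-27d", base.q["0-27d"])
        assert abs(k) < 1e-10

    @pytest.mark.parametrize("k_star", [-2.0, -0.5, 0.0, 0.5, 2.0, 1.7])
    def test_round_trip_inversion(self, pneumonia_fit, k_star):
        sched = predict_pattern(pneumonia_fit, 0.008, k=k_star)
        assert "0-27d" not in sched.repaired
        k = calibrate_k(pneumonia_fit, 0.008, "0-27d", sched.q["0-27d"])
        assert abs(k - k_star) < 1e-10

    def test_anchored_prediction_is_exact(self, pneumonia_fit):
        rng = np.random.default_rng(17)
        for _ in range(50):
            q5 = rng.uniform(0.003, 0.039)
            q_anchor = q5 * rng.uniform(0.02, 0.3)
            k = calibrate_k(pneumonia_fit, q5, "0-27d", q_anchor)
            sched = predict_pattern(pneumonia_fit, q5, k=k)
            if "0-27d" not in sched.repaired:
                assert abs(sched.q["0-27d"] - q_anchor) < 1e-12 * q_anchor + 1e-15

    def test_zero_v_raises_calibration_error(self, identity_set):
        fit = fit_logquad(identity_set, cause="all", degree=2)
        with pytest.raises(CalibrationError):
            calibrate_k(fit, 0.01, "0-27d", 0.005)

    def test_zero_anchor_warns_and_falls_back(self, pneumonia_fit):
        with pytest.warns(UserWarning, match="k = 0"):
            k = calibrate_k(pneumonia_fit, 0.01, "0-27d", 0.0)
        assert k == 0.0


class TestEnforceMonotone:
    def _sched(self, grid, q):
        return AgeSchedule(
            grid=grid, cause="all", q5=q[-1], k=0.0, q=dict(zip(grid.labels, q))
        )

    def test_monotone_schedule_unchanged(self, grid):
        q = [0.002, 0.004, 0.006, 0.008, 0.009, 0.010]
        out = enforce_monotone(self._sched(grid, q))
        assert out.q == dict(zip(grid.labels, q))
        assert out.repaired == set()

    def test_single_violation_capped_by_elder(self, grid):
        q = [0.002, 0.004, 0.006, 0.0080, 0.0079, 0.0090]
        out = enforce_monotone(self._sched(grid, q))
        assert out.q["0-11m"] == 0.0079
        assert out.repaired == {"0-11m"}

    def test_strictly_decreasing_collapses_to_terminal(self, grid):
        q = [0.010, 0.008, 0.006, 0.004, 0.003, 0.002]
        out = enforce_monotone(self._sched(grid, q))
        assert all(val == 0.002 for val in out.q.values())

    @settings(derandomize=True, max_examples=60)
    @given(
        qs=st.lists(
            st.floats(min_value=1e-6, max_value=0.9, allow_nan=False), min_size=6, max_size=6
        )
    )
    def test_matches_cumulative_min_oracle(self, qs):
        grid = AgeGrid()
        out = enforce_monotone(self._sched(grid, qs))
        oracle = np.minimum.accumulate(np.array(qs)[::-1])[::-1]
        assert np.array_equal(out.q_vector(), oracle)
        # idempotent and never increasing
        again = enforce_monotone(out)
        assert again.q == out.q
        assert np.all(out.q_vector() <= np.array(qs))
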