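"""Kernel, GP fitting/prediction, grids, MLE, LOOCV, variogram."""

import math

import numpy as np
import pytest

from paleomob.field_gpr import (
    GridSpec,
    KernelParams,
    SingularCovarianceError,
    SpaceTimePoint,
    empirical_variogram,
    fit_gp,
    gp_predict,
    kernel_value,
    log_marginal_likelihood,
    loocv_score,
    mle_kernel,
    predict_field_grid,
    _cov,
)

from conftest import brute_force_gp_predict, random_kernel, random_training_set


P = KernelParams(theta_x=1e10, theta_y=1e10, theta_t=1e5, tau2=1.0, eta=0.1)


class TestKernelValue:
    def test_zero_distance_is_sill_plus_nugget(self):
        a = SpaceTimePoint(5.0, 5.0, -100.0)
        assert kernel_value(a, a, P) == pytest.approx(1.1)

    def test_one_lengthscale_separation_gives_exp_minus_one(self):
        p = KernelParams(theta_x=4e10, theta_y=1e10, theta_t=1e5, tau2=1.0, eta=0.0)
        a = SpaceTimePoint(0.0, 0.0, 0.0)
        b = SpaceTimePoint(math.sqrt(4e10), 0.0, 0.0)
        assert kernel_value(a, b, p) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_covariance_vanishes_at_large_separation(self):
        a = SpaceTimePoint(0.0, 0.0, 0.0)
        b = SpaceTimePoint(0.0, 0.0, 1e9)
        assert kernel_value(a, b, P) < 1e-300 or kernel_value(a, b, P) == 0.0

    def test_nugget_only_on_exact_equality(self):
        a = SpaceTimePoint(0.0, 0.0, 0.0)
        b = SpaceTimePoint(1e-9, 0.0, 0.0)
        assert kernel_value(a, b, P) < kernel_value(a, a, P)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            SpaceTimePoint(math.nan, 0.0, 0.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(theta_x=-1, theta_y=1, theta_t=1, tau2=1)
        with pytest.raises(ValueError):
            KernelParams(theta_x=1, theta_y=1, theta_t=1, tau2=1, eta=-0.1)

    def test_lengthscale_round_trip(self):
        p = KernelParams.from_lengthscales(250.0, 300.0, 667.0, 1.5, 0.2)
        assert p.lengthscales == pytest.approx((250.0, 300.0, 667.0))
        assert p.theta_x == pytest.approx((250e3) ** 2)


class TestFitPredict:
    def test_two_point_covariance_matches_kernel_calls(self):
        pts = [SpaceTimePoint(0, 0, 0), SpaceTimePoint(1e4, 2e4, -50)]
        model = fit_gp(pts, np.array([[0.3], [0.7]]), P)
        K = model.chol[0] @ model.chol[0].T
        expected = np.array(
            [[kernel_value(a, b, P) for b in pts] for a in pts]
        )
        np.testing.assert_allclose(K, expected, atol=1e-8)

    def test_consistent_duplicate_with_zero_nugget_fits(self):
        p0 = KernelParams(theta_x=1e10, theta_y=1e10, theta_t=1e5, tau2=1.0, eta=0.0)
        pts = [SpaceTimePoint(0, 0, 0), SpaceTimePoint(0, 0, 0), SpaceTimePoint(1e5, 0, 0)]
        model = fit_gp(pts, np.array([[0.5], [0.5], [0.2]]), p0)
        assert model.n_components == 1

    def test_conflicting_duplicate_with_zero_nugget_errors(self):
        p0 = KernelParams(theta_x=1e10, theta_y=1e10, theta_t=1e5, tau2=1.0, eta=0.0)
        pts = [SpaceTimePoint(0, 0, 0), SpaceTimePoint(0, 0, 0)]
        with pytest.raises(SingularCovarianceError, match="nugget"):
            fit_gp(pts, np.array([[0.0], [1.0]]), p0)

    def test_noiseless_interpolation_at_training_point(self):
        p0 = KernelParams(theta_x=1e10, theta_y=1e10, theta_t=1e5, tau2=1.0, eta=0.0)
        pts = [SpaceTimePoint(0, 0, 0), SpaceTimePoint(5e4, 5e4, 100)]
        model = fit_gp(pts, np.array([[0.4], [0.9]]), p0)
        mean, sd = gp_predict(model, [pts[0]])
        assert mean[0, 0] == pytest.approx(0.4, abs=1e-8)
        assert sd[0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_prior_reversion_far_from_data(self):
        pts = [SpaceTimePoint(0, 0, 0), SpaceTimePoint(1e4, 0, 0)]
        model = fit_gp(pts, np.array([[0.2], [0.8]]), P)
        mean, sd = gp_predict(model, [SpaceTimePoint(1e9, 1e9, 1e9)])
        assert mean[0, 0] == pytest.approx(0.5, abs=1e-8)  # training mean
        assert sd[0, 0] == pytest.approx(math.sqrt(P.tau2 + P.eta), abs=1e-8)

    def test_matches_dense_inverse_oracle(self, rng):
        """5 random training points in 3-D vs explicit-inverse conditioning."""
        for _ in range(3):
            params = random_kernel(rng)
            X, Y = random_training_set(rng, 5)
            Q, _ = random_training_set(rng, 3)
            model = fit_gp(X, Y, params)
            mean, sd = gp_predict(model, Q)
            ref_mean, ref_sd = brute_force_gp_predict(X, Y[:, 0], params, Q)
            np.testing.assert_allclose(mean[:, 0], ref_mean, atol=1e-8)
            np.testing.assert_allclose(sd[:, 0], ref_sd, atol=1e-8)

    def test_variance_bounds_and_determinism(self, rng):
        params = random_kernel(rng)
        X, Y = random_training_set(rng, 30)
        Q, _ = random_training_set(rng, 20)
        model = fit_gp(X, Y, params)
        m1, s1 = gp_predict(model, Q)
        m2, s2 = gp_predict(model, Q)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(s1, s2)
        assert (s1 >= 0).all()
        assert (s1 ** 2 <= params.tau2 + params.eta + 1e-9).all()

    def test_extra_training_point_never_increases_variance(self, rng):
        params = KernelParams(theta_x=1e11, theta_y=1e11, theta_t=1e6, tau2=1.0, eta=0.0)
        X, Y = random_training_set(rng, 10)
        X2, Y2 = random_training_set(rng, 11)
        X2[:10], Y2[:10] = X, Y
        Q, _ = random_training_set(rng, 15)
        _, sd_small = gp_predict(fit_gp(X, Y, params), Q)
        _, sd_big = gp_predict(fit_gp(X2, Y2, params), Q)
        assert (sd_big ** 2 <= sd_small ** 2 + 1e-9).all()

    def test_per_component_kernels(self, rng):
        X, Y = random_training_set(rng, 8, n_components=2)
        p2 = KernelParams(theta_x=5e10, theta_y=5e10, theta_t=5e5, tau2=0.5, eta=0.05)
        model = fit_gp(X, Y, [P, p2])
        mean, sd = gp_predict(model, X[:2])
        ref0, _ = brute_force_gp_predict(X, Y[:, 0], P, X[:2])
        ref1, _ = brute_force_gp_predict(X, Y[:, 1], p2, X[:2])
        np.testing.assert_allclose(mean[:, 0], ref0, atol=1e-8)
        np.testing.assert_allclose(mean[:, 1], ref1, atol=1e-8)


class TestFieldGrid:
    def test_100km_square_at_50km_spacing_has_four_cells(self):
        g = GridSpec(0.0, 100e3, 0.0, 100e3, 50e3)
        assert g.n_cells == 4
        centers = g.cell_centers()
        np.testing.assert_allclose(
            centers,
            [[25e3, 25e3], [75e3, 25e3], [25e3, 75e3], [75e3, 75e3]],
        )

    def test_single_cell_slice_equals_single_prediction(self, rng):
        params = random_kernel(rng)
        X, Y = random_training_set(rng, 6)
        model = fit_gp(X, Y, params)
        g = GridSpec(0.0, 50e3, 0.0, 50e3, 50e3)
        (sl,) = predict_field_grid(model, g, [-2500.0])
        mean, sd = gp_predict(model, [SpaceTimePoint(25e3, 25e3, -2500.0)])
        np.testing.assert_allclose(sl.mean, mean)
        np.testing.assert_allclose(sl.sd, sd)

    def test_grid_matches_looped_predictions(self, rng):
        params = random_kernel(rng)
        X, Y = random_training_set(rng, 10)
        model = fit_gp(X, Y, params)
        g = GridSpec(0.0, 500e3, 0.0, 500e3, 50e3)
        (sl,) = predict_field_grid(model, g, [-1000.0])
        for i, (cx, cy) in enumerate(g.cell_centers()):
            mean, sd = gp_predict(model, [SpaceTimePoint(cx, cy, -1000.0)])
            np.testing.assert_allclose(sl.mean[i], mean[0])
            np.testing.assert_allclose(sl.sd[i], sd[0])

    def test_cell_budget_enforced(self, rng):
        params = random_kernel(rng)
        X, Y = random_training_set(rng, 5)
        model = fit_gp(X, Y, params)
        g = GridSpec(0.0, 1e6, 0.0, 1e6, 1e4)
        with pytest.raises(ValueError, match="coarser"):
            predict_field_grid(model, g, [0.0], cell_budget=100)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0.0, 0.0, 0.0, 1e5, 1e4)
        with pytest.raises(ValueError):
            GridSpec(0.0, 1e5, 0.0, 1e5, -1.0)


class TestLoocv:
    def test_closed_form_equals_brute_force_refit(self, rng):
        """20-point fixture: identity-based LOO vs n explicit refits."""
        params = random_kernel(rng)
        X, Y = random_training_set(rng, 20)
        score = loocv_score(X, Y, params)
        offset = float(Y[:, 0].mean())
        errs = []
        for i in range(20):
            mask = np.arange(20) != i
            ref_mean, _ = brute_force_gp_predict(
                X[mask], Y[mask, 0], params, X[i : i + 1], offset=offset
            )
            errs.append((Y[i, 0] - ref_mean[0]) ** 2)
        assert score == pytest.approx(float(np.mean(errs)), abs=1e-8)

    def test_duplicates_with_positive_nugget_are_finite(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1e5, 0, 0], [2e5, 0, 0]])
        y = np.array([0.5, 0.5, 0.2, 0.1])
        assert np.isfinite(loocv_score(pts, y, P))

    def test_constant_observations_score_zero(self, rng):
        X, _ = random_training_set(rng, 10)
        y = np.full(10, 3.7)
        assert loocv_score(X, y, P) == pytest.approx(0.0, abs=1e-10)


class TestVariogram:
    def test_constant_field_has_zero_semivariance(self, rng):
        X, _ = random_training_set(rng, 40)
        y = np.full(40, 1.5)
        df = empirical_variogram(X, y, [0, 1e6, 4e6], [0, 5000, 20000])
        occupied = df[df.n_pairs > 0]
        assert (occupied.gamma_C1.abs() < 1e-20).all()

    def test_iid_noise_semivariance_near_variance(self):
        rng = np.random.default_rng(7)
        n, v = 400, 2.0
        X = np.column_stack(
            [rng.uniform(0, 1e6, n), rng.uniform(0, 1e6, n), rng.uniform(0, 1000, n)]
        )
        y = rng.normal(0, math.sqrt(v), n)
        df = empirical_variogram(X, y, [0, 5e5, 1.5e6], [0, 500, 1000])
        occupied = df[df.n_pairs > 500]
        # for i.i.d. noise the semivariance estimates the realized variance
        # of the draw in every bin, regardless of lag
        assert np.allclose(occupied.gamma_C1, np.var(y), rtol=0.1)
        assert np.allclose(occupied.gamma_C1, v, rtol=0.3)

    def test_three_point_hand_fixture(self):
        X = np.array([[0, 0, 0], [1000, 0, 0], [0, 0, 500]])
        y = np.array([0.0, 1.0, 3.0])
        df = empirical_variogram(X, y, [0, 2000], [0, 100, 1000])
        # bin (space<2000, time<100): pair (0,1); gamma = 0.5 * 1^2
        b1 = df[(df.time_lo == 0)].iloc[0]
        assert b1.n_pairs == 1 and b1.gamma_C1 == pytest.approx(0.5)
        # bin (space<2000, 100<=time<1000): pairs (0,2) and (1,2)
        b2 = df[(df.time_lo == 100)].iloc[0]
        assert b2.n_pairs == 2
        assert b2.gamma_C1 == pytest.approx(0.5 * (9 + 4) / 2)

    def test_empty_bins_reported_with_zero_count(self, rng):
        X, Y = random_training_set(rng, 5)
        df = empirical_variogram(X, Y[:, 0], [0, 1e-3, 1e7], [0, 1e5])
        empty = df[(df.space_hi == 1e-3)]
        assert (empty.n_pairs == 0).all()
        assert empty.gamma_C1.isna().all()


class TestMleKernel:
    TRUE = KernelParams.from_lengthscales(400, 400, 600, 1.0, 0.1)
    INIT = KernelParams.from_lengthscales(800, 800, 1200, 1.0, 0.05)

    @staticmethod
    def _simulate(seed, n=300, params=None):
        params = params or TestMleKernel.TRUE
        r = np.random.default_rng(seed)
        X = np.column_stack(
            [r.uniform(0, 3e6, n), r.uniform(0, 3e6, n), r.uniform(-8000, 2000, n)]
        )
        y = r.multivariate_normal(np.zeros(n), _cov(X, X, params), method="cholesky")
        return X, y

    def test_recovers_lengthscales_within_factor_two(self):
        """Simulation-recovery: majority of seeded replicates within 2x."""
        hits = 0
        for seed in range(6):
            X, y = self._simulate(seed)
            fit, _ = mle_kernel(X, y, self.INIT, seed=seed)
            ratio = np.array(fit.lengthscales) / np.array(self.TRUE.lengthscales)
            hits += bool(np.all((ratio >= 0.5) & (ratio <= 2.0)))
        assert hits >= 4

    def test_white_noise_is_nugget_dominated(self):
        rng = np.random.default_rng(3)
        X = np.column_stack(
            [rng.uniform(0, 3e6, 150), rng.uniform(0, 3e6, 150),
             rng.uniform(-8000, 2000, 150)]
        )
        y = rng.normal(size=150)
        fit, _ = mle_kernel(X, y, self.INIT, seed=0)
        assert fit.eta / fit.tau2 >= 1.0

    def test_optimum_at_least_as_good_as_init(self):
        X, y = self._simulate(42, n=80)
        fit, ll_opt = mle_kernel(X, y, self.INIT, seed=0)
        assert ll_opt >= log_marginal_likelihood(X, y, self.INIT) - 1e-6

    def test_profiled_sill_matches_joint_optimum(self):
        """Optimizing tau2 jointly cannot beat the closed-form profile."""
        X, y = self._simulate(5, n=60)
        fit, _ = mle_kernel(X, y, self.INIT, seed=0)
        base = log_marginal_likelihood(X, y, fit)
        # perturbing tau2 (with eta scaled along) around the profile optimum
        # cannot improve the full likelihood
        for scale in (0.7, 0.9, 1.1, 1.4):
            other = KernelParams(
                fit.theta_x, fit.theta_y, fit.theta_t,
                fit.tau2 * scale, fit.eta * scale,
            )
            assert _joint_ll(X, y, other) <= _joint_ll(X, y, fit) + 1e-6
        assert np.isfinite(base)


def _joint_ll(X, y, params):
    """Full (non-profiled) Gaussian log marginal likelihood."""
    yc = y - y.mean()
    K = _cov(np.asarray(X), np.asarray(X), params)
    n = len(yc)
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    return float(
        -0.5 * yc @ np.linalg.solve(K, yc) - 0.5 * logdet - 0.5 * n * math.log(2 * math.pi)
    )
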