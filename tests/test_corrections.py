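"""Measurement-error corrections: attenuation algebra, Fuller, calibration,
orthogonal regression, SIMEX, marginal likelihoods and the method chooser."""

import numpy as np
import pytest
from scipy import integrate, stats

from mistime.corrections import (
    AttenuationInputs,
    CalibrationModel,
    MELikelihoodSpec,
    SimexConfig,
    correct_slope,
    fit_me_likelihood,
    fuller_moment_fit,
    me_likelihood,
    orthogonal_regression_fit,
    regression_calibration,
    reliability_ratio,
    select_correction_method,
    simex,
    variance_inequality_holds,
)
from mistime.errorsim import (
    EquationErrorSpec,
    ErrorSpec,
    generate_linear_dataset,
    generate_oscillation_dataset,
)
from mistime.naivefit import GaussianNoiseSpec, fit_least_squares, predict


def _ols_slope(w, y):
    A = np.column_stack([np.ones_like(w), w])
    return float(np.linalg.lstsq(A, y, rcond=None)[0][1])


class TestReliabilityRatio:
    def test_linear_design_value(self):
        assert reliability_ratio(1.0, 0.25) == pytest.approx(0.8)

    def test_no_error_identity(self):
        lam = reliability_ratio(2.3, 0.0)
        assert lam == 1.0
        assert correct_slope(0.77, lam) == 0.77

    def test_corrects_attenuated_slope(self):
        # a naive slope of 0.8431 under lambda = 0.8 corrects to about 1.054
        assert correct_slope(0.8431, 0.8) == pytest.approx(1.0539, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            reliability_ratio(0.0, 0.1)
        with pytest.raises(ValueError):
            correct_slope(1.0, 1.5)


class TestVarianceInequality:
    def test_linear_design_does_not_satisfy(self):
        assert not variance_inequality_holds(AttenuationInputs(1.0, 0.25, 0.25, 1.0))

    def test_flat_slope_satisfies(self):
        assert variance_inequality_holds(AttenuationInputs(1.0, 0.25, 0.25, 0.0))

    def test_monotone_in_error_variance(self):
        held = [
            variance_inequality_holds(AttenuationInputs(1.0, su2, 0.6, 1.0))
            for su2 in np.linspace(0.0, 5.0, 30)
        ]
        # once true, increasing sigma_u^2 keeps it true
        first_true = held.index(True)
        assert all(held[first_true:])


class TestFuller:
    def test_zero_error_is_ols(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 200)
        y = 0.3 + 1.7 * w + rng.normal(0, 0.2, 200)
        slope, intercept = fuller_moment_fit(w, y, 0.0)
        assert slope == pytest.approx(_ols_slope(w, y), rel=1e-12)

    def test_algebraic_identity_vs_naive(self):
        rng = np.random.default_rng(1)
        w = rng.normal(0, 1.3, 150)
        y = rng.normal(0, 1, 150) + 0.5 * w
        s_ww = np.var(w, ddof=1)
        slope, _ = fuller_moment_fit(w, y, 0.3)
        assert slope == pytest.approx(_ols_slope(w, y) * s_ww / (s_ww - 0.3), rel=1e-10)

    def test_consistency_on_classical_design(self):
        # mean estimate over 200 large classical-error datasets centred at 1
        ests = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 10**4)
            w = x + rng.normal(0, 0.5, 10**4)
            y = x + rng.normal(0, 0.5, 10**4)
            ests.append(fuller_moment_fit(w, y, 0.25)[0])
        ests = np.asarray(ests)
        assert abs(ests.mean() - 1.0) < 3 * ests.std() / np.sqrt(len(ests))

    def test_degenerate_denominator(self):
        w = np.array([0.0, 0.1, -0.1, 0.05])
        with pytest.raises(ValueError):
            fuller_moment_fit(w, w, 5.0)


class TestRegressionCalibration:
    def test_identity_when_lambda_one(self):
        w = np.linspace(-3, 3, 10)
        assert np.array_equal(regression_calibration(w, CalibrationModel(0.0, 1.0)), w)

    def test_mean_is_fixed_point(self):
        model = CalibrationModel(1.2, 0.6)
        assert regression_calibration(np.array([1.2]), model)[0] == pytest.approx(1.2)

    def test_shrinks_toward_mean(self):
        model = CalibrationModel(0.0, 0.8)
        xhat = regression_calibration(np.array([-2.0, 2.0]), model)
        assert np.allclose(xhat, [-1.6, 1.6])

    def test_estimated_from_observed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10**5)
        w = x + rng.normal(0, 0.5, 10**5)
        model = CalibrationModel.from_observed(w, 0.25)
        assert model.lam == pytest.approx(0.8, abs=0.01)


class TestOrthogonalRegression:
    def test_large_eta_recovers_ols(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 60)
        y = 0.2 + 1.4 * w + rng.normal(0, 0.3, 60)
        fit = orthogonal_regression_fit("linear", w, y, eta=1e12)
        assert fit.theta_hat["beta_x"] == pytest.approx(_ols_slope(w, y), abs=1e-6)
        assert np.allclose(fit.x_hat, w, atol=1e-6)

    def test_matches_closed_form_deming(self):
        rng = np.random.default_rng(5)
        w = rng.normal(0, 1, 50)
        y = 2.0 * w + 0.5 + rng.normal(0, 0.3, 50)
        fit = orthogonal_regression_fit("linear", w, y, eta=1.0)
        sxx, syy = np.var(w, ddof=1), np.var(y, ddof=1)
        sxy = np.cov(w, y, ddof=1)[0, 1]
        deming = ((syy - sxx) + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
        assert fit.theta_hat["beta_x"] == pytest.approx(deming, abs=1e-8)

    def test_noise_free_exact(self):
        w = np.linspace(0, 1, 20)
        y = 3.0 * w - 1.0
        fit = orthogonal_regression_fit("linear", w, y, eta=1.0)
        assert fit.theta_hat["beta_x"] == pytest.approx(3.0, abs=1e-8)
        assert np.allclose(fit.x_hat, w, atol=1e-8)

    def test_objective_never_exceeds_naive_ssr(self):
        rng = np.random.default_rng(7)
        w = rng.normal(0, 1, 40)
        y = np.cos(2.0 * w) + rng.normal(0, 0.2, 40)
        fit = orthogonal_regression_fit(
            "cosine", w, y, eta=1.0, init={"a": 1.0}, free_params=["a"],
            fixed_params={"b": 2.0},
        )
        naive_ssr = float(np.sum((predict("cosine", {"a": fit.theta_hat["a"], "b": 2.0}, w) - y) ** 2))
        # the joint minimisation searches a superset of the naive solution
        assert fit.objective <= naive_ssr + 1e-9

    def test_eta_one_is_scale_dependent(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 80)
        w = x + rng.normal(0, 0.5, 80)
        y = 2.0 * x + rng.normal(0, 0.5, 80)
        slope_raw = orthogonal_regression_fit("linear", w, y, eta=1.0).theta_hat["beta_x"]
        slope_scaled = orthogonal_regression_fit("linear", w, 10 * y, eta=1.0).theta_hat["beta_x"] / 10
        assert abs(slope_raw - slope_scaled) > 0.01


class TestSimex:
    def test_zero_variance_returns_naive(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, 100)
        y = 2 * w + rng.normal(0, 0.1, 100)
        res = simex(_ols_slope, (w, y), 0.0, rng=rng)
        assert res.corrected[0] == res.naive[0]

    def test_trajectory_monotonically_attenuated(self):
        # mean estimate decreases as the inflated error variance grows
        acc = None
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 2000)
            w = x + rng.normal(0, 0.5, 2000)
            y = x + rng.normal(0, 0.5, 2000)
            res = simex(_ols_slope, (w, y), 0.25,
                        SimexConfig(n_pseudo=10), rng=np.random.default_rng(seed + 1))
            acc = res.trajectory[:, 0] if acc is None else acc + res.trajectory[:, 0]
        mean_traj = acc / 30
        assert np.all(np.diff(mean_traj) < 0)

    def test_rational_linear_recovers_slope(self):
        # rational-linear extrapolation is exact for the attenuation curve
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 5000)
            w = x + rng.normal(0, 0.5, 5000)
            y = x + rng.normal(0, 0.5, 5000)
            res = simex(
                _ols_slope, (w, y), 0.25,
                SimexConfig(n_pseudo=30, extrapolant="rational_linear"),
                rng=np.random.default_rng(1000 + seed),
            )
            ests.append(res.corrected[0])
        ests = np.asarray(ests)
        assert abs(ests.mean() - 1.0) < max(0.02, 3 * ests.std() / np.sqrt(len(ests)))


class TestMeLikelihood:
    def test_degenerate_error_equals_naive_likelihood(self, rng):
        ds = generate_oscillation_dataset("controlled_case2", rng=rng)
        spec = MELikelihoodSpec("berkson", "normal", var_u=0.0)
        noise = GaussianNoiseSpec(0.05)
        theta = {"a": 2.5, "b": 4.0}
        ll = me_likelihood(theta, ds, "cosine", spec, noise)
        resid = predict("cosine", theta, ds.w) - ds.y
        naive = float(np.sum(stats.norm.logpdf(resid, scale=np.sqrt(0.05))))
        assert ll == pytest.approx(naive, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_quadrature_against_adaptive_integration(self, seed):
        # order-21 Gauss-Hermite vs brute-force quad on random Berkson configs
        # (mild oscillation; strongly oscillatory integrands need higher order,
        # exercised in test_removes_case2_amplitude_bias)
        rng = np.random.default_rng(seed)
        import pandas as pd

        from mistime.errorsim import TimecourseDataset

        var_u = rng.uniform(0.005, 0.02)
        sig2 = rng.uniform(0.05, 0.2)
        theta = {"a": rng.uniform(0.5, 3.0), "b": rng.uniform(0.5, 1.5)}
        w = rng.uniform(-1, 1, 3)
        x_true = w + rng.normal(0, np.sqrt(var_u), 3)
        y = theta["a"] * np.cos(theta["b"] * x_true) + rng.normal(0, np.sqrt(sig2), 3)
        ds = TimecourseDataset(
            pd.DataFrame(
                {"subject_id": range(3), "protocol_time": w, "true_time": w, "response": y}
            )
        )
        spec = MELikelihoodSpec("berkson", "normal", var_u=var_u, quad_order=21)
        ll = me_likelihood(theta, ds, "cosine", spec, GaussianNoiseSpec(sig2))
        brute = 0.0
        for wi, yi in zip(w, y):
            f = lambda x: (
                stats.norm.pdf(yi, theta["a"] * np.cos(theta["b"] * x), np.sqrt(sig2))
                * stats.norm.pdf(x, wi, np.sqrt(var_u))
            )
            val, _ = integrate.quad(f, wi - 8 * np.sqrt(var_u), wi + 8 * np.sqrt(var_u))
            brute += np.log(val)
        assert ll == pytest.approx(brute, abs=1e-6)

    def test_berkson_translation_invariance(self, rng):
        import pandas as pd

        from mistime.errorsim import TimecourseDataset

        w = np.array([0.0, 0.5, 1.0])
        y = np.array([1.0, 2.0, 1.5])
        spec = MELikelihoodSpec("berkson", "normal", var_u=0.04)
        noise = GaussianNoiseSpec(0.1)
        theta = {"beta0": 0.2, "beta_x": 1.1}

        def make(wv):
            return TimecourseDataset(
                pd.DataFrame(
                    {"subject_id": range(3), "protocol_time": wv, "true_time": wv, "response": y}
                )
            )

        ll0 = me_likelihood(theta, make(w), "linear", spec, noise)
        # shifting all recorded values and absorbing the shift in the intercept
        shift = 5.0
        theta_shift = {"beta0": 0.2 - 1.1 * shift, "beta_x": 1.1}
        ll1 = me_likelihood(theta_shift, make(w + shift), "linear", spec, noise)
        assert ll0 == pytest.approx(ll1, rel=1e-9)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MELikelihoodSpec("classical", "normal", var_u=0.1)  # missing x density
        with pytest.raises(ValueError):
            MELikelihoodSpec("berkson", "normal", var_u=0.1, x_density=(0.0, 1.0))

    def test_removes_case2_amplitude_bias(self):
        # the Berkson marginal likelihood undoes the naive attenuation;
        # a high quadrature order is needed for the oscillatory integrand
        me_est, naive_est = [], []
        for seed in range(40):
            ds = generate_oscillation_dataset(
                "controlled_case2", rng=np.random.default_rng(seed)
            )
            spec = MELikelihoodSpec("berkson", "normal", var_u=0.05, quad_order=121)
            est = fit_me_likelihood(
                "cosine", ds, spec, GaussianNoiseSpec(0.05), ["a"], {"a": 2.0},
                fixed_params={"b": 4.0},
            )
            me_est.append(est["a"])
            naive = fit_least_squares(
                "cosine", ds, free_params=["a"], fixed_params={"b": 4.0}, init={"a": 1.0}
            )
            naive_est.append(naive.theta_hat["a"])
        me_est, naive_est = np.asarray(me_est), np.asarray(naive_est)
        assert abs(me_est.mean() - 3.0) < 3 * me_est.std() / np.sqrt(len(me_est))
        assert naive_est.mean() < 2.2  # attenuated towards 3 e^{-0.4} ~ 2.01


class TestMethodChooser:
    def test_linear_classical_known_variance(self):
        recs = select_correction_method(
            {
                "model_class": "linear",
                "extra_data": "none",
                "variance_known": True,
                "error_model": "classical",
                "distribution_fully_specified": False,
            }
        )
        assert [r.method for r in recs] == [
            "reliability ratio",
            "Fuller's method of moments",
            "SIMEX",
        ]

    def test_nonlinear_berkson_distribution_specified(self):
        recs = select_correction_method(
            {
                "model_class": "nonlinear",
                "extra_data": "none",
                "variance_known": False,
                "error_model": "berkson",
                "distribution_fully_specified": True,
            }
        )
        assert [r.method for r in recs] == ["Berkson measurement-error likelihood"]

    def test_glm_with_replicates(self):
        recs = select_correction_method(
            {
                "model_class": "glm",
                "extra_data": "replicates",
                "variance_known": False,
                "error_model": "classical",
                "distribution_fully_specified": False,
            }
        )
        assert [r.method for r in recs] == ["regression calibration"]

    def test_invalid_answers(self):
        with pytest.raises(ValueError):
            select_correction_method(
                {
                    "model_class": "quadratic",
                    "extra_data": "none",
                    "variance_known": False,
                    "error_model": "classical",
                    "distribution_fully_specified": False,
                }
            )
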