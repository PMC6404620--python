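"""Left-bounded Gaussian likelihood, BFGS fitting, and Wald contrasts."""
import numpy as np
import pytest
from scipy import optimize, stats

import dispscan as ds
from dispscan.tobit import (
    ContrastError,
    TobitSpec,
    fit_tobit,
    negloglik,
    negloglik_grad,
    wald_contrast,
)


class TestNegloglik:
    def test_single_point_truncated_value(self):
        """y=1, mu=0, sigma=1, tau=0: -log[phi(1) / (1 - Phi(0))]."""
        val = negloglik(
            np.array([0.0, 0.0]), np.array([1.0]), np.ones((1, 1)),
            TobitSpec(0.0, "truncated"),
        )
        expected = -np.log(stats.norm.pdf(1.0) / (1.0 - stats.norm.cdf(0.0)))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_bound_at_minus_infinity_equals_gaussian(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2, 1.5, 30)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        params = np.array([1.0, 0.3, np.log(1.2)])
        for variant in ("truncated", "censored"):
            val = negloglik(params, y, X, TobitSpec(-1e10, variant))
            gauss = -stats.norm.logpdf(
                y, X @ params[:2], np.exp(params[-1])
            ).sum()
            assert val == pytest.approx(gauss, abs=1e-10)

    def test_censored_without_bound_observations_equals_gaussian(self):
        rng = np.random.default_rng(1)
        y = np.abs(rng.normal(3, 0.5, 50)) + 0.5   # all well above 0
        X = np.ones((50, 1))
        params = np.array([2.5, np.log(0.8)])
        cens = negloglik(params, y, X, TobitSpec(0.0, "censored"))
        gauss = -stats.norm.logpdf(y, X @ params[:1], np.exp(params[-1])).sum()
        assert cens == pytest.approx(gauss, abs=1e-10)

    @pytest.mark.parametrize("variant", ["truncated", "censored"])
    def test_analytic_gradient_matches_numerical(self, variant):
        rng = np.random.default_rng(2)
        n = 40
        if variant == "truncated":
            y = np.abs(rng.normal(1, 1, n))
        else:
            y = np.maximum(rng.normal(0.5, 1, n), 0.0)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        spec = TobitSpec(0.0, variant)
        for p0 in ([0.5, 0.2, -0.1], [1.2, -0.3, 0.4]):
            err = optimize.check_grad(
                negloglik, negloglik_grad, np.array(p0), y, X, spec
            )
            assert err < 1e-5

    def test_sigma_profile_unimodal_at_true_beta(self):
        """Fixing beta at truth, nll is unimodal in sigma over a grid."""
        tn = stats.truncnorm(a=-1.0, b=np.inf, loc=1.0, scale=1.0)
        y = tn.rvs(500, random_state=3)
        X = np.ones((500, 1))
        spec = TobitSpec(0.0, "truncated")
        grid = np.linspace(0.1, 10.0, 200)
        vals = np.array(
            [negloglik(np.array([1.0, np.log(s)]), y, X, spec) for s in grid]
        )
        k = int(np.argmin(vals))
        assert 0 < k < len(grid) - 1
        assert (np.diff(vals[: k + 1]) < 0).all()
        assert (np.diff(vals[k:]) > 0).all()

    def test_duplicating_data_doubles_loglik(self):
        rng = np.random.default_rng(4)
        y = np.abs(rng.normal(1, 1, 30))
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        params = np.array([0.8, 0.1, 0.2])
        for variant in ("truncated", "censored"):
            spec = TobitSpec(0.0, variant)
            single = negloglik(params, y, X, spec)
            double = negloglik(
                params, np.concatenate([y, y]), np.vstack([X, X]), spec
            )
            assert double == pytest.approx(2 * single, rel=1e-12)


class TestFitTobit:
    def test_censored_far_from_bound_matches_ols(self):
        rng = np.random.default_rng(5)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([100.0, 3.0]) + rng.normal(0, 5, n)
        fit = fit_tobit(y, X, TobitSpec(0.0, "censored"))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma_ml = np.sqrt(((y - X @ beta_ols) ** 2).mean())
        assert fit.beta == pytest.approx(beta_ols, abs=1e-6)
        assert fit.sigma == pytest.approx(sigma_ml, abs=1e-6)

    def test_truncated_recovers_simulated_parameters(self):
        tn = stats.truncnorm(a=-1.0, b=np.inf, loc=1.0, scale=1.0)
        y = tn.rvs(2000, random_state=42)
        fit = fit_tobit(y, np.ones((2000, 1)), TobitSpec(0.0, "truncated"))
        se_mu = np.sqrt(fit.vcov[0, 0])
        se_sigma = np.sqrt(fit.vcov[1, 1])
        assert fit.converged
        assert abs(fit.beta[0] - 1.0) < 3 * se_mu
        assert abs(fit.sigma - 1.0) < 3 * se_sigma

    def test_optimum_matches_grid_search(self):
        """2-D dense grid over (mu, sigma) agrees with BFGS optimum."""
        tn = stats.truncnorm(a=-0.8, b=np.inf, loc=0.8, scale=1.0)
        y = tn.rvs(50, random_state=7)
        X = np.ones((50, 1))
        spec = TobitSpec(0.0, "truncated")
        fit = fit_tobit(y, X, spec)
        mus = np.linspace(fit.beta[0] - 1, fit.beta[0] + 1, 201)
        sigmas = np.linspace(max(fit.sigma - 0.5, 0.05), fit.sigma + 0.5, 201)
        best = min(
            (negloglik(np.array([m, np.log(s)]), y, X, spec), m, s)
            for m in mus
            for s in sigmas
        )
        assert best[1] == pytest.approx(fit.beta[0], abs=0.011)
        assert best[2] == pytest.approx(fit.sigma, abs=0.006)

    def test_gradient_norm_small_at_optimum(self):
        rng = np.random.default_rng(8)
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 150
            X = np.column_stack([np.ones(n), r.integers(0, 2, n).astype(float)])
            y = np.abs(r.normal(1, 1, n) * (1 + 0.5 * X[:, 1]))
            fit = fit_tobit(y, X, TobitSpec(0.0, "truncated"))
            if fit.converged:
                assert fit.grad_norm < 1e-5

    def test_rank_deficient_design_raises(self):
        y = np.abs(np.random.default_rng(9).normal(1, 1, 30))
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_tobit(y, X, TobitSpec(0.0, "truncated"))

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError, match="observations"):
            fit_tobit(np.array([1.0, 2.0]), np.ones((2, 1)), TobitSpec(0.0, "truncated"))


class TestWaldContrast:
    def _fit(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, n)
        X = np.column_stack([np.ones(n), (g == 0).astype(float), (g == 1).astype(float)])
        y = np.abs(rng.normal(1, 1, n))
        return fit_tobit(y, X, TobitSpec(0.0, "truncated"))

    def test_single_row_contrast_is_squared_z(self):
        fit = self._fit()
        c = wald_contrast(fit, np.array([[0.0, 1.0, 0.0]]))
        z = fit.beta[1] / np.sqrt(fit.vcov[1, 1])
        assert c.stat == pytest.approx(z**2, rel=1e-10)
        assert c.estimate == pytest.approx(fit.beta[1])

    def test_zero_beta_gives_zero_stat_unit_p(self):
        fit = self._fit()
        fit.beta = np.zeros_like(fit.beta)
        c = wald_contrast(fit, np.eye(3))
        assert c.stat == 0.0 and c.p == 1.0

    def test_all_zero_row_rejected(self):
        fit = self._fit()
        with pytest.raises(ContrastError, match="zero"):
            wald_contrast(fit, np.zeros((1, 3)))

    def test_wrong_width_rejected(self):
        fit = self._fit()
        with pytest.raises(ContrastError, match="columns"):
            wald_contrast(fit, np.array([[1.0, 0.0]]))

    def test_null_joint_pvalues_uniform(self):
        """2-df genotype contrast on null data: P ~ Uniform(0,1) by KS."""
        C = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        pvals = []
        for seed in range(400):
            rng = np.random.default_rng(100_000 + seed)
            g = rng.integers(0, 3, 300)
            X = np.column_stack(
                [np.ones(300), (g == 0).astype(float), (g == 1).astype(float)]
            )
            y = np.abs(rng.normal(1, 1, 300))
            fit = fit_tobit(y, X, TobitSpec(0.0, "truncated"))
            pvals.append(wald_contrast(fit, C).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
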