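"""Core regression engine: OLS, conjugate Bayes, hybrid alternation, Wald summaries."""

import numpy as np
import pytest
import statsmodels.api as sm

from bfhde import (
    PriorSpec,
    RegressionData,
    fit_bayes_conjugate,
    fit_frequentist,
    fit_hybrid_em,
    noninformative_prior,
    wald_summary,
)
from bfhde.exceptions import (
    InsufficientDataError,
    InvalidInputError,
    InvalidPriorError,
    SingularDesignError,
)
from bfhde.inference import ConvergenceWarning

from ._oracles import hybrid_fixed_point, ols_normal_equations, posterior_mean_metropolis
from .conftest import random_regression


class TestFrequentist:
    def test_noiseless_recovers_beta_exactly(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
        beta = np.array([2.0, -1.5, 0.25])
        fit = fit_frequentist(RegressionData(Y=X @ beta, X=X))
        np.testing.assert_allclose(fit.estimate, beta, atol=1e-10)
        assert fit.sigma2_used == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equation_oracle(self, seed):
        data, _ = random_regression(seed)
        fit = fit_frequentist(data)
        np.testing.assert_allclose(
            fit.estimate, ols_normal_equations(data.X, data.Y), rtol=1e-10
        )

    def test_matches_statsmodels_ols(self):
        data, _ = random_regression(7)
        ref = sm.OLS(data.Y, data.X).fit()
        fit = fit_frequentist(data)
        np.testing.assert_allclose(fit.estimate, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)

    def test_singular_design_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(SingularDesignError):
            fit_frequentist(RegressionData(Y=np.zeros(10), X=X, names=("a", "b")))

    def test_too_few_rows_without_sigma2_raises(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(3), rng.normal(size=(3, 2))])
        with pytest.raises(InsufficientDataError):
            fit_frequentist(RegressionData(Y=rng.normal(size=3), X=X))

    def test_supplied_sigma2_bypasses_estimation(self):
        data, _ = random_regression(2)
        fit = fit_frequentist(data, sigma2=4.0)
        assert fit.sigma2_used == 4.0


class TestBayesConjugate:
    def test_flat_prior_limit_is_ols(self):
        data, _ = random_regression(3)
        ols = fit_frequentist(data)
        prior = PriorSpec(np.zeros(3), np.full(3, 1e12), np.ones(3, bool))
        bay = fit_bayes_conjugate(data, prior)
        np.testing.assert_allclose(bay.estimate, ols.estimate, rtol=1e-6)

    def test_dogmatic_prior_limit_is_prior_mean(self):
        data, _ = random_regression(4)
        mu = np.array([0.3, -0.7, 1.1])
        prior = PriorSpec(mu, np.full(3, 1e-12), np.ones(3, bool))
        bay = fit_bayes_conjugate(data, prior)
        np.testing.assert_allclose(bay.estimate, mu, atol=1e-6)

    def test_posterior_mean_matches_metropolis_oracle(self):
        data, _ = random_regression(5)
        prior = PriorSpec(np.array([0.0, -0.5, 0.5]), np.array([2.0, 0.5, 1.0]),
                          np.ones(3, bool))
        fit = fit_bayes_conjugate(data, prior)
        mc = posterior_mean_metropolis(
            data.X, data.Y, prior.mean, prior.variance, fit.sigma2_used, seed=11
        )
        np.testing.assert_allclose(fit.estimate, mc, atol=0.05)

    def test_nonpositive_prior_variance_rejected(self):
        with pytest.raises(InvalidPriorError):
            PriorSpec(np.zeros(2), np.array([1.0, 0.0]), np.ones(2, bool))

    def test_monotone_shrinkage_toward_prior_mean(self):
        """Shrinking the prior variance moves the group estimate monotonically
        from OLS toward the prior mean."""
        data, _ = random_regression(6)
        ols_b1 = fit_frequentist(data)["group"]["estimate"]
        target = ols_b1 + 2.0
        path = []
        for v in (1e6, 10.0, 1.0, 0.1, 0.01, 1e-6):
            prior = PriorSpec(
                np.array([0.0, target, 0.0]), np.array([1e6, v, 1e6]), np.ones(3, bool)
            )
            path.append(fit_bayes_conjugate(data, prior)["group"]["estimate"])
        diffs = np.diff(path)
        assert np.all(diffs > -1e-9) or np.all(diffs < 1e-9)  # monotone
        assert abs(path[0] - ols_b1) < 1e-3 and abs(path[-1] - target) < 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_information_never_decreases(self, seed):
        """Posterior covariance is SPD with diagonal no larger than either the
        OLS covariance or the (sigma2-free) prior variance."""
        data, _ = random_regression(seed + 50)
        prior = PriorSpec(np.zeros(3), np.array([4.0, 0.5, 2.0]), np.ones(3, bool))
        fit = fit_bayes_conjugate(data, prior)
        ols = fit_frequentist(data)
        prec = np.diag(1 / prior.variance) + data.X.T @ data.X / fit.sigma2_used
        eigs = np.linalg.eigvalsh(np.linalg.inv(prec))
        assert np.all(eigs > 0)
        assert np.all(fit.se <= ols.se + 1e-12)
        assert np.all(fit.se**2 <= prior.variance + 1e-12)


class TestHybridEM:
    def test_all_frequentist_partition_degenerates_to_ols(self):
        data, _ = random_regression(8)
        prior = PriorSpec(np.zeros(3), np.full(3, 1.0), np.zeros(3, bool))
        hyb = fit_hybrid_em(data, prior)
        ols = fit_frequentist(data)
        np.testing.assert_allclose(hyb.estimate, ols.estimate, rtol=1e-12)
        np.testing.assert_allclose(hyb.se, ols.se, rtol=1e-12)
        assert hyb.method == "hybrid"

    def test_all_bayesian_partition_routes_to_conjugate(self):
        data, _ = random_regression(9)
        prior = noninformative_prior(3)
        with pytest.warns(UserWarning, match="degenerates"):
            hyb = fit_hybrid_em(data, prior)
        bay = fit_bayes_conjugate(data, prior)
        np.testing.assert_allclose(hyb.estimate, bay.estimate)
        assert hyb.method == "hybrid"

    @pytest.mark.parametrize("seed", range(8))
    def test_converges_to_direct_fixed_point(self, seed):
        data, _ = random_regression(seed + 100)
        prior = PriorSpec(
            np.array([0.0, -0.4, 0.0]), np.array([100.0, 0.3, 100.0]),
            np.array([False, True, False]),
        )
        tol = 1e-10
        hyb = fit_hybrid_em(data, prior, tol=tol, max_iter=500)
        assert hyb.converged
        direct = hybrid_fixed_point(
            data.X, data.Y, prior.partition, prior.mean[1:2], prior.variance[1:2],
            hyb.sigma2_used,
        )
        np.testing.assert_allclose(hyb.estimate, direct, atol=10 * tol)

    def test_fixed_point_is_idempotent(self):
        """One extra alternation sweep from the converged point moves nothing
        beyond tolerance."""
        data, _ = random_regression(13)
        prior = PriorSpec(
            np.array([0.0, 0.5, 0.0]), np.array([100.0, 0.2, 100.0]),
            np.array([False, True, False]),
        )
        tol = 1e-10
        hyb = fit_hybrid_em(data, prior, tol=tol, max_iter=500)
        s2 = hyb.sigma2_used
        XB, XF = data.X[:, prior.partition], data.X[:, ~prior.partition]
        beta = hyb.estimate
        yB = data.Y - XF @ beta[~prior.partition]
        prec = 1 / prior.variance[1] + float(XB.ravel() @ XB.ravel()) / s2
        bB = (prior.mean[1] / prior.variance[1] + float(XB.ravel() @ yB) / s2) / prec
        yF = data.Y - XB.ravel() * bB
        bF = np.linalg.solve(XF.T @ XF, XF.T @ yF)
        swept = beta.copy()
        swept[prior.partition] = bB
        swept[~prior.partition] = bF
        assert np.max(np.abs(swept - beta)) < 10 * tol

    @pytest.mark.parametrize("seed", range(5))
    def test_flat_prior_hybrid_reproduces_ols(self, seed):
        """Backfitting with an uninformative prior converges to the full OLS
        solution (the pattern where hybrid non-informative and frequentist
        give the same point estimate)."""
        data, _ = random_regression(seed + 200)
        prior = PriorSpec(
            np.zeros(3), np.array([1e6, 1e6, 1e6]), np.array([False, True, False])
        )
        hyb = fit_hybrid_em(data, prior, tol=1e-12, max_iter=1000)
        ols = fit_frequentist(data)
        np.testing.assert_allclose(hyb.estimate, ols.estimate, rtol=1e-4)

    def test_hybrid_se_below_bayes_se_for_bayesian_coefficient(self):
        """Conditioning removes cross-coefficient uncertainty: the hybrid SE of
        the Bayesian coefficient is no larger than the all-Bayesian SE."""
        data, _ = random_regression(14)
        mask = np.array([False, True, False])
        prior = PriorSpec(np.zeros(3), np.array([100.0, 0.3, 100.0]), mask)
        hyb = fit_hybrid_em(data, prior)
        bay = fit_bayes_conjugate(data, prior)
        assert hyb["group"]["se"] <= bay["group"]["se"] + 1e-12

    def test_nonconvergence_flagged(self):
        data, _ = random_regression(15)
        prior = PriorSpec(
            np.zeros(3), np.full(3, 100.0), np.array([False, True, False])
        )
        with pytest.warns(ConvergenceWarning):
            hyb = fit_hybrid_em(data, prior, tol=1e-15, max_iter=2)
        assert not hyb.converged
        assert hyb.iterations == 2


class TestWaldSummary:
    @pytest.mark.parametrize(
        "estimate,se,expected",
        [(-0.299, 0.106, 0.005), (-0.275, 0.214, 0.199)],
    )
    def test_published_pvalues_reproduced(self, estimate, se, expected):
        _, _, p = wald_summary(estimate, se)
        assert round(p, 3) == expected

    def test_null_estimate(self):
        lo, hi, p = wald_summary(0.0, 0.7)
        assert p == 1.0
        assert lo == -hi

    def test_interval_arithmetic(self):
        lo, hi, _ = wald_summary(1.0, 0.5)
        assert (lo, hi) == (1.0 - 1.96 * 0.5, 1.0 + 1.96 * 0.5)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(InvalidInputError):
            wald_summary(1.0, 0.0)


def test_coverage_and_bias_at_moderate_sample_size():
    """Over replicated draws at n=50 the OLS group estimate is unbiased and its
    1.96-normal interval covers the truth at a rate inside [0.90, 0.99]."""
    from bfhde import generate_toy_regression

    beta = np.array([1.0, 1.0, -0.5])
    hits, errs = [], []
    for rep in range(200):
        data = generate_toy_regression(50, beta, sigma=1.0, seed=10_000 + rep)
        fit = fit_frequentist(data)
        b1 = fit["group"]
        errs.append(b1["estimate"] - beta[1])
        hits.append(b1["ci_low"] <= beta[1] <= b1["ci_high"])
    assert abs(np.mean(errs)) < 0.05
    assert 0.90 <= np.mean(hits) <= 0.99
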