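"""Independent oracles used by the tests.

Deliberately naive implementations kept separate from the package so the
checked paths and the checks share no code: direct linear-system solves,
a Metropolis sampler for the conjugate posterior, a hand-rolled BH
step-up, and exact-rational hypergeometric tails.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.stats import norm


def ols_normal_equations(X, Y):
    """Solve X'X beta = X'Y with a generic dense solver."""
    return np.linalg.solve(np.asarray(X).T @ X, np.asarray(X).T @ Y)


def hybrid_fixed_point(X, Y, mask, mu_B, var_B, sigma2):
    """Direct solution of the stationarity system of the alternating scheme.

    Unknowns (beta_B, beta_F) satisfy
        (S_B^-1 sigma^2 + X_B'X_B) beta_B + X_B'X_F beta_F
            = S_B^-1 sigma^2 mu_B + X_B'Y
        X_F'X_B beta_B + X_F'X_F beta_F = X_F'Y
    (the conjugate-posterior-mean and conditional-OLS equations with each
    block's residual substituted).  Returns the full-length beta.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    mask = np.asarray(mask, bool)
    XB, XF = X[:, mask], X[:, ~mask]
    SBinv_s2 = np.diag(sigma2 / np.asarray(var_B, float))
    pB, pF = XB.shape[1], XF.shape[1]
    A = np.zeros((pB + pF, pB + pF))
    b = np.zeros(pB + pF)
    A[:pB, :pB] = SBinv_s2 + XB.T @ XB
    A[:pB, pB:] = XB.T @ XF
    A[pB:, :pB] = XF.T @ XB
    A[pB:, pB:] = XF.T @ XF
    b[:pB] = SBinv_s2 @ np.asarray(mu_B, float) + XB.T @ Y
    b[pB:] = XF.T @ Y
    sol = np.linalg.solve(A, b)
    beta = np.empty(X.shape[1])
    beta[mask], beta[~mask] = sol[:pB], sol[pB:]
    return beta


def posterior_mean_metropolis(X, Y, mu, var, sigma2, n_iter=200_000, step=0.25, seed=0):
    """Posterior mean of beta by random-walk Metropolis on the log posterior.

    Knows only densities: normal likelihood with known sigma2 plus
    independent normal priors.  Returns the post-burn-in mean of the chain.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    mu, var = np.asarray(mu, float), np.asarray(var, float)
    rng = np.random.default_rng(seed)
    p = X.shape[1]

    def logpost(beta):
        resid = Y - X @ beta
        return (
            -0.5 * resid @ resid / sigma2
            - 0.5 * np.sum((beta - mu) ** 2 / var)
        )

    beta = ols_normal_equations(X, Y)
    lp = logpost(beta)
    draws = np.empty((n_iter, p))
    for t in range(n_iter):
        prop = beta + step * rng.standard_normal(p)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
        draws[t] = beta
    return draws[n_iter // 4:].mean(axis=0)


def bh_step_up(pvalues):
    """Textbook Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def hypergeom_upper_tail_exact(r, R, n, N) -> Fraction:
    """Exact rational P(X >= r) for X ~ Hypergeom(N, n, R) via binomials."""
    total = math.comb(N, R)
    acc = Fraction(0)
    for k in range(r, min(R, n) + 1):
        acc += Fraction(math.comb(n, k) * math.comb(N - n, R - k), total)
    return acc


def wald_pvalue(estimate, se):
    return 2 * norm.cdf(-abs(estimate / se))
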