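"""Random-intercept logistic (binomial GLMM) via adaptive Gauss-Hermite quadrature.

Messages are aggregated to school-year binomial counts (covariates are
constant within a cell, so the aggregated binomial likelihood is identical
to the message-level Bernoulli one).  The model for cell i in school g is::

    y_i ~ Binomial(n_i, p_i),   logit p_i = x_i' beta + gamma_g,
    gamma_g ~ N(0, sigma^2)

The marginal likelihood integrates gamma out per school.  Each school's
integral is evaluated by Gauss-Hermite quadrature after centering and
scaling at the conditional mode (adaptive GHQ; 25 nodes by default, which is
far past the accuracy plateau for clusters this large).  The outer
optimization is quasi-Newton over (beta, log sigma); Wald standard errors
come from the numerically differentiated observed information.

By default the outcome is coded Negative = 1 so that exp(beta) is directly
the odds ratio of negative sentiment; fitting the complementary coding
simply flips every coefficient's sign (reciprocal odds ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm

from .simulate import NEGATIVE, NON_NEGATIVE

__all__ = [
    "join_design",
    "aggregate_counts",
    "GLMMResult",
    "RandomInterceptLogit",
    "fit_glmm",
    "report",
]


def join_design(counts: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Join per-school-year counts to design covariates with 0/1 codings.

    Adds ``x_type`` (1 = private), ``x_location`` (1 = small city),
    ``x_year`` (1 = the later year) and ``x_in_person`` (1 = in-person), plus
    ``total`` and ``pct_negative`` if missing.
    """
    missing = set(counts["school_id"]) - set(design["school_id"])
    if missing:
        raise ValueError(f"schools absent from design table: {sorted(missing)}")
    out = counts.merge(
        design[["school_id", "funding", "location", "in_person"]], on="school_id"
    )
    out["x_type"] = (out["funding"] == "private").astype(int)
    out["x_location"] = (out["location"] == "small").astype(int)
    out["x_year"] = (out["year"] == out["year"].max()).astype(int)
    out["x_in_person"] = (out["in_person"] == "yes").astype(int)
    if "total" not in out:
        out["total"] = out["n_negative"] + out["n_nonnegative"]
    if "pct_negative" not in out:
        out["pct_negative"] = 100.0 * out["n_negative"] / out["total"]
    return out


def aggregate_counts(
    messages: pd.DataFrame, design: pd.DataFrame, label_col: str = "final_label"
) -> pd.DataFrame:
    """Per-school-year Negative / non-Negative counts from labelled messages.

    ``messages`` needs ``school_id``, ``year`` and a label column holding
    Negative / nonNegative values.  Returns one row per observed school-year
    with counts, totals, percent Negative, and the joined design covariates.
    """
    if len(messages) == 0:
        return pd.DataFrame(
            columns=["school_id", "year", "n_negative", "n_nonnegative", "total", "pct_negative"]
        )
    labels = messages[label_col]
    bad = set(labels.unique()) - {NEGATIVE, NON_NEGATIVE}
    if bad:
        raise ValueError(f"unrecognized labels: {sorted(bad)}")
    grouped = (
        messages.assign(_neg=(labels == NEGATIVE).astype(int))
        .groupby(["school_id", "year"], as_index=False)
        .agg(n_negative=("_neg", "sum"), total=("_neg", "size"))
    )
    grouped["n_nonnegative"] = grouped["total"] - grouped["n_negative"]
    grouped["pct_negative"] = 100.0 * grouped["n_negative"] / grouped["total"]
    cols = ["school_id", "year", "n_negative", "n_nonnegative", "total", "pct_negative"]
    return join_design(grouped[cols], design)


@dataclass
class GLMMResult:
    """Fitted fixed effects, random-intercept SD, and Wald inference."""

    terms: list
    params: np.ndarray
    se: np.ndarray
    sigma: float
    loglik: float
    n_quad: int
    converged: bool

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "coef": self.params[i],
            "se": self.se[i],
            "odds_ratio": self.odds_ratios[i],
            "pvalue": self.pvalues[i],
        }


class RandomInterceptLogit:
    """Binomial logistic model with one normal random intercept per group."""

    def __init__(self, n_quad: int = 25):
        if n_quad < 1:
            raise ValueError("n_quad must be >= 1")
        self.n_quad = n_quad
        self._nodes, self._weights = hermgauss(n_quad)

    # per-group log integrand pieces -------------------------------------
    @staticmethod
    def _group_loglik_at(u, eta0, y, n):
        """log f(y | u) for scalar or vector u (binomial, logit link)."""
        eta = eta0[:, None] + u[None, :] if np.ndim(u) else eta0 + u
        if np.ndim(u):
            return np.sum(y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta), axis=0)
        return np.sum(y * eta - n * np.logaddexp(0.0, eta))

    def _group_marginal(self, eta0, y, n, sigma):
        """log of the per-group marginal integral over the random intercept."""
        if sigma == 0.0:
            return self._group_loglik_at(0.0, eta0, y, n)
        # conditional mode of h(u) = log f(y|sigma*u) + log phi(u), Newton
        u = 0.0
        for _ in range(100):
            p = expit(eta0 + sigma * u)
            g = sigma * np.sum(y - n * p) - u
            H = -(sigma**2) * np.sum(n * p * (1 - p)) - 1.0
            step = g / H
            u_new = u - step
            if not np.isfinite(u_new):
                break
            u = u_new
            if abs(step) < 1e-10:
                break
        p = expit(eta0 + sigma * u)
        H = -(sigma**2) * np.sum(n * p * (1 - p)) - 1.0
        tau = 1.0 / np.sqrt(-H)
        ut = u + np.sqrt(2.0) * tau * self._nodes
        h = self._group_loglik_at(sigma * ut, eta0, y, n) - 0.5 * ut**2 - 0.5 * np.log(2 * np.pi)
        return float(
            np.log(np.sqrt(2.0) * tau) + logsumexp(self._nodes**2 + np.log(self._weights) + h)
        )

    def _nll(self, theta, X, y, n, group_idx, n_groups, sigma_fixed):
        beta = theta[: X.shape[1]]
        sigma = sigma_fixed if sigma_fixed is not None else float(np.exp(theta[-1]))
        eta0 = X @ beta
        ll = 0.0
        for g in range(n_groups):
            m = group_idx == g
            ll += self._group_marginal(eta0[m], y[m], n[m], sigma)
        return -ll

    def fit(self, X, successes, totals, groups, *, sigma: float | None = None,
            terms: list | None = None) -> GLMMResult:
        """Maximize the marginal likelihood.

        ``X`` is the fixed-effects design (including the intercept column),
        ``successes``/``totals`` the binomial outcome, ``groups`` the cluster
        labels.  ``sigma`` fixes the random-intercept SD (0 gives the plain
        logistic model); otherwise it is estimated on the log scale.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(successes, dtype=float)
        n = np.asarray(totals, dtype=float)
        _, group_idx = np.unique(np.asarray(groups), return_inverse=True)
        n_groups = group_idx.max() + 1
        if n_groups < 2 and sigma is None:
            raise ValueError("need >= 2 groups to estimate a random intercept")
        col_var = X.var(axis=0)
        if np.any(col_var[1:] == 0):
            raise ValueError("non-identifiable design: a covariate is constant")

        k = X.shape[1]
        if sigma is not None:
            x0 = np.zeros(k)
        else:
            # warm-start beta from the fixed-effects-only (sigma = 0) fit
            stage0 = minimize(
                self._nll, np.zeros(k), args=(X, y, n, group_idx, n_groups, 0.0),
                method="BFGS", options={"gtol": 1e-8, "maxiter": 500},
            )
            x0 = np.append(stage0.x, np.log(0.3))
        res = minimize(
            self._nll, x0, args=(X, y, n, group_idx, n_groups, sigma),
            method="BFGS", options={"gtol": 1e-8, "maxiter": 500},
        )
        theta = res.x
        sigma_hat = sigma if sigma is not None else float(np.exp(theta[-1]))
        const = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
        loglik = -res.fun + const

        hess = _num_hessian(
            lambda t: self._nll(t, X, y, n, group_idx, n_groups, sigma), theta
        )
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0.0, None))
        if terms is None:
            terms = ["intercept"] + [f"x{j}" for j in range(1, k)]
        return GLMMResult(
            terms=list(terms), params=theta[:k].copy(), se=se,
            sigma=sigma_hat, loglik=loglik, n_quad=self.n_quad,
            # BFGS often reports precision loss once the finite-difference
            # gradient is at noise level; a tiny gradient still means converged
            converged=bool(res.success or np.max(np.abs(res.jac)) < 1e-2),
        )


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = x.size
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def fit_glmm(
    table: pd.DataFrame,
    terms: list,
    *,
    outcome: str = "negative",
    n_quad: int = 25,
    sigma: float | None = None,
) -> GLMMResult:
    """Fit the random-intercept model to a joined count table.

    ``terms`` are covariate column names (e.g. ``["x_type", "x_location",
    "x_year"]``); an intercept is always included.  ``outcome`` chooses the
    success coding: ``"negative"`` (default; odds ratios of negative
    sentiment, directly comparable to the reported effects) or
    ``"nonnegative"`` (every coefficient flips sign).
    """
    if outcome not in ("negative", "nonnegative"):
        raise ValueError("outcome must be 'negative' or 'nonnegative'")
    successes = table["n_negative"] if outcome == "negative" else table["n_nonnegative"]
    X = np.column_stack([np.ones(len(table))] + [table[t].to_numpy(float) for t in terms])
    model = RandomInterceptLogit(n_quad=n_quad)
    return model.fit(
        X, successes.to_numpy(float), table["total"].to_numpy(float),
        table["school_id"].to_numpy(), sigma=sigma, terms=["intercept"] + list(terms),
    )


def report(fit: GLMMResult) -> pd.DataFrame:
    """Odds ratios with Wald p-values, one row per fixed-effect term."""
    return pd.DataFrame(
        {
            "term": fit.terms,
            "coef": fit.params,
            "se": fit.se,
            "odds_ratio": fit.odds_ratios,
            "pvalue": fit.pvalues,
        }
    )
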