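"""Binomial random-intercept model for indicator-taxon frequency by age.

The proportion of participants in each age class who list an indicator
taxon is modelled on the logit scale as

    logit p_{tk} = beta0 + f(age_k) + u_t,     u_t ~ N(0, sigma^2),

where f is an unpenalized fixed-df smooth of the age-class code (df = 2 by
default) and u_t is a per-taxon random intercept absorbing how generally
well known each taxon is.  The marginal likelihood integrates u_t out by
adaptive Gauss-Hermite quadrature (Laplace-centered, 15 nodes by default)
and is maximized over (beta, log sigma).  The age effect is assessed by a
likelihood-ratio statistic against the model without the smooth, on the
smooth's degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .types import FitError, ParameterError

_REQUIRED = {"taxon", "age_class", "n_listers", "n_in_class"}


def _binom_loglik_terms(
    eta: np.ndarray, succ: np.ndarray, tot: np.ndarray
) -> np.ndarray:
    """Binomial log-likelihood per observation, including the log C(n,k) term."""
    const = (
        special.gammaln(tot + 1)
        - special.gammaln(succ + 1)
        - special.gammaln(tot - succ + 1)
    )
    return const + succ * eta - tot * np.logaddexp(0.0, eta)


def _group_loglik(
    offset: np.ndarray,
    succ: np.ndarray,
    tot: np.ndarray,
    sigma: float,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    """log integral over one group's random intercept, adaptive GH."""

    # Laplace: find the mode of the joint log density by Newton in 1-D
    u_hat = 0.0
    for _ in range(50):
        p = special.expit(offset + u_hat)
        grad = float(np.sum(succ - tot * p)) - u_hat / sigma**2
        hess = -float(np.sum(tot * p * (1 - p))) - 1 / sigma**2
        step = grad / hess
        u_hat -= step
        if abs(step) < 1e-10:
            break
    tau = 1.0 / np.sqrt(-hess)

    z = u_hat + np.sqrt(2.0) * tau * nodes
    eta = offset[:, None] + z[None, :]
    logf = _binom_loglik_terms(eta, succ[:, None], tot[:, None]).sum(
        axis=0
    ) + stats.norm.logpdf(z, scale=sigma)
    # log sum_k w_k exp(nodes_k^2) exp(f(z_k)) + log(sqrt(2) tau)
    return float(
        special.logsumexp(logf + nodes**2 + np.log(weights))
        + 0.5 * np.log(2.0)
        + np.log(tau)
    )


@dataclass
class GlmmFit:
    beta: pd.Series               # fixed effects (intercept + smooth columns)
    sigma: float                  # random-intercept standard deviation
    llf: float
    llf_null: float               # intercept + random intercept only
    lr_stat: float                # 2 * (llf - llf_null)
    lr_df: int
    lr_p: float
    n_groups: int
    n_obs: int
    converged: bool
    fitted: pd.DataFrame | None = None  # per-age-class population-level curve


def _marginal_loglik(
    params: np.ndarray,
    X: np.ndarray,
    succ: np.ndarray,
    tot: np.ndarray,
    group_idx: list[np.ndarray],
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    beta = params[:-1]
    sigma = float(np.exp(params[-1]))
    if not np.isfinite(sigma) or sigma > 50:
        return -np.inf
    eta = X @ beta
    total = 0.0
    for idx in group_idx:
        total += _group_loglik(eta[idx], succ[idx], tot[idx], sigma, nodes, weights)
    return total


def _maximize(
    X: np.ndarray,
    succ: np.ndarray,
    tot: np.ndarray,
    group_idx: list[np.ndarray],
    n_nodes: int,
    start_beta: np.ndarray,
) -> tuple[np.ndarray, float, bool]:
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def neg(params: np.ndarray) -> float:
        return -_marginal_loglik(params, X, succ, tot, group_idx, nodes, weights)

    x0 = np.append(start_beta, np.log(0.5))
    best = None
    for method in ("BFGS", "Nelder-Mead"):
        res = optimize.minimize(
            neg, x0, method=method, options={"maxiter": 2000}
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            best = res if res.fun <= best.fun else best
            break
    if best is None or not np.isfinite(best.fun):
        raise FitError("binomial mixed-model fit failed")
    return best.x, -float(best.fun), bool(best.success)


def fit_binomial_glmm(
    table: pd.DataFrame, df: int = 2, n_nodes: int = 15
) -> GlmmFit:
    """Fit the binomial random-intercept age model to an age-frequency table.

    ``table`` needs columns taxon, age_class, n_listers, n_in_class (one row
    per taxon and age class).  Requires at least 2 taxa (otherwise the random
    intercept is unidentifiable) and at least 3 age classes.
    """
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ParameterError(f"age-frequency table missing columns {sorted(missing)}")
    taxa = table["taxon"].unique()
    if len(taxa) < 2:
        raise ParameterError("need >= 2 taxa to identify the taxon random effect")
    ages = np.sort(table["age_class"].unique())
    if len(ages) < 3:
        raise ParameterError("need >= 3 age classes for the age smooth")

    from .models import spline_basis

    tab = table.reset_index(drop=True)
    succ = tab["n_listers"].to_numpy(float)
    tot = tab["n_in_class"].to_numpy(float)
    if np.any(succ > tot):
        raise ParameterError("n_listers exceeds n_in_class")
    basis = spline_basis(tab["age_class"].to_numpy(float), df)
    X = np.hstack([np.ones((len(tab), 1)), basis])
    colnames = ["(Intercept)"] + [f"s(age).{j + 1}" for j in range(df)]
    group_idx = [
        np.flatnonzero((tab["taxon"] == t).to_numpy()) for t in taxa
    ]

    # starting values from the pooled (no random effect) logistic fit
    import statsmodels.api as sm

    pooled = sm.GLM(
        np.column_stack([succ, tot - succ]), X, family=sm.families.Binomial()
    ).fit()
    params, llf, converged = _maximize(X, succ, tot, group_idx, n_nodes, pooled.params)

    X0 = X[:, :1]
    params0, llf0, _ = _maximize(
        X0, succ, tot, group_idx, n_nodes, pooled.params[:1]
    )
    lr = max(0.0, 2 * (llf - llf0))

    beta = pd.Series(params[:-1], index=colnames)
    # population-level fitted curve per age class (random intercept at 0)
    uniq_idx = [int(np.flatnonzero(tab["age_class"].to_numpy() == a)[0]) for a in ages]
    fitted = pd.DataFrame(
        {
            "age_class": ages,
            "fitted_freq": special.expit(X[uniq_idx] @ params[:-1]),
        }
    )
    return GlmmFit(
        beta=beta,
        sigma=float(np.exp(params[-1])),
        llf=llf,
        llf_null=llf0,
        lr_stat=lr,
        lr_df=df,
        lr_p=float(stats.chi2.sf(lr, df)),
        n_groups=len(taxa),
        n_obs=len(tab),
        converged=converged,
        fitted=fitted,
    )
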