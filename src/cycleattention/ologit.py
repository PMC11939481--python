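"""Cumulative-logit (proportional-odds) model for ordinal attention.

The model for an ordinal response ``F`` with K ordered categories is

    logit P(F <= k) = gamma_k - theta,      theta = sum_p beta_p x_p,

with strictly increasing thresholds ``gamma_1 < ... < gamma_{K-1}``.
Under this sign convention a positive coefficient pushes probability
mass toward higher (more focused) levels, and ``exp(beta)`` is the odds
ratio of higher attention.

Factor coding follows the study's report layout: riding style with
"aggressive" as the reference (so the conservative dummy is estimated)
and traffic density with "dense" as the reference (sparse and moderate
dummies estimated); both references are configurable.

Maximum likelihood uses BFGS with an analytic gradient on the
order-preserving parameterization ``gamma_k = gamma_1 + sum exp(delta)``;
the covariance comes from the inverse observed information in the
natural ``(gamma, beta)`` space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_expit
from statsmodels.tools import numdiff

__all__ = [
    "ModelSpec",
    "OrderedFit",
    "build_design",
    "cumlogit_logprobs",
    "cumlogit_loglik",
    "fit_cumulative_logit",
    "fit_ordered_logit",
    "wald_inference",
    "predict_category",
]

Z_95 = 1.96  # normal quantile used for the reported 95% intervals


@dataclass(frozen=True)
class ModelSpec:
    """Response/predictor layout of the attention models."""

    response: str = "attention_level"
    style_col: str = "riding_style"
    style_ref: str = "aggressive"
    density_col: str = "traffic_density"
    density_ref: str = "dense"
    # hierarchical extras (ignored by the flat model)
    covariates: tuple[str, ...] = ("lane_fixation_share", "pupil_cv")
    group_col: str = "cyclist"


def build_design(trials: pd.DataFrame, spec: ModelSpec = ModelSpec()):
    """Dummy-coded design matrix (reference levels omitted).

    Returns ``(y, X, names)`` with ``y`` the integer levels and ``X`` one
    column per non-reference factor level, ordered style-then-density.
    """
    y = trials[spec.response].to_numpy(dtype=int)
    cols, names = [], []
    for col, ref in ((spec.style_col, spec.style_ref),
                     (spec.density_col, spec.density_ref)):
        levels = [l for l in pd.unique(trials[col]) if l != ref]
        if ref not in set(trials[col]):
            warnings.warn(f"reference level {ref!r} absent from {col!r}")
        for l in sorted(levels):
            cols.append((trials[col] == l).to_numpy(dtype=float))
            names.append(f"{col}[{l}]")
    X = np.column_stack(cols) if cols else np.empty((len(trials), 0))
    return y, X, names


def cumlogit_logprobs(gamma: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Log category probabilities, shape (n, K); stable in the tails.

    ``gamma`` are K-1 increasing thresholds, already including any
    per-observation shift if hierarchical; ``eta`` the linear predictor.
    ``gamma`` may be (K-1,) or (n, K-1).
    """
    g = np.atleast_2d(np.asarray(gamma, dtype=float))
    eta = np.asarray(eta, dtype=float)
    margins = g - eta[:, None] if g.shape[0] == len(eta) else g[0][None, :] - eta[:, None]
    lc = log_expit(margins)            # log P(F <= k)
    ls = log_expit(-margins)           # log P(F > k)
    n, km1 = margins.shape
    out = np.empty((n, km1 + 1))
    out[:, 0] = lc[:, 0]
    out[:, -1] = ls[:, -1]
    for k in range(1, km1):
        # log(P(F<=k+1) - P(F<=k)) via log-diff-exp on the cumulative scale
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, k] = lc[:, k] + np.log1p(-np.exp(lc[:, k - 1] - lc[:, k]))
    return out


def cumlogit_loglik(gamma, eta, y) -> float:
    """Sum of log category probabilities of the observed levels (1-based)."""
    lp = cumlogit_logprobs(gamma, eta)
    picked = lp[np.arange(len(eta)), np.asarray(y, dtype=int) - 1]
    if not np.isfinite(picked).all():
        return -np.inf
    return float(picked.sum())


@dataclass
class OrderedFit:
    gamma: np.ndarray
    beta: np.ndarray
    names: list
    cov: np.ndarray                  # over (gamma..., beta...)
    loglik: float
    n_obs: int
    converged: bool
    grad_norm: float
    n_iter: int
    spec: ModelSpec | None = None

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.gamma, self.beta])

    @property
    def param_names(self) -> list:
        return [f"threshold[{k+1}]" for k in range(len(self.gamma))] + list(self.names)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        """Parameter table in the study's report layout (Wald, 95% CI, OR)."""
        tab = wald_inference(self.params, self.se)
        tab.index = self.param_names
        tab["odds_ratio"] = np.exp(tab["estimate"])
        tab["loglik"] = self.loglik
        return tab


def _pack(gamma, beta):
    g = np.asarray(gamma, dtype=float)
    return np.concatenate([[g[0]], np.log(np.diff(g)), np.asarray(beta, dtype=float)])


def _unpack(t, km1, p):
    g = np.empty(km1)
    g[0] = t[0]
    if km1 > 1:
        g[1:] = t[0] + np.cumsum(np.exp(t[1:km1]))
    return g, t[km1:km1 + p]


def _score_natural(gamma, beta, y, X):
    """Analytic gradient of the log-likelihood in (gamma, beta) space."""
    km1, p = len(gamma), X.shape[1]
    eta = X @ beta if p else np.zeros(len(y))
    margins = gamma[None, :] - eta[:, None]
    s = expit(margins)
    dens = s * (1.0 - s)
    lp = cumlogit_logprobs(gamma, eta)
    probs = np.exp(lp)
    n = len(y)
    d_margin = np.zeros((n, km1))
    yi = y - 1
    for k in range(km1 + 1):
        sel = yi == k
        if not sel.any():
            continue
        pk = np.maximum(probs[sel, k], 1e-300)
        if k < km1:
            d_margin[sel, k] += dens[sel, k] / pk
        if k > 0:
            d_margin[sel, k - 1] -= dens[sel, k - 1] / pk
    dg = d_margin.sum(axis=0)
    db = -(d_margin.sum(axis=1) @ X) if p else np.empty(0)
    return dg, db


def fit_cumulative_logit(
    y: np.ndarray,
    X: np.ndarray,
    names=None,
    tol: float = 1e-10,
    gtol: float = 1e-8,
    max_iter: int = 100,
) -> OrderedFit:
    """Maximum-likelihood fit of the cumulative-logit model.

    ``y`` holds 1-based ordinal levels; every level between 1 and
    max(y) must be observed.  Raises on empty categories or a
    rank-deficient design; non-convergence is reported on the fit
    object together with the gradient norm.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    K = int(y.max())
    counts = np.bincount(y, minlength=K + 1)[1:]
    if y.min() < 1 or (counts == 0).any():
        raise ValueError(f"every category 1..{K} needs observations; counts={counts}")
    p = X.shape[1]
    if p and np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    km1 = K - 1

    cum = np.cumsum(counts)[:-1] / len(y)
    g0 = np.log(cum / (1 - cum))
    t0 = _pack(g0, np.zeros(p))

    def negloglik(t):
        g, b = _unpack(t, km1, p)
        eta = X @ b if p else np.zeros(len(y))
        return -cumlogit_loglik(g, eta, y)

    def neggrad(t):
        g, b = _unpack(t, km1, p)
        dg, db = _score_natural(g, b, y, X)
        # chain rule to (gamma_1, delta...) space
        dt = np.empty_like(t)
        dt[0] = dg.sum()
        for k in range(1, km1):
            dt[k] = dg[k:].sum() * np.exp(t[k])
        dt[km1:] = db
        return -dt

    res = optimize.minimize(
        negloglik, t0, jac=neggrad, method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    gamma, beta = _unpack(res.x, km1, p)
    grad_norm = float(np.max(np.abs(neggrad(res.x))))
    converged = bool(res.success) or grad_norm < 1e-5
    if not converged:
        warnings.warn(
            f"ordered-logit fit did not converge (grad inf-norm {grad_norm:.3g}); "
            "possible separation or empty-cell pattern"
        )

    def negloglik_natural(q):
        return -cumlogit_loglik(q[:km1], X @ q[km1:] if p else np.zeros(len(y)), y)

    H = numdiff.approx_hess1(np.concatenate([gamma, beta]), negloglik_natural)
    try:
        cov = np.linalg.inv(H)
        if (np.diag(cov) <= 0).any():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("observed information not positive definite; "
                      "covariance set to NaN")
        cov = np.full((km1 + p, km1 + p), np.nan)
    return OrderedFit(
        gamma=gamma, beta=beta, names=names, cov=cov,
        loglik=-float(res.fun), n_obs=len(y), converged=converged,
        grad_norm=grad_norm, n_iter=int(res.nit),
    )


def fit_ordered_logit(trials: pd.DataFrame, spec: ModelSpec = ModelSpec(),
                      **kwargs) -> OrderedFit:
    """Fit the baseline model from a trial table using the study coding."""
    y, X, names = build_design(trials, spec)
    fit = fit_cumulative_logit(y, X, names, **kwargs)
    fit.spec = spec
    return fit


def wald_inference(estimates, ses) -> pd.DataFrame:
    """Wald chi-square tests and 95% CIs from estimates and standard errors.

    ``wald = (estimate/se)^2`` referred to chi-square(1);
    ``CI = estimate +/- 1.96 * se``.
    """
    est = np.atleast_1d(np.asarray(estimates, dtype=float))
    se = np.atleast_1d(np.asarray(ses, dtype=float))
    if (se < 0).any():
        raise ValueError("standard errors must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, (est / se) ** 2, np.inf)
    pvals = stats.chi2.sf(wald, df=1)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "wald": wald,
            "p": pvals,
            "ci_lower": est - Z_95 * se,
            "ci_upper": est + Z_95 * se,
        }
    )


def predict_category(fit: OrderedFit, X) -> tuple[np.ndarray, np.ndarray]:
    """Modal predicted level and category probabilities per row."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = X @ fit.beta if X.shape[1] else np.zeros(len(X))
    probs = np.exp(cumlogit_logprobs(fit.gamma, eta))
    return probs.argmax(axis=1) + 1, probs


def predict_trials(fit: OrderedFit, trials: pd.DataFrame):
    """Predict from a trial table using the fit's factor coding."""
    if fit.spec is None:
        raise ValueError("fit carries no ModelSpec; use predict_category")
    y, X, names = build_design(trials, fit.spec)
    if names != fit.names:
        raise ValueError(f"factor levels {names} do not match fit {fit.names}")
    return predict_category(fit, X)
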