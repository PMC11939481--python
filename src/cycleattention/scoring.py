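"""Composite attention scoring.

The per-trial indicator vectors are standardized and reduced by
principal component analysis on the correlation matrix; components with
eigenvalue above 1 are retained (falling back to the first component if
none qualifies) and combined into a single composite score with
eigenvalue-proportional weights.  Component signs are oriented so each
retained component correlates positively with the fixation-time
percentage, making "higher composite = more focused" the fixed reading.
The composite is cut into three ordered levels (1 Distracted,
2 Scattered, 3 Focused) by equal-frequency tertiles.

Candidate design factors (slope, traffic density, riding style) are
screened by classical one-way ANOVA on the composite.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_INDICATORS",
    "Scaler",
    "PCAScore",
    "standardize_indicators",
    "pca_composite_score",
    "categorize_attention",
    "apply_cutpoints",
    "screen_factors_anova",
]

#: The seven indicators carried into the composite (the region-resolved
#: "fixation time distribution" is operationalized as the lane share).
DEFAULT_INDICATORS = (
    "fixation_time_pct",
    "saccade_time_pct",
    "blink_freq_per_min",
    "pupil_mean_mm",
    "avg_fixation_ms",
    "avg_saccade_ms",
    "lane_fixation_share",
)

ORIENT_COLUMN = "fixation_time_pct"


@dataclass(frozen=True)
class Scaler:
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    dropped: tuple[str, ...] = ()

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[list(self.columns)] - self.means) / self.sds

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        return z[list(self.columns)] * self.sds + self.means


def standardize_indicators(
    table: pd.DataFrame, columns=None
) -> tuple[pd.DataFrame, Scaler]:
    """Center and scale each indicator column to mean 0, SD 1.

    Zero-variance columns are dropped with a warning (they carry no
    ordering information and would break the correlation matrix).
    Returns the standardized table and the fitted :class:`Scaler`.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    if len(table) < 2:
        raise ValueError("need at least two rows to standardize")
    sub = table[cols].astype(float)
    sds = sub.std(ddof=1)
    dead = [c for c in cols if not np.isfinite(sds[c]) or sds[c] == 0.0]
    if dead:
        logger.warning("dropping zero-variance indicator(s): %s", dead)
        cols = [c for c in cols if c not in dead]
        sub = sub[cols]
        sds = sds[cols]
    means = sub.mean()
    scaler = Scaler(tuple(cols), means.to_numpy(), sds.to_numpy(), tuple(dead))
    return (sub - means) / sds, scaler


@dataclass(frozen=True)
class PCAScore:
    """Fitted composite-score parameters (loadings, weights, cut points)."""

    columns: tuple[str, ...]
    eigenvalues: np.ndarray          # all, descending
    loadings: np.ndarray             # (n_indicators, n_retained), unit norm
    weights: np.ndarray              # eigenvalue-proportional, sum 1
    cutpoints: np.ndarray | None = None
    scaler: Scaler | None = None

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]

    def score(self, z: pd.DataFrame | np.ndarray) -> np.ndarray:
        zz = z[list(self.columns)].to_numpy() if isinstance(z, pd.DataFrame) else np.asarray(z)
        return (zz @ self.loadings) @ self.weights

    def to_json(self, path) -> None:
        payload = {
            "columns": list(self.columns),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "weights": self.weights.tolist(),
            "cutpoints": None if self.cutpoints is None else self.cutpoints.tolist(),
        }
        if self.scaler is not None:
            payload["scaler"] = {
                "columns": list(self.scaler.columns),
                "means": self.scaler.means.tolist(),
                "sds": self.scaler.sds.tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def pca_composite_score(
    z: pd.DataFrame,
    indicators=None,
    retention_threshold: float = 1.0,
) -> tuple[np.ndarray, PCAScore]:
    """Eigenvalue-weighted principal-component composite of standardized indicators.

    Eigendecomposition of the correlation matrix of ``z`` (which must
    already be standardized, so the correlation matrix is its covariance);
    components with eigenvalue > ``retention_threshold`` are kept — if
    none passes, the leading component is kept — and the composite is
    ``sum_r w_r * score_r`` with ``w_r = lambda_r / sum(retained lambda)``.
    """
    cols = list(indicators) if indicators is not None else list(z.columns)
    missing = [c for c in cols if c not in z.columns]
    if missing:
        raise ValueError(f"indicators not in table: {missing}")
    zz = z[cols].to_numpy(dtype=float)
    if zz.shape[0] < 2:
        raise ValueError("need at least two rows for PCA")
    corr = np.corrcoef(zz, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > retention_threshold
    if not keep.any():
        keep[0] = True
    loadings = evecs[:, keep]
    # orient each component to correlate positively with fixation share
    if ORIENT_COLUMN in cols:
        ref = zz[:, cols.index(ORIENT_COLUMN)]
    else:
        ref = zz[:, 0]
    comp_scores = zz @ loadings
    for r in range(loadings.shape[1]):
        c = np.corrcoef(ref, comp_scores[:, r])[0, 1]
        if c < 0 or (c == 0 and loadings[0, r] < 0):
            loadings[:, r] *= -1.0
    lam = evals[keep]
    weights = lam / lam.sum()
    composites = (zz @ loadings) @ weights
    fit = PCAScore(tuple(cols), evals.copy(), loadings, weights)
    return composites, fit


def categorize_attention(
    composites, n_levels: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency ordinal levels from composite scores.

    Scores are ranked (stable order breaks ties deterministically) and
    split into ``n_levels`` groups as equal as integer division allows;
    higher composite -> higher level (3 = Focused).  Returns the level
    array and the fitted cut points (upper score boundary of each level
    but the last), reusable via :func:`apply_cutpoints`.
    """
    x = np.asarray(composites, dtype=float)
    n = len(x)
    if n < n_levels:
        raise ValueError(f"need at least {n_levels} scores")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    base, rem = divmod(n, n_levels)
    sizes = [base + (1 if i < rem else 0) for i in range(n_levels)]
    bounds = np.cumsum(sizes)
    levels = 1 + np.searchsorted(bounds - 1, ranks)
    if len(np.unique(x)) < n:
        # ties spanning a boundary are split by stable input order
        for b in bounds[:-1]:
            lo, hi = x[order[b - 1]], x[order[b]]
            if lo == hi:
                warnings.warn("tied scores at a tertile boundary; "
                              "stable-order tie-break applied")
                break
    cutpoints = np.array([(x[order[b - 1]] + x[order[b]]) / 2.0
                          for b in bounds[:-1]])
    return levels.astype(int), cutpoints


def apply_cutpoints(composites, cutpoints) -> np.ndarray:
    """Re-apply fitted cut points to new composite scores."""
    return 1 + np.searchsorted(np.asarray(cutpoints),
                               np.asarray(composites, dtype=float),
                               side="right").astype(int)


def screen_factors_anova(
    table: pd.DataFrame, factor: str, response: str = "composite"
) -> tuple[float, float]:
    """Classical one-way ANOVA of ``response`` across ``factor`` groups.

    Returns ``(F, p)``.  Requires at least two groups with at least two
    observations each.
    """
    groups = [g[response].to_numpy(dtype=float)
              for _, g in table.groupby(factor, observed=True)]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
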