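"""Synthetic study-design generator.

Emulates the campus cycling experiment: ``n_cyclists`` riders each cover
every road section in both directions during a peak and an off-peak
period, giving ``n_cyclists x n_sections x 2 x 2`` design cells (108 for
the default 9-rider, 3-section layout).  A small random fraction of
trials is lost to recording attrition, mirroring the 108 -> ~97 valid
trial bookkeeping of such eye-tracking field studies.

Ordinal attention levels are drawn from the hierarchical ordered
logistic model with known "true" parameters, so every downstream stage
(scoring, both model fits, evaluation) can be tested end-to-end against
a known generating process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "Section",
    "DesignSpec",
    "TrueParams",
    "generate_design",
    "simulate_trials",
    "simulate_gaze_stream",
    "category_probs",
]

LEVELS = (1, 2, 3)  # 1 Distracted, 2 Scattered, 3 Focused


@dataclass(frozen=True)
class Section:
    label: str
    length_m: float
    grade_pct: float


#: The three campus road sections used in the study design.
DEFAULT_SECTIONS = (
    Section("A", 104.0, 7.9),
    Section("B", 90.0, 4.4),
    Section("C", 120.0, 0.0),
)


@dataclass(frozen=True)
class DesignSpec:
    """Factorial trial layout of the riding experiment.

    ``attrition_rate`` is the per-trial probability that a recording is
    unusable (default 11/108, the study's observed loss).  Traffic
    density is tied to the time period (peak -> dense, offpeak ->
    sparse); ``moderate_fraction`` of cells are relabelled "moderate" so
    all three density levels occur.
    """

    n_cyclists: int = 9
    sections: tuple[Section, ...] = DEFAULT_SECTIONS
    directions: tuple[str, ...] = ("outbound", "return")
    periods: tuple[str, ...] = ("peak", "offpeak")
    attrition_rate: float = 11.0 / 108.0
    period_density: dict = field(
        default_factory=lambda: {"peak": "dense", "offpeak": "sparse"}
    )
    moderate_fraction: float = 0.25

    @property
    def n_cells(self) -> int:
        return (
            self.n_cyclists
            * len(self.sections)
            * len(self.directions)
            * len(self.periods)
        )

    def validate(self) -> None:
        if self.n_cyclists < 1:
            raise ValueError("n_cyclists must be a positive integer")
        if not self.sections or not self.directions or not self.periods:
            raise ValueError("sections, directions and periods must be non-empty")
        if not 0.0 <= self.attrition_rate < 1.0:
            raise ValueError("attrition_rate must lie in [0, 1)")
        if not 0.0 <= self.moderate_fraction <= 1.0:
            raise ValueError("moderate_fraction must lie in [0, 1]")
        missing = [p for p in self.periods if p not in self.period_density]
        if missing:
            raise ValueError(f"period_density lacks entries for {missing}")


@dataclass(frozen=True)
class TrueParams:
    """Known generating parameters of the hierarchical ordinal model.

    ``gamma`` are the ordered base thresholds; ``beta_*`` the dummy
    coefficients of the conservative-style and sparse/moderate-density
    indicators (aggressive and dense are the references, coefficient 0);
    ``alpha`` shifts the thresholds by the two trial covariates
    (lane-fixation share, pupil-diameter CV); ``tau`` is the precision
    of the zero-mean cyclist random effect B_j ~ Normal(0, 1/tau).
    """

    gamma: tuple[float, float] = (0.1, 1.5)
    beta_conservative: float = 1.2
    beta_sparse: float = 2.0
    beta_moderate: float = 0.9
    alpha: tuple[float, float] = (3.0, -9.5)
    tau: float = 4.0
    # covariate distributions (lane share ~ Beta, pupil CV ~ Normal>0)
    lane_share_mean: float = 0.60
    lane_share_conc: float = 20.0
    pupil_cv_mean: float = 0.10
    pupil_cv_sd: float = 0.03
    # speed model feeding the style-assignment rule (m/s)
    speed_mean: float = 4.2
    speed_between_sd: float = 0.8
    speed_within_sd: float = 0.3
    # per-trial indicator targets used when emitting gaze streams
    pupil_mean_mm: float = 4.0
    pupil_between_sd: float = 0.25

    def validate(self) -> None:
        if not self.gamma[0] < self.gamma[1]:
            raise ValueError("gamma must be strictly increasing")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("lane_share_conc", "pupil_cv_sd", "speed_between_sd",
                     "speed_within_sd", "pupil_between_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.lane_share_mean < 1.0:
            raise ValueError("lane_share_mean must lie in (0, 1)")

    @property
    def beta(self) -> np.ndarray:
        return np.array(
            [self.beta_conservative, self.beta_sparse, self.beta_moderate]
        )


def generate_design(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Lay out one skeleton row per design cell.

    Returns a frame with columns ``cyclist, section, direction, period,
    traffic_density`` — factors only, no responses yet.  Deterministic
    given ``seed`` (randomness enters only through the moderate-density
    relabelling).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(1, spec.n_cyclists + 1):
        for sec in spec.sections:
            for d in spec.directions:
                for p in spec.periods:
                    rows.append(
                        {
                            "cyclist": j,
                            "section": sec.label,
                            "direction": d,
                            "period": p,
                            "traffic_density": spec.period_density[p],
                        }
                    )
    df = pd.DataFrame(rows)
    if spec.moderate_fraction > 0:
        relabel = rng.random(len(df)) < spec.moderate_fraction
        df.loc[relabel, "traffic_density"] = "moderate"
    return df


def category_probs(gamma: np.ndarray, theta, shift=0.0) -> np.ndarray:
    """Three-category probabilities of the cumulative-logit model.

    ``P(F <= k) = logistic(gamma_k + shift - theta)``; ``shift`` carries
    the covariate and random-effect displacement of the thresholds.
    Accepts scalars or aligned arrays; returns shape ``(n, 3)``.
    """
    g1, g2 = gamma
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    shift = np.broadcast_to(np.asarray(shift, dtype=float), theta.shape)
    c1 = expit(g1 + shift - theta)
    c2 = expit(g2 + shift - theta)
    return np.column_stack([c1, c2 - c1, 1.0 - c2])


def simulate_trials(
    skeletons: pd.DataFrame,
    params: TrueParams,
    seed: int,
    attrition_rate: float = 0.0,
    return_latent: bool = False,
):
    """Fill design skeletons with covariates, factors and attention levels.

    For each cyclist a random effect ``B_j ~ Normal(0, 1/tau)`` and a
    base speed are drawn; each trial draws a speed around the cyclist's
    base, and riding style is assigned by the speed rule (strictly above
    the grand mean speed -> aggressive).  Trial covariates (lane-fixation
    share, pupil CV) are drawn from their configured distributions, the
    linear predictor and shifted thresholds are formed, and the ordinal
    attention level is sampled from the implied three-category
    distribution.  Indicator columns (fixation %, blink rate, pupil
    stats, ...) correlated with the drawn level are added so the PCA
    scoring stage has realistic inputs.

    With ``attrition_rate > 0`` each trial is independently dropped with
    that probability.  ``return_latent=True`` additionally returns a dict
    with the per-cyclist random effects and the per-trial true category
    probabilities (before attrition).
    """
    params.validate()
    if not 0.0 <= attrition_rate < 1.0:
        raise ValueError("attrition_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    df = skeletons.reset_index(drop=True).copy()
    n = len(df)
    cyclists = np.sort(df["cyclist"].unique())
    j_index = pd.Series(np.arange(len(cyclists)), index=cyclists)
    jj = j_index[df["cyclist"]].to_numpy()

    b = rng.normal(0.0, 1.0 / math.sqrt(params.tau), size=len(cyclists))
    base_speed = rng.normal(params.speed_mean, params.speed_between_sd,
                            size=len(cyclists))
    speed = rng.normal(base_speed[jj], params.speed_within_sd)
    # strictly-greater-than-grand-mean rule for the aggressive label
    df["speed_mps"] = speed
    df["riding_style"] = np.where(speed > speed.mean(), "aggressive",
                                  "conservative")

    a = params.lane_share_mean * params.lane_share_conc
    bb = (1.0 - params.lane_share_mean) * params.lane_share_conc
    df["lane_fixation_share"] = rng.beta(a, bb, size=n)
    pcv = rng.normal(params.pupil_cv_mean, params.pupil_cv_sd, size=n)
    while (pcv <= 0).any():  # truncate at zero by redrawing
        bad = pcv <= 0
        pcv[bad] = rng.normal(params.pupil_cv_mean, params.pupil_cv_sd,
                              size=int(bad.sum()))
    df["pupil_cv"] = pcv

    x_cons = (df["riding_style"] == "conservative").to_numpy(float)
    x_sparse = (df["traffic_density"] == "sparse").to_numpy(float)
    x_mod = (df["traffic_density"] == "moderate").to_numpy(float)
    theta = (params.beta_conservative * x_cons
             + params.beta_sparse * x_sparse
             + params.beta_moderate * x_mod)
    shift = (params.alpha[0] * df["lane_fixation_share"].to_numpy()
             + params.alpha[1] * df["pupil_cv"].to_numpy()
             + b[jj])
    probs = category_probs(np.asarray(params.gamma), theta, shift)
    if not np.isfinite(probs).all():
        raise FloatingPointError("overflow in logistic category probabilities")
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    level = 1 + (u[:, None] > cum).sum(axis=1)
    df["attention_level"] = level.astype(int)

    _add_indicator_targets(df, params, level, rng)

    if attrition_rate > 0:
        keep = rng.random(n) >= attrition_rate
        df = df[keep].reset_index(drop=True)

    if return_latent:
        latent = {"b": dict(zip(cyclists.tolist(), b.tolist())),
                  "probs": probs, "theta": theta, "shift": shift}
        return df, latent
    return df


def _add_indicator_targets(df: pd.DataFrame, params: TrueParams,
                           level: np.ndarray, rng: np.random.Generator) -> None:
    """Attach eye-tracking indicator columns correlated with attention.

    Focused trials spend more time fixating (and less saccading), blink
    less, and hold longer fixations; values are clipped to physically
    plausible ranges.
    """
    n = len(df)
    f = level.astype(float)
    fix = np.clip(rng.normal(0.42 + 0.06 * f, 0.05), 0.05, 0.90)
    sac = np.clip(rng.normal(0.30 - 0.03 * f, 0.04), 0.03, None)
    sac = np.minimum(sac, 0.95 - fix)  # leave room for blinks/other
    blink = np.clip(rng.normal(22.0 - 3.0 * f, 3.0), 2.0, None)
    df["fixation_time_pct"] = fix
    df["saccade_time_pct"] = sac
    df["blink_freq_per_min"] = blink
    df["avg_fixation_ms"] = np.clip(rng.normal(180 + 60 * f, 30), 60, None)
    df["avg_saccade_ms"] = np.clip(rng.normal(70 - 5 * f, 8), 20, None)
    df["pupil_mean_mm"] = np.clip(
        rng.normal(params.pupil_mean_mm, params.pupil_between_sd, size=n),
        2.0, 8.0)
    df["pupil_sd_mm"] = df["pupil_cv"] * df["pupil_mean_mm"]


def simulate_gaze_stream(
    trial,
    seed: int,
    duration_s: float = 60.0,
    rate_hz: float = 50.0,
    avg_blink_ms: float = 150.0,
    avg_fixation_ms: float | None = None,
) -> pd.DataFrame:
    """Emit a labelled 50 Hz gaze-sample stream matching trial targets.

    ``trial`` is a mapping (e.g. a trial-table row) with targets
    ``fixation_time_pct``, ``saccade_time_pct``, ``blink_freq_per_min``,
    ``lane_fixation_share``, ``pupil_mean_mm``, ``pupil_sd_mm``.  The
    stream is built from contiguous event runs whose sample counts match
    the targeted shares to within one sample, and pupil draws are
    rescaled so their population mean/SD hit the targets exactly; the
    round trip through :func:`cycleattention.gaze.compute_trial_metrics`
    therefore recovers the targets to well within 2 %.

    Blink samples carry a missing pupil diameter.  Columns:
    ``time_ms, event, pupil_mm, aoi``.
    """
    t = dict(trial)
    fix_pct = float(t["fixation_time_pct"])
    sac_pct = float(t["saccade_time_pct"])
    blink_pm = float(t["blink_freq_per_min"])
    lane = float(t["lane_fixation_share"])
    pmean = float(t["pupil_mean_mm"])
    psd = float(t["pupil_sd_mm"])
    for name, v in (("fixation_time_pct", fix_pct),
                    ("saccade_time_pct", sac_pct),
                    ("lane_fixation_share", lane)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if psd < 0 or pmean <= 0:
        raise ValueError("pupil targets must satisfy mean > 0 and sd >= 0")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    dt_ms = 1000.0 / rate_hz

    n_blink_runs = int(round(blink_pm * duration_s / 60.0))
    blink_run_len = max(1, int(round(avg_blink_ms / dt_ms)))
    n_blink = n_blink_runs * blink_run_len
    n_fix = int(round(fix_pct * n))
    n_sac = int(round(sac_pct * n))
    if n_fix + n_sac + n_blink > n:
        raise ValueError("targets exceed the stream duration")

    if avg_fixation_ms is None:
        avg_fixation_ms = float(t.get("avg_fixation_ms", 300.0))
    fix_run_len = max(1, int(round(avg_fixation_ms / dt_ms)))
    n_fix_runs = max(1, int(round(n_fix / fix_run_len))) if n_fix else 0
    n_sac_runs = max(n_fix_runs, 1) if n_sac else 0

    events: list[str] = []
    fix_sizes = _split_sizes(n_fix, n_fix_runs)
    sac_sizes = _split_sizes(n_sac, n_sac_runs)
    other_total = n - n_fix - n_sac - n_blink
    other_sizes = _split_sizes(other_total, max(n_fix_runs, 1))
    blink_sizes = [blink_run_len] * n_blink_runs
    # interleave fixation / saccade / blink / other runs
    k = max(len(fix_sizes), len(sac_sizes), len(blink_sizes), len(other_sizes))
    for i in range(k):
        if i < len(fix_sizes):
            events.extend(["fixation"] * fix_sizes[i])
        if i < len(sac_sizes):
            events.extend(["saccade"] * sac_sizes[i])
        if i < len(blink_sizes):
            events.extend(["blink"] * blink_sizes[i])
        if i < len(other_sizes):
            events.extend(["other"] * other_sizes[i])
    events = events[:n]
    ev = np.array(events)

    aoi = np.full(n, "none", dtype=object)
    fix_idx = np.flatnonzero(ev == "fixation")
    n_lane = int(round(lane * len(fix_idx)))
    lane_pick = rng.permutation(len(fix_idx))[:n_lane]
    aoi[fix_idx] = "left"
    aoi[fix_idx[len(fix_idx) // 2:]] = "right"
    aoi[fix_idx[lane_pick]] = "lane"

    pupil = np.full(n, np.nan)
    seen = ev != "blink"
    m = int(seen.sum())
    draws = rng.normal(size=m)
    if m > 1 and psd > 0:
        draws = (draws - draws.mean()) / draws.std()  # population SD
        pupil[seen] = pmean + psd * draws
    else:
        pupil[seen] = pmean
    if (pupil[seen] <= 0).any():
        pupil[seen] = np.clip(pupil[seen], 1e-3, None)

    return pd.DataFrame(
        {
            "time_ms": np.arange(n) * dt_ms,
            "event": ev,
            "pupil_mm": pupil,
            "aoi": aoi,
        }
    )


def _split_sizes(total: int, parts: int) -> list[int]:
    if parts <= 0 or total <= 0:
        return []
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]
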