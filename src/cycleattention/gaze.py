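"""Per-trial eye-tracking indicators from labelled gaze-sample streams.

A stream is a table of device samples (``time_ms, event, pupil_mm,
aoi``) with events already classified by the recording platform as
fixation / saccade / blink / other and fixations tagged with an
area-of-interest (driving lane, left side, right side, none).  This
module reduces one stream to the indicator vector used for attention
scoring: event-time percentages, blink rate, mean event durations,
pupil-diameter statistics, the lane-fixation share and the pupil
coefficient of variation (SD over mean).

Duration attribution: each sample owns the interval up to the next
sample; the final sample owns the median inter-sample gap.  On an
even-rate stream this reduces to counting samples.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TrialMetrics",
    "compute_trial_metrics",
    "lane_fixation_share",
    "pupil_cv",
    "read_gaze_csv",
    "write_gaze_csv",
]

EVENTS = ("fixation", "saccade", "blink", "other")
AOIS = ("lane", "left", "right", "none")


@dataclass(frozen=True)
class TrialMetrics:
    """Indicator vector of one trial; time shares in [0, 1], durations in ms."""

    fixation_time_pct: float
    saccade_time_pct: float
    blink_freq_per_min: float
    avg_fixation_ms: float
    avg_saccade_ms: float
    avg_blink_ms: float
    pupil_mean_mm: float
    pupil_sd_mm: float
    pupil_max_mm: float
    pupil_min_mm: float
    lane_fixation_share: float
    pupil_cv: float

    def as_dict(self) -> dict:
        return asdict(self)


def _durations_ms(time_ms: np.ndarray) -> np.ndarray:
    """Per-sample owned duration (interval to next; median gap for last)."""
    if len(time_ms) == 1:
        return np.array([1.0])
    gaps = np.diff(time_ms)
    if (gaps < 0).any():
        raise ValueError("sample times must be non-decreasing")
    return np.append(gaps, np.median(gaps))


def compute_trial_metrics(stream: pd.DataFrame, pupil_ddof: int = 0) -> TrialMetrics:
    """Reduce one labelled gaze stream to its indicator vector.

    ``pupil_ddof=0`` (population SD) matches the descriptive use of the
    pupil coefficient of variation; pass 1 for the sample SD.
    Raises on an empty stream; an all-blink stream (no pupil samples)
    yields NaN pupil statistics.
    """
    if len(stream) == 0:
        raise ValueError("empty gaze stream")
    t = stream["time_ms"].to_numpy(dtype=float)
    dur = _durations_ms(t)
    total = dur.sum()
    ev = stream["event"].to_numpy()

    def share(name: str) -> float:
        return float(dur[ev == name].sum() / total)

    run_id = np.concatenate([[0], np.cumsum(ev[1:] != ev[:-1])])
    run_ev = ev[np.concatenate([[True], ev[1:] != ev[:-1]])]
    run_dur = np.bincount(run_id, weights=dur)

    def avg_run_ms(name: str) -> float:
        d = run_dur[run_ev == name]
        return float(d.mean()) if len(d) else float("nan")

    n_blinks = int((run_ev == "blink").sum())
    minutes = total / 60000.0

    pupil = stream["pupil_mm"].to_numpy(dtype=float)
    pupil = pupil[np.isfinite(pupil)]
    if len(pupil) and (pupil <= 0).any():
        raise ValueError("pupil_mm must be positive where present")
    if len(pupil):
        pm = float(pupil.mean())
        ps = float(pupil.std(ddof=pupil_ddof)) if len(pupil) > pupil_ddof else float("nan")
        pmax, pmin = float(pupil.max()), float(pupil.min())
        cv = ps / pm if np.isfinite(ps) else float("nan")
    else:
        pm = ps = pmax = pmin = cv = float("nan")

    fix_mask = ev == "fixation"
    if fix_mask.any():
        lane = float(dur[fix_mask & (stream["aoi"].to_numpy() == "lane")].sum()
                     / dur[fix_mask].sum())
    else:
        lane = float("nan")

    return TrialMetrics(
        fixation_time_pct=share("fixation"),
        saccade_time_pct=share("saccade"),
        blink_freq_per_min=n_blinks / minutes,
        avg_fixation_ms=avg_run_ms("fixation"),
        avg_saccade_ms=avg_run_ms("saccade"),
        avg_blink_ms=avg_run_ms("blink"),
        pupil_mean_mm=pm,
        pupil_sd_mm=ps,
        pupil_max_mm=pmax,
        pupil_min_mm=pmin,
        lane_fixation_share=lane,
        pupil_cv=cv,
    )


def lane_fixation_share(stream: pd.DataFrame) -> float:
    """Fixation time on the driving-lane AOI over total fixation time.

    All fixation samples count in the denominator, including fixations
    outside any named AOI.  Raises if the stream holds no fixations
    (the ratio is undefined).
    """
    ev = stream["event"].to_numpy()
    fix = ev == "fixation"
    if not fix.any():
        raise ValueError("no fixation samples: lane share undefined")
    dur = _durations_ms(stream["time_ms"].to_numpy(dtype=float))
    return float(dur[fix & (stream["aoi"].to_numpy() == "lane")].sum()
                 / dur[fix].sum())


def pupil_cv(values, ddof: int = 0) -> float:
    """Pupil-diameter coefficient of variation: SD over mean.

    Requires at least two present values and a positive mean.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("pupil_cv needs at least two pupil values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("pupil_cv undefined for non-positive mean")
    return float(v.std(ddof=ddof) / mean)


def read_gaze_csv(path) -> pd.DataFrame:
    """Read a gaze-sample stream (columns time_ms, event, pupil_mm, aoi)."""
    df = pd.read_csv(path)
    required = {"time_ms", "event", "pupil_mm", "aoi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gaze stream missing columns: {sorted(missing)}")
    bad = set(df["event"].unique()) - set(EVENTS)
    if bad:
        raise ValueError(f"unknown event labels: {sorted(bad)}")
    return df


def write_gaze_csv(stream: pd.DataFrame, path) -> None:
    stream.to_csv(path, index=False)
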