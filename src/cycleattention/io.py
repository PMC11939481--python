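"""Trial-table schemas and readers/writers.

All files are plain CSV (comma-separated, UTF-8, header row, "."
decimal).  The canonical trial table carries one analysis row per
valid trial:

    cyclist, section, direction, period, traffic_density, riding_style,
    lane_fixation_share, pupil_cv, attention_level

plus optional indicator columns (fixation_time_pct, ...) when gaze
metrics are available.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["TRIAL_COLUMNS", "read_trial_table", "write_trial_table",
           "load_deposit", "write_metadata"]

TRIAL_COLUMNS = (
    "cyclist", "section", "direction", "period", "traffic_density",
    "riding_style", "lane_fixation_share", "pupil_cv", "attention_level",
)


def read_trial_table(path, require_response: bool = True,
                     require_covariates: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = set(TRIAL_COLUMNS)
    if not require_response:
        required -= {"attention_level"}
    if not require_covariates:
        required -= {"lane_fixation_share", "pupil_cv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if require_response and not df["attention_level"].isin([1, 2, 3]).all():
        raise ValueError("attention_level must be in {1, 2, 3}")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_deposit(path, column_map: dict) -> pd.DataFrame:
    """Load an externally deposited trial table with a column mapping.

    The study's data are deposited at FigShare
    (DOI 10.6084/m9.figshare.27902439.V1); since the deposit's exact
    column layout is not standardized, ``column_map`` maps deposit
    column names to the canonical names in :data:`TRIAL_COLUMNS`.
    Nothing in this package requires the deposit — all analyses run on
    synthetic data — but a local copy can be adapted through this
    loader.
    """
    df = pd.read_csv(path).rename(columns=dict(column_map))
    return read_trial_table_frame(df)


def read_trial_table_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mapped table missing columns: {sorted(missing)}")
    return df


def write_metadata(path, **entries) -> None:
    """Write a JSON metadata snapshot (config, seeds, version) for a run."""
    from . import __version__

    payload = {"package_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
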