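"""Model evaluation: observed-vs-predicted cross tables, overall
accuracy, model comparison, and odds-ratio analysis with reference
recoding.

A prediction counts as accurate when the predicted ordinal level equals
the level derived from the eye-movement composite; overall accuracy is
the diagonal share of the 3x3 cross table, reported as a percentage to
two decimals.  Odds ratios are exponentiated cumulative-logit
coefficients; recoding against a new reference level uses the exact
contrast identity ``beta'_a = beta_a - beta_newref`` (equivalent to a
refit for maximum-likelihood estimates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CrossTable", "cross_table", "accuracy", "compare_models",
           "odds_ratios"]

LEVEL_NAMES = {1: "Distracted", 2: "Scattered", 3: "Focused"}


@dataclass(frozen=True)
class CrossTable:
    """3x3 observed-by-predicted counts with margins."""

    counts: np.ndarray           # rows observed, columns predicted
    levels: tuple = (1, 2, 3)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [LEVEL_NAMES.get(l, str(l)) for l in self.levels]
        df = pd.DataFrame(self.counts, index=names, columns=names)
        df["Total"] = self.row_totals
        df.loc["Total"] = list(self.col_totals) + [self.grand_total]
        return df


def cross_table(observed, predicted, levels=(1, 2, 3)) -> CrossTable:
    """Count (observed, predicted) level pairs."""
    obs = np.asarray(observed, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if len(obs) != len(pred):
        raise ValueError("observed and predicted must have equal length")
    ok = set(levels)
    bad = (set(obs) | set(pred)) - ok
    if bad:
        raise ValueError(f"levels outside {sorted(ok)}: {sorted(bad)}")
    k = len(levels)
    lut = {l: i for i, l in enumerate(levels)}
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, ([lut[o] for o in obs], [lut[p] for p in pred]), 1)
    return CrossTable(counts=counts, levels=tuple(levels))


def accuracy(table: CrossTable) -> float:
    """Overall accuracy in percent: 100 x diagonal sum / grand total."""
    if table.grand_total == 0:
        raise ValueError("empty cross table")
    return 100.0 * float(np.trace(table.counts)) / table.grand_total


def compare_models(table_a: CrossTable, table_b: CrossTable) -> float:
    """Accuracy(A) - accuracy(B) in percentage points.

    Both tables must describe the same trial set (identical observed
    margins).
    """
    if table_a.grand_total != table_b.grand_total or \
            not np.array_equal(table_a.row_totals, table_b.row_totals):
        raise ValueError("cross tables describe different trial sets")
    return accuracy(table_a) - accuracy(table_b)


def odds_ratios(coefs: dict | pd.Series, recode_reference: str | None = None,
                factor_prefix: str | None = None) -> pd.DataFrame:
    """Odds ratios from cumulative-logit coefficients.

    ``coefs`` maps term names (e.g. ``"traffic_density[sparse]"``) to
    estimates; the reference level of each factor is implicit with
    coefficient 0.  With ``recode_reference`` set to a level name of the
    factor selected by ``factor_prefix`` (or inferred when unambiguous),
    the table is re-expressed against that level via the contrast
    identity, including the old reference as an estimated row.
    """
    s = pd.Series(coefs, dtype=float)
    if recode_reference is None:
        return pd.DataFrame({"estimate": s, "odds_ratio": np.exp(s)})

    def level_of(name: str) -> str:
        return name.rsplit("[", 1)[-1].rstrip("]")

    if factor_prefix is not None:
        terms = [t for t in s.index if t.startswith(factor_prefix)]
    else:
        terms = list(s.index)
    matches = [t for t in terms if level_of(t) == recode_reference]
    if len(matches) != 1:
        raise KeyError(f"cannot identify level {recode_reference!r} among "
                       f"{terms}")
    new_ref = matches[0]
    prefix = new_ref.rsplit("[", 1)[0]
    fam = [t for t in s.index if t.rsplit("[", 1)[0] == prefix]
    out = {}
    for t in s.index:
        if t in fam:
            if t == new_ref:
                continue
            out[t] = s[t] - s[new_ref]
        else:
            out[t] = s[t]
    # the old (implicit) reference becomes an estimated contrast
    out[f"{prefix}[reference]"] = -s[new_ref]
    res = pd.Series(out)
    return pd.DataFrame({"estimate": res, "odds_ratio": np.exp(res)})
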