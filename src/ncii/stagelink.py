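"""Cross-stage performance: family means per treatment and OLS stage regression.

Each sire x dam pair (full-sib family) has a mean performance per treatment
cell, averaged over replicate jars.  Within each treatment cell, ordinary
least squares relates mean performance at one developmental stage to the
other across families; R^2 is symmetric in the choice of axis, so both
regression directions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import family_id

__all__ = ["pair_means", "stage_regression", "stage_link_table", "RegressionFit"]


def pair_means(records: pd.DataFrame, response: str = "percent") -> pd.DataFrame:
    """Mean performance of each family in each treatment cell.

    Returns columns family, temperature, ph, mean, n_replicates; one row per
    family x treatment combination.
    """
    df = records.copy()
    df["family"] = [family_id(s, d) for s, d in zip(df["sire"], df["dam"])]
    out = (df.groupby(["family", "temperature", "ph"], sort=True)[response]
           .agg(mean="mean", n_replicates="size").reset_index())
    return out


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of one stage's family means on the other within a cell."""

    temperature: object
    ph: object
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def stage_regression(fert_means: pd.DataFrame, gast_means: pd.DataFrame,
                     temperature, ph,
                     direction: str = "gast_on_fert") -> RegressionFit:
    """Regress one stage on the other across families in one treatment cell.

    ``direction`` selects the predictor: ``gast_on_fert`` (later stage on
    earlier) or ``fert_on_gast``.  R^2 is identical either way.
    """
    merged = fert_means.merge(gast_means, on=["family", "temperature", "ph"],
                              suffixes=("_fert", "_gast"))
    cell = merged[(merged["temperature"] == temperature)
                  & (merged["ph"] == ph)]
    if len(cell) < 3:
        raise ValueError("need at least 3 paired family means in the cell")
    x = cell["mean_fert"].to_numpy(float)
    y = cell["mean_gast"].to_numpy(float)
    if direction == "fert_on_gast":
        x, y = y, x
    elif direction != "gast_on_fert":
        raise ValueError(f"unknown direction {direction!r}")
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor within the cell")
    fit = stats.linregress(x, y)
    return RegressionFit(temperature=temperature, ph=ph,
                         slope=float(fit.slope), intercept=float(fit.intercept),
                         r2=float(fit.rvalue ** 2), p=float(fit.pvalue),
                         n=len(cell))


def stage_link_table(records: pd.DataFrame,
                     fert_column: str = "fertilization",
                     gast_column: str = "gastrulation") -> pd.DataFrame:
    """Per-treatment-cell regressions between the two stages, both directions."""
    fert = pair_means(records, fert_column)
    gast = pair_means(records, gast_column)
    cells = records[["temperature", "ph"]].drop_duplicates().sort_values(
        ["temperature", "ph"])
    rows = []
    for _, (t, p) in cells.iterrows():
        for direction in ("gast_on_fert", "fert_on_gast"):
            fit = stage_regression(fert, gast, t, p, direction=direction)
            rows.append({"temperature": t, "ph": p, "direction": direction,
                         "slope": fit.slope, "intercept": fit.intercept,
                         "R2": fit.r2, "p": fit.p, "n": fit.n})
    return pd.DataFrame(rows)
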