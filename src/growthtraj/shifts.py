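"""Individual percentile-crossing growth shifts (AACAP monitoring rule).

A growth change is flagged as potentially clinically meaningful when the
z-score moves across two percentile lines on a chart showing the 5th,
10th, 25th, 50th, 75th, 90th, and 95th percentiles.  On the z scale those
chart lines are the standard-normal quantiles of the grid percentiles.  A
value exactly on a line does not count that line as crossed ("strictly
between"); two or more crossed lines in either direction qualify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["PercentileGrid", "ShiftResult", "classify_shift", "shift_table"]

DEFAULT_PERCENTILES = (5, 10, 25, 50, 75, 90, 95)
MONOTHERAPY_SUBGROUPS = ("first_line_guanfacine_mono", "nonfirst_line_guanfacine_mono")


@dataclass(frozen=True)
class PercentileGrid:
    percentiles: tuple = DEFAULT_PERCENTILES

    @property
    def z_cutpoints(self) -> np.ndarray:
        return norm.ppf(np.asarray(self.percentiles, dtype=float) / 100.0)


@dataclass(frozen=True)
class ShiftResult:
    patient_id: str
    measure: str
    z_baseline: float
    z_final: float
    lines_crossed: int
    direction: str  # increase | decrease | none


def classify_shift(
    patient_id: str,
    measure: str,
    z_baseline: float,
    z_final: float,
    grid: PercentileGrid | None = None,
) -> ShiftResult:
    """Count percentile lines strictly between baseline and final z; the
    shift direction is reported only when at least two lines are crossed."""
    grid = grid or PercentileGrid()
    lo, hi = sorted((z_baseline, z_final))
    cuts = grid.z_cutpoints
    lines = int(np.sum((cuts > lo) & (cuts < hi)))
    if lines >= 2:
        direction = "increase" if z_final > z_baseline else "decrease"
    else:
        direction = "none"
    return ShiftResult(patient_id, measure, float(z_baseline), float(z_final), lines, direction)


def shift_table(results: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of qualifying shifts by subgroup x sex x
    measure x direction, plus pooled guanfacine-monotherapy rows.

    ``results`` has one row per patient and measure with columns
    patient_id, measure, direction; ``assignments`` maps patient_id to
    subgroup and sex.  The denominator of each cell is the number of
    patients with a shift result in that subgroup x sex for the measure.
    """
    merged = results.merge(assignments[["patient_id", "subgroup", "sex"]], on="patient_id")
    rows = []
    subgroups = sorted(merged["subgroup"].unique())
    for measure in sorted(merged["measure"].unique()):
        m = merged[merged["measure"] == measure]
        for subgroup in subgroups:
            for sex in ("male", "female"):
                cell = m[(m["subgroup"] == subgroup) & (m["sex"] == sex)]
                rows.extend(_direction_rows(cell, measure, subgroup, sex))
        pooled = m[m["subgroup"].isin(MONOTHERAPY_SUBGROUPS)]
        rows.extend(_direction_rows(pooled, measure, "pooled_monotherapy", "all"))
    return pd.DataFrame(rows, columns=["measure", "subgroup", "sex", "direction", "count", "n", "percent"])


def _direction_rows(cell: pd.DataFrame, measure, subgroup, sex) -> list:
    n = len(cell)
    out = []
    for direction in ("increase", "decrease"):
        count = int((cell["direction"] == direction).sum())
        pct = 100.0 * count / n if n else 0.0
        out.append((measure, subgroup, sex, direction, count, n, pct))
    return out
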