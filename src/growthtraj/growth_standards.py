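"""Age- and sex-standardized anthropometry via the LMS method.

Growth references such as the 2000 CDC charts express the distribution of
weight or height at each age as three parameters: a Box-Cox power ``L``
removing skewness, the median ``M``, and a coefficient of variation ``S``.
A raw measurement ``X`` maps to a z-score by

    z = ((X/M)**L - 1) / (L*S)     if L != 0
    z = ln(X/M) / S                if L == 0

and back by the closed-form inverse.  This module provides those transforms,
linear interpolation of (L, M, S) between the reference table's age grid
rows, conversion of z-scores to percentile labels, and the plausibility
filter (|z| <= 4.5) applied to analysis measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Sex",
    "LmsParams",
    "LmsTable",
    "StandardizedMeasurement",
    "lms_zscore",
    "zscore_to_value",
    "z_to_percentile",
    "z_to_percentile_label",
    "reasonableness_filter",
    "standardize",
    "standardize_frame",
    "AgeOutOfRangeError",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

#: Plausibility bound on standardized scores, inclusive on both sides.
REASONABLE_Z_BOUND = 4.5


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class AgeOutOfRangeError(ValueError):
    """Raised when an age query falls outside the reference table grid."""


@dataclass(frozen=True)
class LmsParams:
    L: float
    M: float
    S: float


@dataclass(frozen=True)
class StandardizedMeasurement:
    patient_id: str
    date: date
    measure: str
    raw_value: float
    age_years: float
    z: float
    percentile: float


def lms_zscore(value: float, L: float, M: float, S: float) -> float:
    """Standardized score of ``value`` under LMS parameters.

    Continuous in ``L`` across 0 (the L=0 branch is the Box-Cox limit).
    """
    value, L, M, S = (np.asarray(a, dtype=float) for a in (value, L, M, S))
    if np.any(value <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("value, M and S must all be positive")
    log_ratio = np.log(value / M)
    # expm1 form is exact at L=0 and stable for small |L|
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(L == 0, log_ratio / S,
                     np.expm1(L * log_ratio) / (np.where(L == 0, 1.0, L) * S))
    return float(z) if z.ndim == 0 else z


def zscore_to_value(z: float, L: float, M: float, S: float) -> float:
    """Raw measurement corresponding to a z-score; exact inverse of
    :func:`lms_zscore`."""
    z, L, M, S = (np.asarray(a, dtype=float) for a in (z, L, M, S))
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    base = L * S * z
    if np.any((L != 0) & (base <= -1.0)):
        raise ValueError("1 + L*S*z must be positive when L != 0")
    # log1p form mirrors the stable forward transform
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(
            L == 0,
            M * np.exp(S * z),
            M * np.exp(np.log1p(np.where((L != 0) & (base > -1.0), base, 0.0))
                       / np.where(L == 0, 1.0, L)),
        )
    return float(value) if value.ndim == 0 else value


def z_to_percentile(z: float) -> float:
    """Percentile (0-100 scale) of a standard-normal z-score."""
    return 100.0 * norm.cdf(z)


def z_to_percentile_label(z: float) -> int:
    """Integer percentile label: nearest integer, halves rounded away
    from zero (so 52.79 -> 53, 64.93 -> 65)."""
    p = z_to_percentile(z)
    return int(np.floor(p + 0.5)) if p >= 0 else -int(np.floor(-p + 0.5))


def reasonableness_filter(z) -> bool | np.ndarray:
    """True where a z-score passes the plausibility test -4.5 <= z <= 4.5
    (boundaries inclusive)."""
    z = np.asarray(z, dtype=float)
    keep = (z >= -REASONABLE_Z_BOUND) & (z <= REASONABLE_Z_BOUND)
    return bool(keep) if keep.ndim == 0 else keep


class LmsTable:
    """Sex- and age-indexed (L, M, S) reference parameters for one measure.

    Parameters
    ----------
    measure:
        ``"weight"`` or ``"height"``.
    frame:
        DataFrame with columns ``sex`` (``"male"``/``"female"``),
        ``age_months``, ``L``, ``M``, ``S``; ages strictly increasing
        within each sex.
    """

    REQUIRED_COLUMNS = ("sex", "age_months", "L", "M", "S")

    def __init__(self, measure: str, frame: pd.DataFrame):
        if measure not in ("weight", "height"):
            raise ValueError(f"unknown measure {measure!r}")
        missing = set(self.REQUIRED_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"LMS frame missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        frame["sex"] = frame["sex"].map(_normalize_sex)
        frame = frame.sort_values(["sex", "age_months"]).reset_index(drop=True)
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise ValueError("M and S must be positive in every row")
        self._grids: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for sex, sub in frame.groupby("sex"):
            ages = sub["age_months"].to_numpy(dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"duplicate or non-increasing ages for sex {sex!r}")
            self._grids[sex] = (
                ages,
                sub["L"].to_numpy(dtype=float),
                sub["M"].to_numpy(dtype=float),
                sub["S"].to_numpy(dtype=float),
            )
        self.measure = measure
        self.frame = frame

    @property
    def age_range(self) -> tuple[float, float]:
        lows = [g[0][0] for g in self._grids.values()]
        highs = [g[0][-1] for g in self._grids.values()]
        return (max(lows), min(highs))

    def lookup(self, sex: str | Sex, age_months: float) -> LmsParams:
        """Linearly interpolated (L, M, S) at an arbitrary age.

        Exact grid ages return that row; ages outside the grid raise
        :class:`AgeOutOfRangeError`.
        """
        sex = _normalize_sex(sex)
        if sex not in self._grids:
            raise ValueError(f"no LMS rows for sex {sex!r}")
        ages, L, M, S = self._grids[sex]
        if age_months < ages[0] or age_months > ages[-1]:
            raise AgeOutOfRangeError(
                f"age {age_months:.1f} mo outside {self.measure} grid "
                f"[{ages[0]:.1f}, {ages[-1]:.1f}]"
            )
        return LmsParams(
            L=float(np.interp(age_months, ages, L)),
            M=float(np.interp(age_months, ages, M)),
            S=float(np.interp(age_months, ages, S)),
        )

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, measure: str | None = None) -> "LmsTable":
        """Load the published CDC layout (``sex`` coded 1=male/2=female,
        ``agemos``) or a long-format dialect with explicit ``measure``,
        ``sex`` (text) and ``age_months`` columns."""
        raw = pd.read_csv(path)
        raw.columns = [c.strip().lower() for c in raw.columns]
        if "measure" in raw.columns:
            measures = raw["measure"].unique()
            if measure is None:
                if len(measures) != 1:
                    raise ValueError("measure must be given for a multi-measure file")
                measure = str(measures[0])
            raw = raw[raw["measure"] == measure]
        if measure is None:
            raise ValueError("measure must be given for the CDC wide layout")
        age_col = "agemos" if "agemos" in raw.columns else "age_months"
        frame = pd.DataFrame(
            {
                "sex": raw["sex"],
                "age_months": raw[age_col],
                "L": raw["l"],
                "M": raw["m"],
                "S": raw["s"],
            }
        )
        return cls(measure, frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "measure", self.measure)
        out.to_csv(path, index=False)


def _normalize_sex(value) -> str:
    if isinstance(value, Sex):
        return value.value
    if isinstance(value, (int, np.integer)) or (isinstance(value, float) and value == int(value)):
        code = int(value)
        if code == 1:
            return Sex.MALE.value
        if code == 2:
            return Sex.FEMALE.value
        raise ValueError(f"unknown sex code {value!r}")
    text = str(value).strip().lower()
    if text in ("m", "male", "1"):
        return Sex.MALE.value
    if text in ("f", "female", "2"):
        return Sex.FEMALE.value
    raise ValueError(f"unknown sex {value!r}")


def age_in_months(birth_date: date, on: date) -> float:
    """Age as (days since birth) x 12/365.25 -- deterministic, calendar-free."""
    return (on - birth_date).days / DAYS_PER_MONTH


def standardize(
    measurement_date: date,
    measure: str,
    value: float,
    unit: str,
    patient_id: str,
    sex: str | Sex,
    birth_date: date,
    table: LmsTable,
) -> StandardizedMeasurement:
    """Standardize one raw measurement against the LMS reference.

    Raises ``ValueError`` on a measure/unit mismatch and propagates
    :class:`AgeOutOfRangeError` for ages off the reference grid.
    """
    expected_unit = {"weight": "kg", "height": "cm"}[table.measure]
    if measure != table.measure:
        raise ValueError(f"measurement {measure!r} does not match table {table.measure!r}")
    if unit != expected_unit:
        raise ValueError(f"unit {unit!r} invalid for {measure} (expected {expected_unit!r})")
    if measurement_date < birth_date:
        raise ValueError("measurement date precedes birth date")
    age_mo = age_in_months(birth_date, measurement_date)
    p = table.lookup(sex, age_mo)
    z = lms_zscore(value, p.L, p.M, p.S)
    return StandardizedMeasurement(
        patient_id=patient_id,
        date=measurement_date,
        measure=measure,
        raw_value=float(value),
        age_years=age_mo / 12.0,
        z=z,
        percentile=z_to_percentile(z),
    )


def standardize_frame(
    measurements: pd.DataFrame,
    patients: pd.DataFrame,
    tables: dict[str, LmsTable],
) -> pd.DataFrame:
    """Standardize a measurements extract against LMS references.

    ``measurements`` needs columns patient_id, date, type, value, unit;
    ``patients`` needs patient_id, sex, birth_date.  Rows whose age falls
    outside the reference grid are dropped with a logged count.  Returns a
    frame with ``age_years``, ``z`` and ``percentile`` columns added.
    """
    pat = patients.set_index("patient_id")
    rows = []
    n_dropped = 0
    for rec in measurements.itertuples(index=False):
        measure = rec.type
        table = tables.get(measure)
        if table is None:
            raise ValueError(f"no LMS table for measure {measure!r}")
        info = pat.loc[rec.patient_id]
        try:
            sm = standardize(
                measurement_date=_as_date(rec.date),
                measure=measure,
                value=float(rec.value),
                unit=rec.unit,
                patient_id=rec.patient_id,
                sex=info["sex"],
                birth_date=_as_date(info["birth_date"]),
                table=table,
            )
        except AgeOutOfRangeError:
            n_dropped += 1
            continue
        rows.append(sm)
    if n_dropped:
        logger.warning("dropped %d measurements outside the LMS age range", n_dropped)
    out = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "date": [r.date for r in rows],
            "measure": [r.measure for r in rows],
            "value": [r.raw_value for r in rows],
            "age_years": [r.age_years for r in rows],
            "z": [r.z for r in rows],
            "percentile": [r.percentile for r in rows],
        }
    )
    out.attrs["n_dropped_age_range"] = n_dropped
    return out


def _as_date(value) -> date:
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    return pd.Timestamp(value).date()
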