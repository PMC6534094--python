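"""Synthetic EMR extracts with the longitudinal structure the analyses assume.

The generator emulates a pediatric EMR extract: ADHD diagnosis records
(ICD-9 314.0x), dated prescriptions with days-supply for guanfacine,
stimulant, and atomoxetine classes (refill gaps, summer drug holidays,
dose changes, early refills, co-prescription patterns), irregular
measurement visits with differential loss to follow-up, and growth
trajectories generated on the z scale from a random-coefficients model
(per-patient random intercept/linear/quadratic time) before being
converted to raw kg/cm through an LMS reference so the pipeline ingests
raw measurements.

Each simulated patient carries a generator label (intended regimen and the
realized random effects) so cohort assignment and model estimates can be
validated against known truth.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .growth_standards import DAYS_PER_YEAR, LmsTable, zscore_to_value

__all__ = [
    "GrowthParams",
    "RxParams",
    "SimulationConfig",
    "simulate_population",
    "simulate_growth_panel",
    "simulate_prepost_panel",
    "make_synthetic_lms_table",
    "REGIMENS",
]

REGIMENS = (
    "first_line_guanfacine",
    "nonfirst_line_guanfacine",
    "combined",
    "first_line_stimulant",
    "unmedicated",
)

REGIMEN_COHORT = {
    "first_line_guanfacine": ("guanfacine", "first_line_guanfacine_mono"),
    "nonfirst_line_guanfacine": ("guanfacine", "nonfirst_line_guanfacine_mono"),
    "combined": ("guanfacine", "combined_pharmacotherapy"),
    "first_line_stimulant": ("first_line_stimulant", "none"),
    "unmedicated": ("unmedicated", "none"),
}

ADHD_DX_CODES = ("314.01", "314.00", "314.0")


@dataclass(frozen=True)
class GrowthParams:
    """Fixed-effect truth for one regimen and measure: z(t) = intercept +
    time*t + time2*t^2 (+ covariate effects), t in years from time zero."""

    intercept: float
    time: float
    time2: float


# Regimen-level trajectory truth.  Stimulant and unmedicated values follow
# the declining / flat weight and height courses reported for large
# observational ADHD cohorts; the guanfacine-family values place the
# combined-pharmacotherapy group on a declining path from a depressed
# baseline and the monotherapy subgroups on near-flat paths.
DEFAULT_GROWTH_TRUTH: dict[str, dict[str, GrowthParams]] = {
    "first_line_guanfacine": {
        "weight": GrowthParams(0.348, 0.160, -0.0516),
        "height": GrowthParams(0.166, -0.0205, 0.0098),
    },
    "nonfirst_line_guanfacine": {
        "weight": GrowthParams(0.075, 0.174, -0.0516),
        "height": GrowthParams(0.074, -0.0437, 0.0098),
    },
    "combined": {
        "weight": GrowthParams(-0.090, -0.0212, -0.0516),
        "height": GrowthParams(0.000, -0.1666, 0.0098),
    },
    "first_line_stimulant": {
        "weight": GrowthParams(0.419, -0.7100, 0.2127),
        "height": GrowthParams(0.198, -0.2141, 0.0296),
    },
    "unmedicated": {
        "weight": GrowthParams(0.378, 0.0143, -0.0002),
        "height": GrowthParams(0.223, -0.0133, 0.0033),
    },
}

#: Supply-day effect of pre-guanfacine stimulant exposure on z (per day).
DEFAULT_STIM_PRE_EFFECT = -0.00057

STIMULANT_DRUGS = ("MPH", "AMP")
GUANFACINE_DOSES = ("GXR 1 mg/day", "GXR 2 mg/day", "GXR 3 mg/day", "GXR 4 mg/day")
STIMULANT_DOSES = ("10 mg/day", "20 mg/day", "30 mg/day")


@dataclass(frozen=True)
class RxParams:
    days_supply: int = 30
    refill_gap_mean: float = 3.0       # days, Poisson
    summer_holiday_prob: float = 0.35  # once per chain, gap 45-110 d in Jun-Aug
    dose_change_prob: float = 0.15     # per refill
    early_refill_prob: float = 0.08    # per refill, 3-10 d overlap
    atomoxetine_prob: float = 0.06     # guanfacine-family co-medication


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 4000
    seed: int = 20090101
    study_start: date = date(2009, 1, 1)
    study_end: date = date(2013, 6, 30)
    # regimen mix scaled from the observed cohort sizes (guanfacine
    # subgroups are rare relative to first-line stimulant users)
    cohort_mix: dict = field(
        default_factory=lambda: {
            "first_line_guanfacine": 0.020,
            "nonfirst_line_guanfacine": 0.017,
            "combined": 0.035,
            "first_line_stimulant": 0.688,
            "unmedicated": 0.240,
        }
    )
    growth_truth: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROWTH_TRUTH.items()})
    stim_pre_effect: float = DEFAULT_STIM_PRE_EFFECT
    random_effect_cov: tuple = ((1.00, 0.0, 0.0), (0.0, 0.04, 0.0), (0.0, 0.0, 0.0025))
    residual_sd: float = 0.12
    male_fraction: float = 0.67
    visit_interval_mean_days: float = 100.0
    followup_mean_days_medicated: float = 420.0
    followup_mean_days_unmedicated: float = 650.0
    rx: RxParams = field(default_factory=RxParams)
    p_weight_at_visit: float = 0.92
    p_height_at_visit: float = 0.85

    def validate(self) -> None:
        probs = np.array([self.cohort_mix.get(r, 0.0) for r in REGIMENS])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("cohort_mix proportions must sum to 1")
        if np.any(probs < 0):
            raise ValueError("cohort_mix proportions must be non-negative")
        cov = np.asarray(self.random_effect_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ValueError("random_effect_cov must be symmetric 3x3")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("random_effect_cov must be positive semidefinite")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


def make_synthetic_lms_table(measure: str, age_min: float = 24.0, age_max: float = 246.0,
                             step: float = 6.0) -> LmsTable:
    """A smooth, plausible LMS reference covering both sexes.

    Synthetic stand-in for a published growth reference: the median
    increases with age, S stays within the usual 0.05-0.25 band, and L
    declines gently for weight (right-skew grows with age).
    """
    ages = np.arange(age_min, age_max + 1e-9, step)
    rows = []
    for sex, sex_factor in (("male", 1.0), ("female", 0.97)):
        if measure == "weight":
            L = 1.0 - 0.002 * ages
            M = (8.0 + 0.23 * ages) * sex_factor
            S = np.clip(0.11 + 0.0003 * ages, 0.05, 0.25)
        elif measure == "height":
            L = np.ones_like(ages)
            M = (80.0 + 0.42 * ages) * sex_factor
            S = np.full_like(ages, 0.05)
        else:
            raise ValueError(f"unknown measure {measure!r}")
        for a, l, m, s in zip(ages, L, M, S):
            rows.append((sex, a, l, m, s))
    frame = pd.DataFrame(rows, columns=["sex", "age_months", "L", "M", "S"])
    return LmsTable(measure, frame)


def _rx_chain(
    rng: np.random.Generator,
    patient_id: str,
    drug_class: str,
    drug_name: str,
    doses: tuple,
    start: date,
    target_supply_days: int,
    params: RxParams,
    max_refill_gap: int | None = None,
) -> list[dict]:
    """One refill chain: successive fills until the dispensed supply
    reaches the target, with renewal delays, optional dose switches, early
    refills, and at most one summer drug holiday."""
    fills = []
    dose = doses[int(rng.integers(len(doses)))]
    cur = start
    supplied = 0
    holiday_taken = False
    while supplied < target_supply_days:
        supply = params.days_supply
        fills.append(
            dict(patient_id=patient_id, drug_name=drug_name, drug_class=drug_class,
                 dose_label=dose, start_date=cur, days_supply=supply)
        )
        supplied += supply
        end = cur + timedelta(days=supply - 1)
        if rng.random() < params.dose_change_prob:
            dose = doses[int(rng.integers(len(doses)))]
        if rng.random() < params.early_refill_prob:
            gap = -int(rng.integers(3, 11))
        elif (
            not holiday_taken
            and end.month in (5, 6, 7)
            and rng.random() < params.summer_holiday_prob
        ):
            gap = int(rng.integers(45, 111))
            holiday_taken = True
        else:
            gap = int(rng.poisson(params.refill_gap_mean))
            if max_refill_gap is not None:
                gap = min(gap, max_refill_gap)
        cur = end + timedelta(days=1 + gap)
    return fills


def _chain_end(fills: list[dict]) -> date:
    return max(f["start_date"] + timedelta(days=f["days_supply"] - 1) for f in fills)


def _duration_draw(rng: np.random.Generator, median: float = 140.0, sigma: float = 1.0,
                   lo: int = 15, hi: int = 1200) -> int:
    return int(np.clip(rng.lognormal(np.log(median), sigma), lo, hi))


def simulate_prescriptions(
    rng: np.random.Generator,
    patient_id: str,
    regimen: str,
    index_date: date,
    params: RxParams,
    study_end: date,
) -> tuple[list[dict], date]:
    """Prescription records for one patient plus the guanfacine initiation
    date (index date for regimens without prior stimulant exposure).

    The fill pattern realizes the target subgroup: no prior stimulant for
    first-line regimens; stimulant exposure ending within 28 days of
    guanfacine initiation for the nonfirst-line subgroup; simultaneous
    start or >28-day concurrency for combined pharmacotherapy.
    """
    fills: list[dict] = []
    g0 = index_date
    if regimen == "unmedicated":
        return fills, g0

    if regimen == "first_line_stimulant":
        drug = STIMULANT_DRUGS[int(rng.integers(2))]
        fills += _rx_chain(rng, patient_id, "stimulant", drug, STIMULANT_DOSES,
                           index_date, _duration_draw(rng), params)
        return fills, g0

    if regimen == "first_line_guanfacine":
        fills += _rx_chain(rng, patient_id, "guanfacine", "GUAN", GUANFACINE_DOSES,
                           index_date, _duration_draw(rng), params)
        g0 = index_date

    elif regimen == "nonfirst_line_guanfacine":
        drug = STIMULANT_DRUGS[int(rng.integers(2))]
        stim = _rx_chain(rng, patient_id, "stimulant", drug, STIMULANT_DOSES,
                         index_date, _duration_draw(rng, median=150, hi=540), params)
        fills += stim
        stim_end = _chain_end(stim)
        g0 = stim_end + timedelta(days=int(rng.integers(-20, 61)))
        g0 = max(g0, index_date + timedelta(days=1))
        g0 = min(g0, study_end - timedelta(days=30))
        # keep the subgroup unambiguous: no stimulant fill on the
        # initiation date itself
        starts = {f["start_date"] for f in stim}
        while g0 in starts:
            g0 += timedelta(days=1)
        fills += _rx_chain(rng, patient_id, "guanfacine", "GUAN", GUANFACINE_DOSES,
                           g0, _duration_draw(rng), params)

    elif regimen == "combined":
        drug = STIMULANT_DRUGS[int(rng.integers(2))]
        if rng.random() < 0.35:
            g0 = index_date
        else:
            g0 = index_date + timedelta(days=int(rng.integers(60, 401)))
            g0 = min(g0, study_end - timedelta(days=45))
        # stimulant coverage must extend well past g0 + 28 days with no
        # episode-breaking gap before then
        stim_target = (g0 - index_date).days + int(rng.integers(60, 301))
        fills += _rx_chain(rng, patient_id, "stimulant", drug, STIMULANT_DOSES,
                           index_date, stim_target, params, max_refill_gap=25)
        fills += _rx_chain(rng, patient_id, "guanfacine", "GUAN", GUANFACINE_DOSES,
                           g0, _duration_draw(rng), params)
    else:
        raise ValueError(f"unknown regimen {regimen!r}")

    if rng.random() < params.atomoxetine_prob:
        # co-medication: atomoxetine during (or, when there is room,
        # before) guanfacine exposure -- never inside the pre-index washout
        if regimen in ("nonfirst_line_guanfacine", "combined") and (g0 - index_date).days > 40 and rng.random() < 0.5:
            atx_start = index_date + timedelta(days=int(rng.integers(10, (g0 - index_date).days - 20)))
        else:
            atx_start = g0 + timedelta(days=int(rng.integers(10, 61)))
        fills.append(
            dict(patient_id=patient_id, drug_name="ATX", drug_class="atomoxetine",
                 dose_label="ATX 25 mg/day", start_date=atx_start,
                 days_supply=params.days_supply)
        )
    return fills, g0


def _growth_z(
    t_years: np.ndarray,
    truth: GrowthParams,
    b: np.ndarray,
    stim_pre_days: float,
    stim_pre_effect: float,
    noise: np.ndarray,
) -> np.ndarray:
    t = np.maximum(t_years, 0.0)
    return (
        truth.intercept + b[0]
        + (truth.time + b[1]) * t
        + (truth.time2 + b[2]) * t ** 2
        + stim_pre_effect * stim_pre_days
        + noise
    )


def simulate_population(config: SimulationConfig, lms_tables: dict[str, LmsTable] | None = None):
    """Generate a full synthetic extract.

    Returns ``(patients, prescriptions, diagnoses, measurements, truth)``
    DataFrames; ``truth`` holds the generator labels (regimen, cohort,
    subgroup, time zero, per-measure random effects) joinable by
    patient_id.  Output is fully determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tables = lms_tables or {
        "weight": make_synthetic_lms_table("weight"),
        "height": make_synthetic_lms_table("height"),
    }
    re_cov = np.asarray(config.random_effect_cov, dtype=float)
    re_chol = np.linalg.cholesky(re_cov + 1e-12 * np.eye(3))

    probs = np.array([config.cohort_mix.get(r, 0.0) for r in REGIMENS])
    study_span_late = (date(2012, 6, 30) - config.study_start).days
    study_span_early = (date(2011, 6, 30) - config.study_start).days

    patients, rx_rows, dx_rows, meas_rows, truth_rows = [], [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        regimen = REGIMENS[int(rng.choice(len(REGIMENS), p=probs))]
        cohort, subgroup = REGIMEN_COHORT[regimen]
        sex = "male" if rng.random() < config.male_fraction else "female"

        span = study_span_early if regimen in ("nonfirst_line_guanfacine", "combined") else study_span_late
        index_date = config.study_start + timedelta(days=int(rng.integers(0, span + 1)))
        age_years = 4.0 + 12.9 * rng.beta(1.0, 3.0)
        birth_date = index_date - timedelta(days=int(round(age_years * DAYS_PER_YEAR)))
        emr_start = index_date - timedelta(days=int(rng.integers(380, 1096)))

        fills, g0 = simulate_prescriptions(rng, pid, regimen, index_date, config.rx, config.study_end)
        rx_rows.extend(fills)
        time_zero = g0 if cohort == "guanfacine" else index_date

        dx_rows.append(dict(patient_id=pid, date=index_date, icd9_code=ADHD_DX_CODES[int(rng.integers(3))]))
        if rng.random() < 0.3:
            early = config.study_start - timedelta(days=int(rng.integers(30, 1500)))
            if early >= emr_start:
                dx_rows.append(dict(patient_id=pid, date=early, icd9_code=ADHD_DX_CODES[int(rng.integers(3))]))

        mean_fu = (
            config.followup_mean_days_unmedicated
            if regimen == "unmedicated"
            else config.followup_mean_days_medicated
        )
        emr_end = time_zero + timedelta(days=int(120 + rng.exponential(mean_fu)))
        emr_end = min(emr_end, config.study_end)
        patients.append(
            dict(patient_id=pid, sex=sex, birth_date=birth_date,
                 emr_start=emr_start, emr_end=emr_end)
        )

        # visit process: one baseline visit, then a renewal process
        visit_dates = [time_zero - timedelta(days=int(rng.integers(10, 331)))]
        if rng.random() < 0.3:
            visit_dates.append(time_zero)
        cur = time_zero + timedelta(days=int(rng.integers(5, 56)))
        while cur <= emr_end:
            visit_dates.append(cur)
            cur += timedelta(days=int(14 + rng.exponential(config.visit_interval_mean_days)))

        stim_pre_days = sum(
            min(f["days_supply"], max(0, (g0 - f["start_date"]).days))
            for f in fills
            if f["drug_class"] == "stimulant" and f["start_date"] < g0
        )
        truth = dict(patient_id=pid, regimen=regimen, cohort=cohort, subgroup=subgroup,
                     sex=sex, time_zero=time_zero, index_date=index_date,
                     stim_pre_days=stim_pre_days)
        for measure, p_take in (("weight", config.p_weight_at_visit), ("height", config.p_height_at_visit)):
            b = re_chol @ rng.standard_normal(3)
            truth[f"{measure}_b0"], truth[f"{measure}_b1"], truth[f"{measure}_b2"] = b
            params = config.growth_truth[regimen][measure]
            table = tables[measure]
            lo, hi = table.age_range
            for vd in visit_dates:
                if rng.random() > p_take:
                    continue
                age_mo = (vd - birth_date).days * 12.0 / DAYS_PER_YEAR
                if age_mo < lo or age_mo > hi:
                    continue
                t = (vd - time_zero).days / DAYS_PER_YEAR
                z = _growth_z(np.array([t]), params, b,
                              stim_pre_days if cohort == "guanfacine" else 0.0,
                              config.stim_pre_effect,
                              rng.normal(0.0, config.residual_sd, 1))[0]
                lms = table.lookup(sex, age_mo)
                try:
                    value = zscore_to_value(z, lms.L, lms.M, lms.S)
                except ValueError:
                    continue  # z beyond the LMS domain: unrecordable outlier
                meas_rows.append(
                    dict(patient_id=pid, date=vd, type=measure,
                         value=round(float(value), 2), unit="kg" if measure == "weight" else "cm")
                )
        truth_rows.append(truth)

    patients_df = pd.DataFrame(patients)
    rx_df = pd.DataFrame(
        rx_rows,
        columns=["patient_id", "drug_name", "drug_class", "dose_label", "start_date", "days_supply"],
    )
    dx_df = pd.DataFrame(dx_rows, columns=["patient_id", "date", "icd9_code"])
    meas_df = pd.DataFrame(meas_rows, columns=["patient_id", "date", "type", "value", "unit"])
    truth_df = pd.DataFrame(truth_rows)
    return patients_df, rx_df, dx_df, meas_df, truth_df


def simulate_growth_panel(
    n_patients: int,
    truth: GrowthParams,
    *,
    rng: np.random.Generator,
    visits_per_patient: int = 4,
    t_max: float = 2.0,
    random_effect_cov=None,
    residual_sd: float = 0.12,
    age_effect: float = 0.036,
    female_effect: float = -0.045,
    mpr_effect: float = 0.006,
) -> pd.DataFrame:
    """Long-format z-score panel drawn directly from the stimulant-family
    trajectory model -- the ground-truth generator for parameter-recovery
    checks.

    Each patient contributes a baseline observation at t = 0 and
    ``visits_per_patient - 1`` follow-up observations at uniform times in
    (0, t_max].  Covariates (age at baseline, sex, stimulant MPR) carry the
    stated linear effects.
    """
    cov = np.asarray(
        random_effect_cov if random_effect_cov is not None
        else ((1.0, 0.0, 0.0), (0.0, 0.04, 0.0), (0.0, 0.0, 0.0025)),
        dtype=float,
    )
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
    rows = []
    for i in range(n_patients):
        age = rng.uniform(4, 17)
        female = rng.random() < 0.33
        mpr_val = rng.uniform(0.4, 1.0)
        b = chol @ rng.standard_normal(3)
        times = np.concatenate([[0.0], np.sort(rng.uniform(0.05, t_max, visits_per_patient - 1))])
        eps = rng.normal(0.0, residual_sd, len(times))
        z = (
            truth.intercept + b[0]
            + (truth.time + b[1]) * times
            + (truth.time2 + b[2]) * times ** 2
            + age_effect * age + female_effect * female + mpr_effect * mpr_val
            + eps
        )
        for t, zv in zip(times, z):
            rows.append(
                dict(patient_id=f"S{i:05d}", time_years=float(t), z=float(zv),
                     sex="female" if female else "male", age_at_baseline=age,
                     stimulant_mpr=mpr_val)
            )
    return pd.DataFrame(rows)


def simulate_prepost_panel(
    n_patients: int,
    *,
    rng: np.random.Generator,
    pre_level: float = 0.4263,
    delta: float = -0.1346,
    visits_per_patient: int = 4,
    t_max: float = 2.0,
    time_effect_sd: tuple[float, float] = (0.25, 0.06),
    residual_sd: float = 0.25,
) -> pd.DataFrame:
    """Panel from the pre/post model: z = pre_level + delta*post + b1*t +
    b2*t^2 + noise with patient-level random linear/quadratic time.  One
    pre observation at t = 0 per patient, the rest post."""
    rows = []
    for i in range(n_patients):
        b1 = rng.normal(0.0, time_effect_sd[0])
        b2 = rng.normal(0.0, time_effect_sd[1])
        times = np.concatenate([[0.0], np.sort(rng.uniform(0.05, t_max, visits_per_patient - 1))])
        post = (np.arange(len(times)) > 0).astype(float)
        z = pre_level + delta * post + b1 * times + b2 * times ** 2 + rng.normal(0.0, residual_sd, len(times))
        for t, p_flag, zv in zip(times, post, z):
            rows.append(
                dict(patient_id=f"Q{i:05d}", time_years=float(t), z=float(zv),
                     post=float(p_flag), sex="male")
            )
    return pd.DataFrame(rows)
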