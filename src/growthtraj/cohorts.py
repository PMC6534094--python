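"""New-user cohort derivation for the growth analyses.

The study design anchors each patient at an index date: the first
study-medication prescription (guanfacine or stimulant) inside the study
period, or the first ADHD diagnosis for never-medicated patients.
Eligibility requires an ADHD diagnosis at any time, age 4-17 at index, an
EMR reaching back at least 12 months, a 12-month medication-free washout,
a baseline measurement in the 12 months before time zero, and at least one
plausible post-baseline measurement.  Patients are then partitioned into a
guanfacine cohort (subdivided by prior/concurrent stimulant exposure into
first-line monotherapy, nonfirst-line monotherapy, and combined
pharmacotherapy using a 28-day concurrency rule), a first-line stimulant
monotherapy cohort, and an unmedicated cohort.  Follow-up is censored at
age 20, study end, or loss to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

from .exposure import (
    ExposureEpisode,
    PrescriptionRecord,
    build_episodes,
    episode_metrics,
    total_prescribed_amount,
)
from .growth_standards import reasonableness_filter, DAYS_PER_YEAR

__all__ = [
    "StudyParams",
    "CohortAssignment",
    "ADHD_CODES",
    "STUDY_MED_CLASSES",
    "ADHD_MED_CLASSES",
    "find_index_date",
    "censor_date",
    "assign_cohort",
    "check_eligibility",
    "build_assignments",
    "select_analysis_measurements",
]

ADHD_CODES = frozenset({"314.0", "314.00", "314.01"})
STUDY_MED_CLASSES = frozenset({"guanfacine", "stimulant"})
ADHD_MED_CLASSES = frozenset({"guanfacine", "stimulant", "atomoxetine"})

GUANFACINE = "guanfacine"
STIMULANT = "stimulant"
ATOMOXETINE = "atomoxetine"

ONE_DAY = timedelta(days=1)


@dataclass(frozen=True)
class StudyParams:
    """Run configuration for cohort derivation."""

    study_start: date = date(2009, 1, 1)
    study_end: date = date(2013, 6, 30)
    washout_months: int = 12
    baseline_months: int = 12
    tail_days: int = 60           # post-discontinuation inclusion window
    combined_threshold_days: int = 28
    age_min_years: int = 4
    age_max_years: int = 18       # exclusive upper bound at index
    censor_age_years: int = 20


@dataclass
class CohortAssignment:
    patient_id: str
    cohort: str | None = None      # guanfacine | first_line_stimulant | unmedicated
    subgroup: str = "none"         # first_line_guanfacine_mono | nonfirst_line_guanfacine_mono
    #                              # | combined_pharmacotherapy | none
    index_date: date | None = None
    guanfacine_initiation_date: date | None = None
    time_zero: date | None = None
    censor: date | None = None
    analysis_end: date | None = None   # end of measurement-inclusion window
    episode: ExposureEpisode | None = None
    eligible_weight: bool = False
    eligible_height: bool = False
    exclusion_reasons: list = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return self.eligible_weight or self.eligible_height


def _add_years(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29
        return d.replace(year=d.year + years, month=3, day=1)


def _sub_months(d: date, months: int) -> date:
    return (pd.Timestamp(d) - pd.DateOffset(months=months)).date()


def find_index_date(prescriptions, diagnoses, params: StudyParams) -> date | None:
    """First in-period study-medication fill; else first in-period ADHD
    diagnosis; else ``None`` (patient not indexable).  Atomoxetine is an
    ADHD medication but not a study medication and never sets the index."""
    rx_dates = [
        rx.start_date
        for rx in prescriptions
        if rx.drug_class in STUDY_MED_CLASSES
        and params.study_start <= rx.start_date <= params.study_end
    ]
    if rx_dates:
        return min(rx_dates)
    dx_dates = [
        d for d, code in diagnoses
        if code in ADHD_CODES and params.study_start <= d <= params.study_end
    ]
    if dx_dates:
        return min(dx_dates)
    return None


def censor_date(birth_date: date, emr_end: date, params: StudyParams) -> date:
    """Earliest of: day before the 20th birthday, study end, last EMR
    encounter (loss to follow-up)."""
    return min(
        _add_years(birth_date, params.censor_age_years) - ONE_DAY,
        params.study_end,
        emr_end,
    )


def _stimulant_history_discontinuation(prescriptions, g0: date, params: StudyParams) -> date | None:
    """Discontinuation date of stimulant exposure ongoing at guanfacine
    initiation.

    Considers exposure episodes (with seasonal gap allowances) that begin on
    or before ``g0``; refills after ``g0`` that continue such an episode
    count, stimulant episodes started fresh after ``g0`` do not.
    """
    stim = [rx for rx in prescriptions if rx.drug_class == STIMULANT]
    if not stim:
        return None
    first = min(rx.start_date for rx in stim)
    episodes = build_episodes(stim, STIMULANT, first)
    prior = [ep for ep in episodes if ep.start_date <= g0]
    if not prior:
        return None
    return max(ep.discontinuation_date for ep in prior)


def assign_cohort(patient_id: str, prescriptions, params: StudyParams) -> tuple[str | None, str, date | None, str | None]:
    """Cohort and guanfacine subgroup from the prescription history.

    Returns ``(cohort, subgroup, guanfacine_initiation_date, exclusion_reason)``.
    """
    in_period_gx = [
        rx for rx in prescriptions
        if rx.drug_class == GUANFACINE and params.study_start <= rx.start_date <= params.study_end
    ]
    any_gx = any(rx.drug_class == GUANFACINE for rx in prescriptions)
    any_stim = any(rx.drug_class == STIMULANT for rx in prescriptions)
    any_adhd_med = any(rx.drug_class in ADHD_MED_CLASSES for rx in prescriptions)

    if in_period_gx:
        g0 = min(rx.start_date for rx in in_period_gx)
        simultaneous_stim = any(
            rx.drug_class == STIMULANT and rx.start_date == g0 for rx in prescriptions
        )
        prior_stim = any(
            rx.drug_class == STIMULANT and rx.start_date < g0 for rx in prescriptions
        )
        if simultaneous_stim:
            return ("guanfacine", "combined_pharmacotherapy", g0, None)
        if not prior_stim:
            return ("guanfacine", "first_line_guanfacine_mono", g0, None)
        stim_end = _stimulant_history_discontinuation(prescriptions, g0, params)
        if stim_end is not None and stim_end > g0 + timedelta(days=params.combined_threshold_days):
            return ("guanfacine", "combined_pharmacotherapy", g0, None)
        return ("guanfacine", "nonfirst_line_guanfacine_mono", g0, None)

    if any_gx:
        # guanfacine only outside the study period: no qualifying regimen
        return (None, "none", None, "guanfacine_outside_study_period")
    in_period_stim = [
        rx for rx in prescriptions
        if rx.drug_class == STIMULANT and params.study_start <= rx.start_date <= params.study_end
    ]
    if in_period_stim:
        return ("first_line_stimulant", "none", None, None)
    if any_stim:
        return (None, "none", None, "stimulant_outside_study_period")
    if any_adhd_med:
        return (None, "none", None, "atomoxetine_only")
    return ("unmedicated", "none", None, None)


def _initial_episode(prescriptions, assignment: CohortAssignment, params: StudyParams) -> ExposureEpisode | None:
    """First exposure episode from time zero; for combined pharmacotherapy
    the initial period ends at discontinuation of guanfacine and/or the
    stimulant, whichever comes first."""
    if assignment.cohort == "guanfacine":
        eps = build_episodes(prescriptions, GUANFACINE, assignment.guanfacine_initiation_date)
        if not eps:
            return None
        ep = eps[0]
        if assignment.subgroup == "combined_pharmacotherapy":
            stim_end = _stimulant_history_discontinuation(
                prescriptions, assignment.guanfacine_initiation_date, params
            )
            if stim_end is not None and stim_end < ep.discontinuation_date:
                ep = ExposureEpisode(
                    patient_id=ep.patient_id,
                    drug_classes=frozenset([GUANFACINE, STIMULANT]),
                    start_date=ep.start_date,
                    discontinuation_date=max(stim_end, ep.start_date),
                    prescriptions=ep.prescriptions,
                )
            else:
                ep = ExposureEpisode(
                    patient_id=ep.patient_id,
                    drug_classes=frozenset([GUANFACINE, STIMULANT]),
                    start_date=ep.start_date,
                    discontinuation_date=ep.discontinuation_date,
                    prescriptions=ep.prescriptions,
                )
        return ep
    if assignment.cohort == "first_line_stimulant":
        eps = build_episodes(prescriptions, STIMULANT, assignment.index_date)
        return eps[0] if eps else None
    return None


def check_eligibility(
    *,
    birth_date: date,
    emr_start: date,
    index_date: date,
    time_zero: date,
    censor: date,
    analysis_end: date,
    has_adhd_dx: bool,
    prescriptions,
    std_measurements: pd.DataFrame,
    params: StudyParams,
) -> tuple[dict[str, bool], list[str]]:
    """Apply the inclusion filters; measurement availability is checked
    independently for weight and height, so a patient may qualify for one
    analysis only.

    Returns ``({"weight": bool, "height": bool}, reasons)``.
    """
    reasons: list[str] = []
    if not has_adhd_dx:
        reasons.append("no_adhd_diagnosis")
    age_ok = _add_years(birth_date, params.age_min_years) <= index_date < _add_years(
        birth_date, params.age_max_years
    )
    if not age_ok:
        reasons.append("age_outside_4_17")
    if emr_start > _sub_months(index_date, params.washout_months):
        reasons.append("emr_too_short")
    washout_start = _sub_months(index_date, params.washout_months)
    washout_violation = any(
        rx.drug_class in ADHD_MED_CLASSES and washout_start <= rx.start_date < index_date
        for rx in prescriptions
    )
    if washout_violation:
        reasons.append("washout_violation")

    per_measure: dict[str, bool] = {}
    base_ok = not reasons
    baseline_start = _sub_months(time_zero, params.baseline_months)
    for measure in ("weight", "height"):
        sub = std_measurements[std_measurements["measure"] == measure]
        baseline = sub[(sub["date"] >= baseline_start) & (sub["date"] < time_zero)]
        has_baseline = not baseline.empty
        post = sub[
            (sub["date"] >= time_zero)
            & (sub["date"] <= min(analysis_end, censor))
            & reasonableness_filter(sub["z"].to_numpy())
        ]
        has_post = not post.empty
        per_measure[measure] = base_ok and has_baseline and has_post
        if base_ok and not has_baseline:
            reasons.append(f"no_baseline_{measure}")
        if base_ok and not has_post:
            reasons.append(f"no_postbaseline_{measure}")
    return per_measure, reasons


def build_assignments(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    std_measurements: pd.DataFrame,
    params: StudyParams | None = None,
) -> list[CohortAssignment]:
    """Derive a :class:`CohortAssignment` for every patient in the extract.

    Input frames follow the extract schemas (see :mod:`growthtraj.io`);
    ``std_measurements`` is the output of
    :func:`growthtraj.growth_standards.standardize_frame`.
    """
    params = params or StudyParams()
    rx_by_pat = _prescriptions_by_patient(prescriptions)
    dx_by_pat: dict[str, list] = {}
    for rec in diagnoses.itertuples(index=False):
        dx_by_pat.setdefault(rec.patient_id, []).append((_to_date(rec.date), str(rec.icd9_code)))
    meas_by_pat = dict(tuple(std_measurements.groupby("patient_id"))) if len(std_measurements) else {}
    empty_meas = std_measurements.iloc[0:0]

    out: list[CohortAssignment] = []
    for pat in patients.itertuples(index=False):
        pid = pat.patient_id
        a = CohortAssignment(patient_id=pid)
        rxs = rx_by_pat.get(pid, [])
        dxs = dx_by_pat.get(pid, [])
        birth = _to_date(pat.birth_date)
        emr_start = _to_date(pat.emr_start)
        emr_end = _to_date(pat.emr_end)

        a.index_date = find_index_date(rxs, dxs, params)
        if a.index_date is None:
            a.exclusion_reasons.append("not_indexable")
            out.append(a)
            continue

        cohort, subgroup, g0, reason = assign_cohort(pid, rxs, params)
        if cohort is None:
            a.exclusion_reasons.append(reason)
            out.append(a)
            continue
        a.cohort, a.subgroup, a.guanfacine_initiation_date = cohort, subgroup, g0
        a.time_zero = g0 if cohort == "guanfacine" else a.index_date
        a.censor = censor_date(birth, emr_end, params)
        if a.time_zero > a.censor:
            a.cohort, a.subgroup = None, "none"
            a.exclusion_reasons.append("time_zero_after_censoring")
            out.append(a)
            continue

        a.episode = _initial_episode(rxs, a, params)
        if cohort == "unmedicated":
            a.analysis_end = a.censor
        else:
            if a.episode is None:
                a.cohort, a.subgroup = None, "none"
                a.exclusion_reasons.append("no_exposure_episode")
                out.append(a)
                continue
            a.analysis_end = min(
                a.episode.discontinuation_date + timedelta(days=params.tail_days), a.censor
            )

        meas = meas_by_pat.get(pid, empty_meas)
        per_measure, reasons = check_eligibility(
            birth_date=birth,
            emr_start=emr_start,
            index_date=a.index_date,
            time_zero=a.time_zero,
            censor=a.censor,
            analysis_end=a.analysis_end,
            has_adhd_dx=any(code in ADHD_CODES for _, code in dxs),
            prescriptions=rxs,
            std_measurements=meas,
            params=params,
        )
        a.eligible_weight = per_measure["weight"]
        a.eligible_height = per_measure["height"]
        a.exclusion_reasons.extend(reasons)
        if not a.eligible:
            a.cohort, a.subgroup = None, "none"
        out.append(a)
    return out


def select_analysis_measurements(
    assignment: CohortAssignment,
    std_measurements: pd.DataFrame,
    measure: str,
    params: StudyParams | None = None,
) -> pd.DataFrame:
    """Measurements entering the trajectory model for one patient.

    The baseline measurement (most recent in the 12 months before time
    zero) is imputed to time 0; post-baseline measurements run from time 0
    inclusive to the analysis end (episode discontinuation + 60 days for
    medicated cohorts, censoring for the unmedicated cohort), filtered by
    the plausibility test.  Time is in years from time zero.

    Returns columns: patient_id, date, time_years, z, is_baseline.
    """
    params = params or StudyParams()
    t0 = assignment.time_zero
    sub = std_measurements[
        (std_measurements["patient_id"] == assignment.patient_id)
        & (std_measurements["measure"] == measure)
    ].copy()
    sub["date"] = [_to_date(d) for d in sub["date"]]
    baseline_start = _sub_months(t0, params.baseline_months)
    baseline = sub[(sub["date"] >= baseline_start) & (sub["date"] < t0)]
    rows = []
    if not baseline.empty:
        b = baseline.sort_values("date").iloc[-1]
        rows.append(
            dict(patient_id=assignment.patient_id, date=b["date"], time_years=0.0,
                 z=float(b["z"]), is_baseline=True)
        )
    end = min(assignment.analysis_end, assignment.censor)
    post = sub[(sub["date"] >= t0) & (sub["date"] <= end)]
    post = post[reasonableness_filter(post["z"].to_numpy())]
    for rec in post.sort_values("date").itertuples(index=False):
        rows.append(
            dict(
                patient_id=assignment.patient_id,
                date=rec.date,
                time_years=(rec.date - t0).days / DAYS_PER_YEAR,
                z=float(rec.z),
                is_baseline=False,
            )
        )
    return pd.DataFrame(rows, columns=["patient_id", "date", "time_years", "z", "is_baseline"])


def exposure_covariates(assignment: CohortAssignment, prescriptions) -> dict:
    """Medication covariates for the trajectory models.

    Guanfacine cohort: guanfacine MPR over the initial episode, total
    stimulant prescribed amount before initiation, and atomoxetine use
    before/during the episode.  Stimulant cohort: stimulant MPR.
    """
    cov: dict = {}
    if assignment.cohort == "guanfacine":
        g0 = assignment.guanfacine_initiation_date
        gx = [rx for rx in prescriptions if rx.drug_class == GUANFACINE]
        m = episode_metrics(gx, _class_episode(assignment.episode, GUANFACINE))
        cov["guanfacine_mpr"] = m.mpr
        stim = [rx for rx in prescriptions if rx.drug_class == STIMULANT]
        if stim:
            window = (min(rx.start_date for rx in stim), g0 - ONE_DAY)
            cov["stim_days_preguanfacine"] = (
                total_prescribed_amount(stim, window) if window[0] <= window[1] else 0
            )
        else:
            cov["stim_days_preguanfacine"] = 0
        atx = [rx for rx in prescriptions if rx.drug_class == ATOMOXETINE]
        disc = assignment.episode.discontinuation_date
        cov["atomoxetine_before"] = int(any(rx.start_date < g0 for rx in atx))
        cov["atomoxetine_during"] = int(any(g0 <= rx.start_date <= disc for rx in atx))
    elif assignment.cohort == "first_line_stimulant":
        stim = [rx for rx in prescriptions if rx.drug_class == STIMULANT]
        m = episode_metrics(stim, assignment.episode)
        cov["stimulant_mpr"] = m.mpr
    return cov


def _class_episode(episode: ExposureEpisode, drug_class: str) -> ExposureEpisode:
    if episode.drug_classes == frozenset([drug_class]):
        return episode
    return ExposureEpisode(
        patient_id=episode.patient_id,
        drug_classes=frozenset([drug_class]),
        start_date=episode.start_date,
        discontinuation_date=episode.discontinuation_date,
        prescriptions=episode.prescriptions,
    )


def _prescriptions_by_patient(prescriptions: pd.DataFrame) -> dict[str, list[PrescriptionRecord]]:
    by_pat: dict[str, list[PrescriptionRecord]] = {}
    for rec in prescriptions.itertuples(index=False):
        by_pat.setdefault(rec.patient_id, []).append(
            PrescriptionRecord(
                patient_id=rec.patient_id,
                drug_name=rec.drug_name,
                drug_class=rec.drug_class,
                dose_label=rec.dose_label,
                start_date=_to_date(rec.start_date),
                days_supply=int(rec.days_supply),
            )
        )
    return by_pat


def _to_date(value) -> date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, date):
        return value
    return pd.Timestamp(value).date()
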