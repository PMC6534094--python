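"""End-to-end orchestration: simulate/load -> standardize -> cohorts ->
exposure -> trajectory and pre/post models -> shifts -> report.

Weight and height run as independent passes sharing the cohort logic
(patients may qualify for one analysis only).  Every artifact is plain
CSV plus one JSON run-report; given identical inputs, configuration and
seed the outputs are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import (
    CohortAssignment,
    StudyParams,
    build_assignments,
    exposure_covariates,
    select_analysis_measurements,
    _prescriptions_by_patient,
)
from .exposure import episode_metrics
from .growth_standards import (
    DAYS_PER_YEAR,
    standardize_frame,
    z_to_percentile_label,
)
from .models import (
    TrajectoryModelSpec,
    fit_prepost,
    fit_random_coefficients,
    predict_trajectory,
)
from .shifts import classify_shift, shift_table
from .synthetic import SimulationConfig, make_synthetic_lms_table, simulate_population

__all__ = ["RunConfig", "run_pipeline", "build_analysis_set", "summarize_baseline"]

logger = logging.getLogger(__name__)

FAMILIES = ("guanfacine", "first_line_stimulant", "unmedicated")
PREPOST_POPULATIONS = {
    "first_line_guanfacine_mono": ("guanfacine", "first_line_guanfacine_mono"),
    "first_line_stimulant": ("first_line_stimulant", None),
    "unmedicated": ("unmedicated", None),
}
FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``input_dir`` points at an extract directory (patients.csv,
    prescriptions.csv, diagnoses.csv, measurements.csv and optionally
    lms.csv) or ``simulate`` holds a :class:`SimulationConfig`; when both
    are absent a default simulation is run with ``seed``.
    """

    seed: int = 20090101
    input_dir: str | None = None
    lms_path: str | None = None
    simulate: SimulationConfig | None = None
    study: StudyParams = field(default_factory=StudyParams)
    min_patients_per_model: int = 30
    prediction_horizon_years: float = 2.0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.input_dir = raw.get("input_dir")
        cfg.lms_path = raw.get("lms_path")
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            sim.setdefault("seed", cfg.seed)
            for key in ("study_start", "study_end"):
                if key in sim:
                    sim[key] = pd.Timestamp(sim[key]).date()
            for key in ("n_patients", "seed"):
                if key in sim:
                    sim[key] = int(sim[key])
            cfg.simulate = SimulationConfig(**sim)
            cfg.simulate.validate()
        study_kwargs = dict(raw.get("study", {}))
        for key in ("study_start", "study_end"):
            if key in study_kwargs:
                study_kwargs[key] = pd.Timestamp(study_kwargs[key]).date()
        cfg.study = StudyParams(**study_kwargs)
        cfg.min_patients_per_model = int(raw.get("min_patients_per_model", cfg.min_patients_per_model))
        return cfg


def build_analysis_set(
    assignments: list[CohortAssignment],
    std_measurements: pd.DataFrame,
    patients: pd.DataFrame,
    rx_by_patient: dict,
    measure: str,
    params: StudyParams,
) -> pd.DataFrame:
    """Long-format analysis data for one measure: one row per included
    measurement with times, covariates and the pre/post flag."""
    sex_by_pat = patients.set_index("patient_id")["sex"].to_dict()
    birth_by_pat = patients.set_index("patient_id")["birth_date"].to_dict()
    meas_groups = dict(tuple(std_measurements.groupby("patient_id"))) if len(std_measurements) else {}
    empty = std_measurements.iloc[0:0]

    frames = []
    flag = f"eligible_{measure}"
    for a in assignments:
        if a.cohort is None or not getattr(a, flag):
            continue
        ms = select_analysis_measurements(a, meas_groups.get(a.patient_id, empty), measure, params)
        if ms.empty or not ms["is_baseline"].any():
            continue
        baseline_date = ms.loc[ms["is_baseline"], "date"].iloc[0]
        birth = birth_by_pat[a.patient_id]
        ms = ms.assign(
            cohort=a.cohort,
            subgroup=a.subgroup,
            sex=sex_by_pat[a.patient_id],
            age_at_baseline=(baseline_date - birth).days / DAYS_PER_YEAR,
            baseline_offset_days=(baseline_date - a.time_zero).days,
            post=(~ms["is_baseline"]).astype(float),
        )
        cov = exposure_covariates(a, rx_by_patient.get(a.patient_id, []))
        for key, value in cov.items():
            ms[key] = value
        frames.append(ms)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["patient_id", "time_years"], kind="stable").reset_index(drop=True)


def summarize_baseline(analysis: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Baseline z-score summary per cohort/subgroup: n, mean with 95%
    normal-theory CI, percentile label of the mean, baseline-measurement
    timing, and the distribution of post-baseline measurement counts."""
    rows = []
    base = analysis[analysis["is_baseline"]]
    post_counts = (
        analysis[~analysis["is_baseline"]].groupby("patient_id").size()
    )

    def cell(label, sub):
        n = len(sub)
        if n == 0:
            return None
        z = sub["z"].to_numpy()
        mean = z.mean()
        se = z.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        counts = post_counts.reindex(sub["patient_id"]).fillna(0).astype(int)
        dist = {
            "n_post_1": int((counts == 1).sum()),
            "n_post_2": int((counts == 2).sum()),
            "n_post_3": int((counts == 3).sum()),
            "n_post_4plus": int((counts >= 4).sum()),
        }
        offs = sub["baseline_offset_days"].to_numpy(dtype=float)
        return dict(
            measure=measure,
            group=label,
            n=n,
            baseline_z_mean=mean,
            baseline_z_ci_low=mean - 1.96 * se if n > 1 else np.nan,
            baseline_z_ci_high=mean + 1.96 * se if n > 1 else np.nan,
            percentile=z_to_percentile_label(mean),
            baseline_days_mean=offs.mean(),
            baseline_days_sd=offs.std(ddof=1) if n > 1 else np.nan,
            **dist,
        )

    groups = [("guanfacine_all", base[base["cohort"] == "guanfacine"])]
    for sg in ("first_line_guanfacine_mono", "nonfirst_line_guanfacine_mono", "combined_pharmacotherapy"):
        groups.append((sg, base[base["subgroup"] == sg]))
    groups.append(("first_line_stimulant", base[base["cohort"] == "first_line_stimulant"]))
    groups.append(("unmedicated", base[base["cohort"] == "unmedicated"]))
    for label, sub in groups:
        row = cell(label, sub)
        if row is None:
            logger.warning("baseline summary: empty group %s (%s) omitted", label, measure)
            continue
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis and write all artifacts under ``outdir``.

    Returns the run report (also written to ``run_report.json``).
    """
    t_start = time.perf_counter()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.study

    # ---- stage 1: inputs -------------------------------------------------
    from .io import load_lms_tables, read_extract_dir, write_extract_dir

    truth = None
    if config.input_dir is not None:
        data = read_extract_dir(config.input_dir)
        patients, prescriptions = data["patients"], data["prescriptions"]
        diagnoses, measurements = data["diagnoses"], data["measurements"]
        lms_candidate = Path(config.input_dir) / "lms.csv"
        if config.lms_path:
            tables = load_lms_tables(combined_path=config.lms_path)
        elif lms_candidate.exists():
            tables = load_lms_tables(combined_path=lms_candidate)
        else:
            tables = {m: make_synthetic_lms_table(m) for m in ("weight", "height")}
    else:
        sim = config.simulate or SimulationConfig(seed=config.seed)
        tables = {m: make_synthetic_lms_table(m) for m in ("weight", "height")}
        patients, prescriptions, diagnoses, measurements, truth = simulate_population(sim, tables)
        write_extract_dir(outdir / "extract", patients, prescriptions, diagnoses, measurements, truth)
        pd.concat([t.frame.assign(measure=m) for m, t in tables.items()]).to_csv(
            outdir / "extract" / "lms.csv", index=False
        )

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_patients_in": int(len(patients)),
        "stages": {},
        "artifacts": [],
    }

    # ---- stage 2: standardization ---------------------------------------
    std = standardize_frame(measurements, patients, tables)
    report["stages"]["standardize"] = {
        "measurements_in": int(len(measurements)),
        "measurements_out": int(len(std)),
        "dropped_age_out_of_range": int(std.attrs.get("n_dropped_age_range", 0)),
    }
    _write(std, outdir / "standardized_measurements.csv", report)

    # ---- stage 3: cohorts ------------------------------------------------
    assignments = build_assignments(patients, prescriptions, diagnoses, std, params)
    assign_df = _assignments_frame(assignments, patients)
    _write(assign_df, outdir / "cohort_assignments.csv", report)
    excl = assign_df[assign_df["cohort"].isna() | (~assign_df["eligible_weight"] & ~assign_df["eligible_height"])]
    excl = excl[["patient_id", "exclusion_reasons"]]
    _write(excl, outdir / "exclusions.csv", report)
    included = assign_df["cohort"].notna() & (assign_df["eligible_weight"] | assign_df["eligible_height"])
    report["stages"]["cohorts"] = {
        "patients_in": int(len(assign_df)),
        "included": int(included.sum()),
        "excluded": int((~included).sum()),
        "by_cohort": assign_df.loc[included, "cohort"].value_counts().to_dict(),
    }

    # ---- stage 4: exposure metrics --------------------------------------
    rx_by_pat = _prescriptions_by_patient(prescriptions)
    exp_rows = []
    for a in assignments:
        if a.episode is None or a.cohort is None:
            continue
        m = episode_metrics(rx_by_pat.get(a.patient_id, []), a.episode)
        exp_rows.append(
            dict(
                patient_id=a.patient_id,
                drug_classes="+".join(sorted(a.episode.drug_classes)),
                episode_start=a.episode.start_date,
                discontinuation_date=a.episode.discontinuation_date,
                prescribed_amount_days=m.prescribed_amount_days,
                episode_length_days=m.episode_length_days,
                mpr=m.mpr,
            )
        )
    exposure_df = pd.DataFrame(exp_rows)
    _write(exposure_df, outdir / "exposure_metrics.csv", report)
    report["stages"]["exposure"] = {"episodes": int(len(exposure_df))}

    # ---- stage 5 + 6: analysis sets, models -----------------------------
    coef_frames, cov_rows, pred_frames, prepost_rows, base_frames, shift_frames = [], [], [], [], [], []
    analysis_counts = {}
    for measure in ("weight", "height"):
        analysis = build_analysis_set(assignments, std, patients, rx_by_pat, measure, params)
        _write(analysis, outdir / f"analysis_set_{measure}.csv", report)
        analysis_counts[measure] = {
            "patients": int(analysis["patient_id"].nunique()) if len(analysis) else 0,
            "observations": int(len(analysis)),
        }
        if analysis.empty:
            continue
        base_frames.append(summarize_baseline(analysis, measure))

        for family in FAMILIES:
            fam_data = analysis[analysis["cohort"] == family]
            for stratum in ("all", "male", "female"):
                sub = fam_data if stratum == "all" else fam_data[fam_data["sex"] == stratum]
                n_pat = sub["patient_id"].nunique()
                if n_pat < config.min_patients_per_model:
                    logger.info("skipping %s/%s/%s: %d patients", family, measure, stratum, n_pat)
                    continue
                spec = TrajectoryModelSpec(measure, family, stratum)
                fit = fit_random_coefficients(fam_data, spec)
                sf = fit.summary_frame()
                sf.insert(0, "stratum", stratum)
                sf.insert(0, "family", family)
                sf.insert(0, "measure", measure)
                sf["df"] = fit.n_obs - len(fit.params)
                sf["converged"] = fit.converged
                coef_frames.append(sf)
                cov = fit.random_covariance
                cov_rows.append(
                    dict(measure=measure, family=family, stratum=stratum,
                         var_intercept=cov[0, 0], var_time=cov[1, 1], var_time2=cov[2, 2],
                         cov_int_time=cov[0, 1], cov_int_time2=cov[0, 2], cov_time_time2=cov[1, 2],
                         residual_variance=fit.residual_variance,
                         n_obs=fit.n_obs, n_patients=fit.n_patients, llf=fit.llf)
                )
                if stratum == "all":
                    grid = np.round(np.arange(0.0, config.prediction_horizon_years + 1e-9, 0.1), 3)
                    if family == "guanfacine":
                        for sg in ("first_line_guanfacine_mono", "nonfirst_line_guanfacine_mono",
                                   "combined_pharmacotherapy"):
                            sg_mean = float(
                                fam_data.loc[fam_data["subgroup"] == sg]
                                .groupby("patient_id")["stim_days_preguanfacine"].first().mean()
                            ) if (fam_data["subgroup"] == sg).any() else 0.0
                            pred = predict_trajectory(
                                fit, grid, subgroup=sg,
                                covariate_overrides={"stim_days_preguanfacine": sg_mean},
                            )
                            pred.insert(0, "group", sg)
                            pred.insert(0, "measure", measure)
                            pred_frames.append(pred)
                    else:
                        pred = predict_trajectory(fit, grid)
                        pred.insert(0, "group", family)
                        pred.insert(0, "measure", measure)
                        pred_frames.append(pred)

        # pre/post models: treatment-naive populations, by sex
        for label, (family, subgroup) in PREPOST_POPULATIONS.items():
            sub = analysis[analysis["cohort"] == family]
            if subgroup is not None:
                sub = sub[sub["subgroup"] == subgroup]
            for sex in ("male", "female"):
                cell = sub[sub["sex"] == sex]
                n_pat = cell["patient_id"].nunique()
                if n_pat < config.min_patients_per_model:
                    continue
                try:
                    pp = fit_prepost(cell, sex_stratum=sex)
                except (ValueError, RuntimeError) as exc:
                    logger.warning("pre/post %s/%s/%s failed: %s", label, measure, sex, exc)
                    continue
                prepost_rows.append(
                    dict(measure=measure, population=label, sex=sex, n=n_pat,
                         modeled_z_time0=pp.intercept,
                         ci_low=pp.intercept_ci[0], ci_high=pp.intercept_ci[1],
                         percentile=z_to_percentile_label(pp.intercept),
                         coefficient=pp.prepost_coefficient, se=pp.prepost_se,
                         t=pp.prepost_t, p=pp.prepost_p, converged=pp.converged)
                )

        # individual shifts (guanfacine subgroups)
        gx = analysis[analysis["cohort"] == "guanfacine"]
        shift_records = []
        for pid, sub in gx.groupby("patient_id"):
            base_rows = sub[sub["is_baseline"]]
            post_rows = sub[~sub["is_baseline"]].sort_values("time_years")
            if base_rows.empty or post_rows.empty:
                continue
            res = classify_shift(pid, measure, float(base_rows["z"].iloc[0]), float(post_rows["z"].iloc[-1]))
            shift_records.append(
                dict(patient_id=pid, measure=measure, z_baseline=res.z_baseline,
                     z_final=res.z_final, lines_crossed=res.lines_crossed,
                     direction=res.direction)
            )
        if shift_records:
            shift_df = pd.DataFrame(shift_records)
            pat_info = gx.groupby("patient_id").agg(subgroup=("subgroup", "first"), sex=("sex", "first")).reset_index()
            shift_frames.append(shift_table(shift_df, pat_info))
            _write(shift_df, outdir / f"shift_results_{measure}.csv", report)

    report["stages"]["analysis_sets"] = analysis_counts
    _write(_concat(coef_frames), outdir / "model_coefficients.csv", report)
    _write(pd.DataFrame(cov_rows), outdir / "model_covariances.csv", report)
    _write(_concat(pred_frames), outdir / "predicted_trajectories.csv", report)
    _write(pd.DataFrame(prepost_rows), outdir / "prepost_models.csv", report)
    _write(_concat(base_frames), outdir / "baseline_summary.csv", report)
    _write(_concat(shift_frames), outdir / "shift_table.csv", report)

    report["stages"]["models"] = {
        "trajectory_models": len(cov_rows),
        "prepost_models": len(prepost_rows),
    }
    report["wall_time_s"] = round(time.perf_counter() - t_start, 3)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def _assignments_frame(assignments: list[CohortAssignment], patients: pd.DataFrame) -> pd.DataFrame:
    sex_by_pat = patients.set_index("patient_id")["sex"].to_dict()
    rows = []
    for a in assignments:
        rows.append(
            dict(
                patient_id=a.patient_id,
                sex=sex_by_pat.get(a.patient_id),
                cohort=a.cohort,
                subgroup=a.subgroup,
                index_date=a.index_date,
                guanfacine_initiation_date=a.guanfacine_initiation_date,
                time_zero=a.time_zero,
                censor_date=a.censor,
                analysis_end=a.analysis_end,
                eligible_weight=a.eligible_weight,
                eligible_height=a.eligible_height,
                exclusion_reasons=";".join(a.exclusion_reasons),
            )
        )
    return pd.DataFrame(rows)


def _concat(frames: list) -> pd.DataFrame:
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _write(df: pd.DataFrame, path: Path, report: dict) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    report["artifacts"].append(path.name)
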