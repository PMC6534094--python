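"""Random-coefficients mixed models for longitudinal z-score trajectories.

Each cohort family is analyzed with a linear mixed model in which every
patient carries random intercept, linear-time, and quadratic-time
coefficients with a freely estimated (unstructured) 3x3 covariance, plus
independent Gaussian residuals.  Fixed effects depend on the family:

* guanfacine family: age at baseline, gender (all-patients stratum only),
  guanfacine MPR over the initial exposure, stimulant supply days before
  guanfacine, atomoxetine use before/during exposure, treatment-regimen
  subgroup (reference = combined pharmacotherapy), time, time squared, and
  time x subgroup interactions;
* first-line stimulant family: age at baseline, gender (all only),
  stimulant MPR, time, time squared;
* unmedicated family: age at baseline, gender (all only), time, time
  squared.

Estimation is restricted maximum likelihood through
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; p-values are
nominal (no multiplicity adjustment).  A companion pre/post model regresses
z on a single binary after-initiation indicator with random linear and
quadratic time, so its coefficient is the mean z change after initiation
versus before, across all time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TrajectoryModelSpec",
    "TrajectoryModelFit",
    "PrePostModelFit",
    "build_design",
    "fit_random_coefficients",
    "fit_prepost",
    "predict_trajectory",
]

logger = logging.getLogger(__name__)

SUBGROUP_REFERENCE = "combined_pharmacotherapy"
SUBGROUP_LEVELS = (
    "combined_pharmacotherapy",
    "first_line_guanfacine_mono",
    "nonfirst_line_guanfacine_mono",
)

FAMILY_COVARIATES = {
    "guanfacine": (
        "age_at_baseline",
        "female",
        "guanfacine_mpr",
        "stim_days_preguanfacine",
        "atomoxetine_before",
        "atomoxetine_during",
    ),
    "first_line_stimulant": ("age_at_baseline", "female", "stimulant_mpr"),
    "unmedicated": ("age_at_baseline", "female"),
}


@dataclass(frozen=True)
class TrajectoryModelSpec:
    response: str                  # weight | height
    cohort_family: str             # guanfacine | first_line_stimulant | unmedicated
    sex_stratum: str = "all"       # all | male | female

    def __post_init__(self):
        if self.cohort_family not in FAMILY_COVARIATES:
            raise ValueError(f"unknown cohort family {self.cohort_family!r}")
        if self.sex_stratum not in ("all", "male", "female"):
            raise ValueError(f"unknown sex stratum {self.sex_stratum!r}")

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        terms = ["const"]
        for c in FAMILY_COVARIATES[self.cohort_family]:
            if c == "female" and self.sex_stratum != "all":
                continue
            terms.append(c)
        if self.cohort_family == "guanfacine":
            terms += [
                "subgroup_first_line",
                "subgroup_nonfirst_line",
                "time",
                "time2",
                "time_x_first_line",
                "time_x_nonfirst_line",
            ]
        else:
            terms += ["time", "time2"]
        return tuple(terms)


@dataclass
class TrajectoryModelFit:
    spec: TrajectoryModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    random_covariance: np.ndarray   # 3x3, patient-level [1, t, t^2]
    residual_variance: float
    converged: bool
    llf: float
    n_obs: int
    n_patients: int
    covariate_means: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "coefficient": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "t": self.tvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )


@dataclass
class PrePostModelFit:
    intercept: float                 # modeled z at time 0
    intercept_ci: tuple[float, float]
    prepost_coefficient: float
    prepost_se: float
    prepost_t: float
    prepost_p: float
    converged: bool
    n_obs: int
    n_patients: int


def build_design(data: pd.DataFrame, spec: TrajectoryModelSpec) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Fixed-effect design for one model.

    ``data`` is long format with one row per measurement: patient_id,
    time_years, z, sex, and the family's covariate columns (guanfacine
    family additionally ``subgroup``).  Reference levels: male for gender,
    "no" for binary medication indicators, combined pharmacotherapy for the
    subgroup.  Raises on missing covariates, naming the patient and term.
    """
    df = data
    if spec.sex_stratum != "all":
        df = df[df["sex"] == spec.sex_stratum]
    if df.empty:
        raise ValueError(f"no observations in stratum {spec.sex_stratum!r}")
    df = df.reset_index(drop=True)

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for cov in FAMILY_COVARIATES[spec.cohort_family]:
        if cov == "female":
            if spec.sex_stratum == "all":
                X["female"] = (df["sex"] == "female").astype(float)
            continue
        if cov not in df.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        col = pd.to_numeric(df[cov], errors="coerce")
        if col.isna().any():
            bad = df.loc[col.isna(), "patient_id"].iloc[0]
            raise ValueError(f"missing covariate {cov!r} for patient {bad!r}")
        X[cov] = col.astype(float)

    t = df["time_years"].astype(float)
    if spec.cohort_family == "guanfacine":
        unknown = set(df["subgroup"].unique()) - set(SUBGROUP_LEVELS)
        if unknown:
            raise ValueError(f"unknown subgroup level(s): {sorted(unknown)}")
        fl = (df["subgroup"] == "first_line_guanfacine_mono").astype(float)
        nfl = (df["subgroup"] == "nonfirst_line_guanfacine_mono").astype(float)
        X["subgroup_first_line"] = fl
        X["subgroup_nonfirst_line"] = nfl
        X["time"] = t
        X["time2"] = t ** 2
        X["time_x_first_line"] = t * fl
        X["time_x_nonfirst_line"] = t * nfl
    else:
        X["time"] = t
        X["time2"] = t ** 2

    assert tuple(X.columns) == spec.fixed_terms
    return df["z"].astype(float), X, df["patient_id"]


def _random_design(X: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X["time"].to_numpy(), X["time2"].to_numpy()])


def fit_random_coefficients(
    data: pd.DataFrame,
    spec: TrajectoryModelSpec,
    *,
    reml: bool = True,
    maxiter: int = 200,
    include_random: bool = True,
) -> TrajectoryModelFit:
    """Fit the trajectory model by REML.

    ``include_random=False`` drops the random part entirely (OLS on the
    fixed design) -- the degenerate limit used for validation.  If the
    unstructured random covariance cannot be estimated (singular fit), the
    model is refit with an independent (diagonal) covariance and a warning
    is logged; the returned covariance is always symmetric PSD.
    """
    y, X, groups = build_design(data, spec)

    if not include_random:
        ols = sm.OLS(y, X).fit()
        return TrajectoryModelFit(
            spec=spec,
            params=ols.params,
            bse=ols.bse,
            tvalues=ols.tvalues,
            pvalues=ols.pvalues,
            random_covariance=np.zeros((3, 3)),
            residual_variance=float(ols.scale),
            converged=True,
            llf=float(ols.llf),
            n_obs=int(len(y)),
            n_patients=int(groups.nunique()),
            covariate_means=_covariate_means(X),
        )

    exog_re = _random_design(X)
    model = MixedLM(y.to_numpy(), X.to_numpy(), groups=groups.to_numpy(), exog_re=exog_re)
    result, converged = _fit_mixedlm(model, reml=reml, maxiter=maxiter)
    if result is None:
        logger.warning("unstructured covariance singular; refitting with diagonal covariance")
        free = MixedLMParams.from_components(
            fe_params=np.ones(X.shape[1]), cov_re=np.eye(3)
        )
        result, converged = _fit_mixedlm(model, reml=reml, maxiter=maxiter, free=free)
        if result is None:
            # fully degenerate likelihood (e.g. zero residual variance):
            # the model collapses to its fixed part
            logger.warning("random-effects likelihood degenerate; reporting the fixed-part fit")
            return fit_random_coefficients(
                data, spec, reml=reml, maxiter=maxiter, include_random=False
            )

    names = list(X.columns)
    cov_re = _nearest_psd(np.asarray(result.cov_re))
    k = X.shape[1]
    return TrajectoryModelFit(
        spec=spec,
        params=pd.Series(result.params[:k], index=names),
        bse=pd.Series(result.bse[:k], index=names),
        tvalues=pd.Series(result.tvalues[:k], index=names),
        pvalues=pd.Series(result.pvalues[:k], index=names),
        random_covariance=cov_re,
        residual_variance=float(result.scale),
        converged=bool(converged),
        llf=float(result.llf),
        n_obs=int(len(y)),
        n_patients=int(groups.nunique()),
        covariate_means=_covariate_means(X),
    )


def _fit_mixedlm(model, *, reml, maxiter, free=None):
    """Try a sequence of optimizers; return (result, converged) or (None, _)."""
    for method in ("lbfgs", "cg", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                result = model.fit(reml=reml, method=method, maxiter=maxiter, free=free)
            except (np.linalg.LinAlgError, ValueError):
                continue
        if result is not None and np.all(np.isfinite(result.params)):
            converged = bool(getattr(result, "converged", True))
            if converged:
                return result, True
            fallback = result
    if "fallback" in locals():
        return fallback, False
    return None, False


def _nearest_psd(a: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone (eigenvalue floor)."""
    sym = (a + a.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, floor, None)
    return (v * w) @ v.T


def _covariate_means(X: pd.DataFrame) -> dict:
    skip = {"const", "time", "time2", "time_x_first_line", "time_x_nonfirst_line",
            "subgroup_first_line", "subgroup_nonfirst_line"}
    return {c: float(X[c].mean()) for c in X.columns if c not in skip}


def predict_trajectory(
    fit: TrajectoryModelFit,
    time_grid,
    subgroup: str | None = None,
    covariate_overrides: dict | None = None,
) -> pd.DataFrame:
    """Fixed-effect predicted z over a time grid with covariates held at
    their analysis-population means (overridable, e.g. to hold stimulant
    supply at a subgroup-specific mean).

    Times outside roughly the observed range are permitted but flagged in
    the ``extrapolated`` column.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    means = dict(fit.covariate_means)
    if covariate_overrides:
        means.update(covariate_overrides)
    beta = fit.params
    base = beta["const"] + sum(beta[c] * means.get(c, 0.0) for c in means)
    z_hat = np.full_like(time_grid, base, dtype=float)
    z_hat += beta["time"] * time_grid + beta["time2"] * time_grid ** 2
    if fit.spec.cohort_family == "guanfacine":
        if subgroup is None:
            raise ValueError("subgroup required for guanfacine-family predictions")
        if subgroup == "first_line_guanfacine_mono":
            z_hat += beta["subgroup_first_line"] + beta["time_x_first_line"] * time_grid
        elif subgroup == "nonfirst_line_guanfacine_mono":
            z_hat += beta["subgroup_nonfirst_line"] + beta["time_x_nonfirst_line"] * time_grid
        elif subgroup != SUBGROUP_REFERENCE:
            raise ValueError(f"unknown subgroup {subgroup!r}")
    out = pd.DataFrame({"time_years": time_grid, "z_hat": z_hat})
    out["extrapolated"] = time_grid < 0
    return out


def fit_prepost(
    data: pd.DataFrame,
    sex_stratum: str = "all",
    *,
    reml: bool = True,
    maxiter: int = 200,
) -> PrePostModelFit:
    """Pre/post treatment-initiation model.

    ``data`` is long format with columns patient_id, time_years, z, sex and
    a boolean/0-1 ``post`` flag (measurement on/after the index date).  The
    model is z ~ 1 + post with patient-level random linear and quadratic
    time; the intercept is the modeled z at time 0 before initiation and
    the ``post`` coefficient the mean change afterwards.
    """
    df = data if sex_stratum == "all" else data[data["sex"] == sex_stratum]
    df = df.reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no observations in stratum {sex_stratum!r}")
    post = df["post"].astype(float)
    if (post == 1).all() or (post == 0).all():
        raise ValueError("pre/post model needs both pre and post observations")
    X = pd.DataFrame({"const": 1.0, "post": post})
    t = df["time_years"].to_numpy(dtype=float)
    exog_re = np.column_stack([t, t ** 2])
    model = MixedLM(
        df["z"].to_numpy(dtype=float), X.to_numpy(), groups=df["patient_id"].to_numpy(),
        exog_re=exog_re,
    )
    result, converged = _fit_mixedlm(model, reml=reml, maxiter=maxiter)
    if result is None:
        raise RuntimeError("pre/post model failed to converge")
    b0, delta = result.params[0], result.params[1]
    ci = (b0 - 1.96 * result.bse[0], b0 + 1.96 * result.bse[0])
    return PrePostModelFit(
        intercept=float(b0),
        intercept_ci=(float(ci[0]), float(ci[1])),
        prepost_coefficient=float(delta),
        prepost_se=float(result.bse[1]),
        prepost_t=float(result.tvalues[1]),
        prepost_p=float(result.pvalues[1]),
        converged=bool(converged),
        n_obs=int(len(df)),
        n_patients=int(df["patient_id"].nunique()),
    )
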