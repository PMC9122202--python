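"""Per-cohort regressions: the MR stage models and the observational
quadratic heart-rate model.

Cox proportional-hazards fits go through :class:`lifelines.CoxPHFitter`
(Efron tie handling, Newton iterations); logistic and least-squares fits
go through :mod:`statsmodels`. Every fitted coefficient is returned as a
:class:`StageEstimate` whose p-value follows the two-sided normal Wald
convention ``p = 2 * (1 - Phi(|beta/se|))``, the same convention used
when the estimates are pooled across cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    NoEventsError,
    NoVariationError,
    SeparationError,
    SingularDesignError,
    ValidationError,
)
from .io_formats import CohortDataset, pc_columns

logger = logging.getLogger(__name__)

#: Default adjustment set for every model (PCs and center are appended
#: automatically when present in the phenotype table).
DEFAULT_COVARIATES = ("age", "sex", "pcs", "center")

SEX_CODE = {"female": 0.0, "male": 1.0}


@dataclass
class StageEstimate:
    """One fitted coefficient from one regression in one cohort."""

    cohort: str
    stratum: str  # low / mid / high / all
    model: str  # hr_linear, hr_quadratic, prs_on_hr, prs_on_af, prs_on_af_adj_hr
    beta: float
    se: float
    p: float
    n: int
    n_events: int
    outcome_scale: str  # log_hazard, log_odds, linear

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError(f"negative se {self.se}")
        if self.n_events > self.n:
            raise ValidationError("n_events exceeds n")


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal Wald p-value; degenerate se=0 maps to 0 or 1."""
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def build_covariate_frame(
    df: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Expand a covariate request into a numeric design block.

    ``"sex"`` maps female=0 / male=1; ``"pcs"`` expands to every pc<k>
    column present; ``"center"`` expands to drop-first indicator columns
    when the table has a center column with >1 level. Requested columns
    absent from the table are skipped silently (cohorts differ in which
    optional covariates they carry).
    """
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "sex" and "sex" in df:
            cols["sex"] = df["sex"].map(SEX_CODE).to_numpy(dtype=float)
        elif cov == "pcs":
            for pc in pc_columns(df):
                cols[pc] = df[pc].to_numpy(dtype=float)
        elif cov == "center":
            if "center" in df and df["center"].nunique() > 1:
                dummies = pd.get_dummies(df["center"], prefix="center", drop_first=True)
                for c in dummies:
                    cols[c] = dummies[c].to_numpy(dtype=float)
        elif cov in df:
            cols[cov] = df[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def check_full_rank(design: pd.DataFrame, with_intercept: bool = True) -> None:
    """Raise :class:`SingularDesignError` naming suspect columns if the
    design (plus intercept) is rank-deficient."""
    X = design.to_numpy(dtype=float)
    if with_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        constant = [c for c in design.columns if design[c].nunique() <= 1]
        detail = f"constant column(s): {constant}" if constant else "collinear columns"
        raise SingularDesignError(
            f"design with columns {list(design.columns)} is rank-deficient "
            f"({rank} < {X.shape[1]}); {detail}"
        )


def fit_linear(
    design: pd.DataFrame,
    response: np.ndarray,
    target_term: str,
    *,
    cohort: str = "",
    stratum: str = "all",
    model: str = "prs_on_hr",
) -> StageEstimate:
    """Ordinary least squares of ``response`` on the design (plus
    intercept); returns the coefficient of ``target_term``."""
    import statsmodels.api as sm

    check_full_rank(design)
    X = sm.add_constant(design, has_constant="add")
    res = sm.OLS(np.asarray(response, dtype=float), X).fit()
    beta = float(res.params[target_term])
    se = float(res.bse[target_term])
    if not np.isfinite(se):  # saturated/exact fit: zero residual variance
        se = 0.0
    return StageEstimate(
        cohort=cohort,
        stratum=stratum,
        model=model,
        beta=beta,
        se=se,
        p=wald_p(beta, se),
        n=int(res.nobs),
        n_events=0,
        outcome_scale="linear",
    )


def _fit_cox_model(
    design: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    cohort: str,
    stratum: str,
):
    """Fit a checked Cox model; returns the fitted lifelines object."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LLConvergenceError
    from lifelines.exceptions import ConvergenceWarning as LLConvergenceWarning

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise NoEventsError(f"cohort {cohort}, stratum {stratum}: no events")
    if np.any(time <= 0):
        raise ValidationError(f"cohort {cohort}: non-positive follow-up time")
    check_full_rank(design, with_intercept=False)

    df = design.reset_index(drop=True).copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={"precision": 1e-9, "max_steps": 500},
            )
        except (LLConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            raise ConvergenceError(
                f"cohort {cohort}, stratum {stratum}: Cox fit failed: {exc}"
            ) from exc
    for w in caught:
        if issubclass(w.category, LLConvergenceWarning) and (
            "complete separation" in str(w.message)
            or "convergence" in str(w.message).lower()
        ):
            raise ConvergenceError(
                f"cohort {cohort}, stratum {stratum}: monotone likelihood / "
                f"non-convergence: {w.message}"
            )
    return cph


def fit_cox(
    design: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    target_term: str,
    *,
    cohort: str = "",
    stratum: str = "all",
    model: str = "prs_on_af",
) -> StageEstimate:
    """Cox proportional-hazards fit; returns the ``target_term``
    coefficient on the log-hazard scale.

    Ties are handled with Efron's approximation; the SE comes from the
    observed information. Monotone likelihoods (e.g. a covariate that
    perfectly separates events) surface as :class:`ConvergenceError`.
    """
    cph = _fit_cox_model(design, time, event, cohort, stratum)
    beta = float(cph.params_[target_term])
    se = float(cph.standard_errors_[target_term])
    event = np.asarray(event, dtype=int)
    return StageEstimate(
        cohort=cohort,
        stratum=stratum,
        model=model,
        beta=beta,
        se=se,
        p=wald_p(beta, se),
        n=len(design),
        n_events=int(event.sum()),
        outcome_scale="log_hazard",
    )


def fit_logistic(
    design: pd.DataFrame,
    event: np.ndarray,
    target_term: str,
    *,
    cohort: str = "",
    stratum: str = "all",
    model: str = "prs_on_af",
) -> StageEstimate:
    """Maximum-likelihood logistic fit; the log-odds coefficient is used
    downstream as an approximation of the log-hazard when a cohort has
    no time-to-event information."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    event = np.asarray(event, dtype=float)
    classes = np.unique(event)
    if len(classes) < 2:
        raise NoVariationError(
            f"cohort {cohort}, stratum {stratum}: outcome has a single class"
        )
    check_full_rank(design)
    X = sm.add_constant(design, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(event, X).fit(disp=0, maxiter=100)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"cohort {cohort}, stratum {stratum}: perfect separation"
            ) from exc
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
        raise SeparationError(
            f"cohort {cohort}, stratum {stratum}: logistic fit did not "
            "converge (separation suspected)"
        )
    beta = float(res.params[target_term])
    se = float(res.bse[target_term])
    return StageEstimate(
        cohort=cohort,
        stratum=stratum,
        model=model,
        beta=beta,
        se=se,
        p=wald_p(beta, se),
        n=int(res.nobs),
        n_events=int(event.sum()),
        outcome_scale="log_odds",
    )


def _fit_af_model(
    cohort: CohortDataset,
    design: pd.DataFrame,
    sub: pd.DataFrame,
    target_term: str,
    *,
    stratum: str,
    model: str,
) -> StageEstimate:
    if cohort.has_time_to_event:
        return fit_cox(
            design,
            sub["followup_time"].to_numpy(),
            sub["af_event"].to_numpy(),
            target_term,
            cohort=cohort.name,
            stratum=stratum,
            model=model,
        )
    return fit_logistic(
        design,
        sub["af_event"].to_numpy(),
        target_term,
        cohort=cohort.name,
        stratum=stratum,
        model=model,
    )


@dataclass
class QuadraticFit:
    """Linear and quadratic heart-rate coefficients from the
    observational AF model, parameterised around ``center`` bpm."""

    linear: StageEstimate
    quadratic: StageEstimate
    cov_lin_quad: float
    center: float


def fit_quadratic_hr_model(
    cohort: CohortDataset,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    hr_center: float = 70.0,
) -> QuadraticFit:
    """Observational model of incident AF on heart rate with linear and
    quadratic terms plus covariates, on the full (unstratified) cohort.

    Heart rate enters centred at ``hr_center`` bpm: the quadratic
    coefficient is unchanged by centring, and a common centre keeps the
    linear coefficients poolable across cohorts.
    """
    df = cohort.phenotypes
    hr_c = df["heart_rate"].to_numpy(dtype=float) - hr_center
    design = build_covariate_frame(df, covariates)
    design.insert(0, "hr_quad", hr_c**2)
    design.insert(0, "hr_lin", hr_c)

    if cohort.has_time_to_event:
        cph = _fit_cox_model(
            design,
            df["followup_time"].to_numpy(),
            df["af_event"].to_numpy(),
            cohort.name,
            "all",
        )
        cov = float(cph.variance_matrix_.loc["hr_lin", "hr_quad"])
        n, n_events = len(df), int(df["af_event"].sum())
        lin, quad = (
            StageEstimate(
                cohort=cohort.name,
                stratum="all",
                model=model_name,
                beta=float(cph.params_[term]),
                se=float(cph.standard_errors_[term]),
                p=wald_p(float(cph.params_[term]), float(cph.standard_errors_[term])),
                n=n,
                n_events=n_events,
                outcome_scale="log_hazard",
            )
            for model_name, term in (("hr_linear", "hr_lin"), ("hr_quadratic", "hr_quad"))
        )
    else:
        import statsmodels.api as sm

        check_full_rank(design)
        X = sm.add_constant(design, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(df["af_event"].to_numpy(dtype=float), X).fit(disp=0)
        cov = float(res.cov_params().loc["hr_lin", "hr_quad"])
        lin = StageEstimate(
            cohort=cohort.name,
            stratum="all",
            model="hr_linear",
            beta=float(res.params["hr_lin"]),
            se=float(res.bse["hr_lin"]),
            p=wald_p(float(res.params["hr_lin"]), float(res.bse["hr_lin"])),
            n=int(res.nobs),
            n_events=int(df["af_event"].sum()),
            outcome_scale="log_odds",
        )
        quad = StageEstimate(
            cohort=cohort.name,
            stratum="all",
            model="hr_quadratic",
            beta=float(res.params["hr_quad"]),
            se=float(res.bse["hr_quad"]),
            p=wald_p(float(res.params["hr_quad"]), float(res.bse["hr_quad"])),
            n=int(res.nobs),
            n_events=int(df["af_event"].sum()),
            outcome_scale="log_odds",
        )
    return QuadraticFit(linear=lin, quadratic=quad, cov_lin_quad=cov, center=hr_center)


def fit_stage_regressions(
    cohort: CohortDataset,
    prs: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[StageEstimate]:
    """Fit the three MR stage models within each heart-rate stratum.

    Per stratum: (i) ``prs_on_hr`` — least squares of heart rate on the
    PRS plus covariates (ratio denominator); (ii) ``prs_on_af`` — Cox or
    logistic of incident AF on the PRS plus covariates (ratio
    numerator); (iii) ``prs_on_af_adj_hr`` — as (ii) additionally
    adjusted for heart rate (pleiotropy model: a PRS effect surviving
    heart-rate adjustment suggests an outcome path bypassing the
    exposure).

    Strata with zero events are skipped with a logged warning; they
    cannot contribute a partial-likelihood estimate.
    """
    df = cohort.phenotypes.merge(
        prs[["sample_id", "prs"]], on="sample_id", validate="one_to_one"
    ).merge(
        assignments[["sample_id", "stratum"]], on="sample_id", validate="one_to_one"
    )
    estimates: list[StageEstimate] = []
    for stratum in ("low", "mid", "high"):
        sub = df[df["stratum"] == stratum]
        if len(sub) == 0:
            logger.warning("cohort %s: stratum %s empty, skipped", cohort.name, stratum)
            continue
        if sub["af_event"].sum() == 0:
            logger.warning(
                "cohort %s: stratum %s has zero events, excluded from meta-analysis",
                cohort.name,
                stratum,
            )
            continue
        base = build_covariate_frame(sub, covariates)
        design = base.copy()
        design.insert(0, "prs", sub["prs"].to_numpy(dtype=float))
        estimates.append(
            fit_linear(
                design,
                sub["heart_rate"].to_numpy(dtype=float),
                "prs",
                cohort=cohort.name,
                stratum=stratum,
                model="prs_on_hr",
            )
        )
        estimates.append(
            _fit_af_model(cohort, design, sub, "prs", stratum=stratum, model="prs_on_af")
        )
        design_adj = design.copy()
        design_adj["heart_rate"] = sub["heart_rate"].to_numpy(dtype=float)
        estimates.append(
            _fit_af_model(
                cohort, design_adj, sub, "prs", stratum=stratum, model="prs_on_af_adj_hr"
            )
        )
    return estimates
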