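"""End-to-end orchestration: PRS -> IV-free stratification -> per-cohort
stage fits -> meta-analysis -> ratio estimates -> report tables.

The in-memory entry point is :func:`analyze_consortium`; the file-level
entry point :func:`run_pipeline` reads a manifest (weights table plus
per-cohort dosage and phenotype files), fails fast if any referenced
file is missing, and writes the result tables. Both are deterministic:
re-running on identical inputs yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_models import (
    DEFAULT_COVARIATES,
    QuadraticFit,
    StageEstimate,
    fit_quadratic_hr_model,
    fit_stage_regressions,
)
from .errors import ConfigurationError, StratMRError
from .io_formats import (
    CohortDataset,
    read_dosages,
    read_phenotypes,
    read_variant_weights,
    write_results_tables,
    VariantWeight,
)
from .meta_analysis import MetaEstimate, fisher_combine, ivw_meta
from .mr_ratio import RatioEstimate, UShapeSummary, ratio_estimate, ushape_summary
from .prs import compute_prs
from .stratification import (
    StratumSpec,
    assign_strata,
    compute_iv_free_hr,
    fit_prs_effect_on_hr,
)

logger = logging.getLogger(__name__)

STRATA = ("low", "mid", "high")
STAGE_MODELS = ("prs_on_hr", "prs_on_af", "prs_on_af_adj_hr")


@dataclass
class PipelineSettings:
    """All analysis thresholds, surfaced with their report-convention
    defaults (cutpoints 65/75 bpm, Bonferroni 0.017, normal 95% CI)."""

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    cutpoints: tuple[float, float] = (65.0, 75.0)
    stratum_mode: str = "fixed"  # fixed | tertiles
    meta_method: str = "fixed"  # method feeding the ratio estimator
    missing_policy: str = "mean_dose"
    allow_ambiguous: bool = False
    weak_f_threshold: float = 10.0
    ci_z: float = 1.96
    bonferroni_n: int = 3
    first_stage_adjusted: bool = True
    hr_center: float = 70.0
    min_complete_cases: int = 10


@dataclass
class PipelineConfig:
    """File-level run configuration (manifest plus settings)."""

    weights: str
    cohorts: list[dict]  # each: name, dosages, phenotypes, optional dialect
    base_dir: str = "."
    settings: PipelineSettings = field(default_factory=PipelineSettings)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not raw.get("cohorts"):
            raise ConfigurationError(f"{path}: manifest lists no cohorts")
        settings_kwargs = raw.get("settings", {})
        for key in ("covariates", "cutpoints"):
            if key in settings_kwargs:
                settings_kwargs[key] = tuple(settings_kwargs[key])
        return cls(
            weights=raw["weights"],
            cohorts=raw["cohorts"],
            base_dir=os.path.dirname(os.path.abspath(path)),
            settings=PipelineSettings(**settings_kwargs),
        )


@dataclass
class CohortAnalysis:
    """Everything computed for one cohort."""

    name: str
    n_input: int
    n_analyzed: int
    n_excluded_prevalent: int
    n_excluded_missing: int
    first_stage: StageEstimate
    prs: pd.DataFrame
    assignments: pd.DataFrame
    quadratic: QuadraticFit
    stages: list[StageEstimate]


@dataclass
class ResultBundle:
    """Full pipeline output: per-cohort, pooled, and causal results."""

    cohorts: list[CohortAnalysis]
    metas: dict[tuple[str, str, str], MetaEstimate]  # (model, stratum, method)
    ratios: list[RatioEstimate]
    ushape: UShapeSummary
    fisher_pleiotropy_p: float
    pooled: dict[str, float]
    cohort_summaries: pd.DataFrame
    stratum_spec: StratumSpec
    settings: PipelineSettings

    def causal_table(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": r.stratum,
                "hr_per_5bpm": r.hr_per_5bpm,
                "ci_low_5bpm": r.ci_low_5bpm,
                "ci_high_5bpm": r.ci_high_5bpm,
                "hr_per_bpm": r.hr_per_bpm,
                "beta_per_bpm": r.beta3,
                "se_per_bpm": r.se3,
                "p": r.p,
                "significant": r.significant,
                "weak_instrument": r.weak_instrument,
                "first_stage_f": r.first_stage_f,
            }
            for r in self.ratios
        ]
        return pd.DataFrame(rows)

    def stage_table(self) -> pd.DataFrame:
        rows = []
        for ca in self.cohorts:
            for est in [ca.first_stage, ca.quadratic.linear, ca.quadratic.quadratic, *ca.stages]:
                rows.append(dataclasses.asdict(est))
        return pd.DataFrame(rows)

    def meta_table(self) -> pd.DataFrame:
        rows = []
        for (model, stratum, method), m in sorted(self.metas.items()):
            row = dataclasses.asdict(m)
            row["method"] = method
            # k=1 pools carry no heterogeneity information
            if m.k <= 1:
                row["Q"] = np.nan
                row["i2"] = np.nan
                row["tau2"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def descriptives_table(self) -> pd.DataFrame:
        return self.cohort_summaries

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {"quantity": "fisher_pleiotropy_p", "value": self.fisher_pleiotropy_p},
            {"quantity": "ushape_beta_lin", "value": self.ushape.beta_lin},
            {"quantity": "ushape_beta_quad", "value": self.ushape.beta_quad},
            {"quantity": "ushape_p_quad", "value": self.ushape.p_quad},
            {
                "quantity": "ushape_nadir_bpm",
                "value": np.nan if self.ushape.nadir_bpm is None else self.ushape.nadir_bpm,
            },
        ]
        rows += [{"quantity": k, "value": v} for k, v in self.pooled.items()]
        return pd.DataFrame(rows)

    def exclusions_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cohort": ca.name,
                    "n_input": ca.n_input,
                    "n_excluded_prevalent_af": ca.n_excluded_prevalent,
                    "n_excluded_missing": ca.n_excluded_missing,
                    "n_analyzed": ca.n_analyzed,
                }
                for ca in self.cohorts
            ]
        )


def _apply_exclusions(cohort: CohortDataset) -> tuple[pd.DataFrame, int, int]:
    """Drop prevalent-AF and incomplete rows; returns (frame, n_prev, n_miss)."""
    df = cohort.phenotypes
    n0 = len(df)
    if "prevalent_af" in df.columns:
        df = df[df["prevalent_af"] != 1]
    n_prev = n0 - len(df)
    required = ["age", "sex", "heart_rate", "af_event"]
    if cohort.has_time_to_event:
        required.append("followup_time")
    df = df.dropna(subset=[c for c in required if c in df.columns])
    n_miss = n0 - n_prev - len(df)
    if n_prev or n_miss:
        logger.info(
            "cohort %s: excluded %d prevalent-AF and %d incomplete of %d",
            cohort.name, n_prev, n_miss, n0,
        )
    return df.reset_index(drop=True), n_prev, n_miss


def cohort_summary(cohort: CohortDataset) -> dict:
    """One descriptive row (post-exclusion) for a cohort."""
    df, _, _ = _apply_exclusions(cohort)
    return {
        "cohort": cohort.name,
        "n": len(df),
        "n_women": int((df["sex"] == "female").sum()),
        "mean_age": float(df["age"].mean()),
        "mean_heart_rate": float(df["heart_rate"].mean()),
        "n_events": int(df["af_event"].sum()),
        "mean_followup": (
            float(df["followup_time"].mean()) if cohort.has_time_to_event else np.nan
        ),
    }


def pooled_descriptives(cohorts) -> dict[str, float]:
    """Consortium-level descriptives: totals plus size-weighted means.

    Accepts either a list of :class:`CohortDataset` or a DataFrame of
    per-cohort rows (n, n_women, mean_age, mean_heart_rate, n_events,
    mean_followup). Follow-up is weighted only over cohorts that report
    it (binary-only cohorts contribute nothing to that mean).
    """
    if isinstance(cohorts, pd.DataFrame):
        rows = cohorts
    else:
        rows = pd.DataFrame([cohort_summary(c) for c in cohorts])
    n = rows["n"].to_numpy(dtype=float)
    total_n = float(n.sum())
    total_events = float(rows["n_events"].sum())
    has_fu = rows["mean_followup"].notna()
    fu_n = n[has_fu.to_numpy()]
    return {
        "total_n": total_n,
        "total_events": total_events,
        "pct_incident_af": 100.0 * total_events / total_n,
        "pct_women": 100.0 * float(rows["n_women"].sum()) / total_n,
        "mean_age": float(np.average(rows["mean_age"], weights=n)),
        "mean_heart_rate": float(np.average(rows["mean_heart_rate"], weights=n)),
        "mean_followup": (
            float(np.average(rows.loc[has_fu, "mean_followup"], weights=fu_n))
            if has_fu.any()
            else float("nan")
        ),
    }


def analyze_consortium(
    cohorts: list[CohortDataset],
    weights: list[VariantWeight],
    settings: PipelineSettings = PipelineSettings(),
) -> ResultBundle:
    """Run the complete stratified MR analysis in memory."""
    first_stage_covs = settings.covariates if settings.first_stage_adjusted else ()

    # Pass 1: PRS, exclusions, first stage, IV-free heart rate.
    prepared = []
    for cohort in cohorts:
        if cohort.prs is not None:
            prs = cohort.prs
        elif cohort.dosages is not None:
            prs = compute_prs(
                cohort.dosages,
                weights,
                missing_policy=settings.missing_policy,
                allow_ambiguous=settings.allow_ambiguous,
            )
        else:
            raise ConfigurationError(f"cohort {cohort.name}: neither dosages nor PRS")
        df, n_prev, n_miss = _apply_exclusions(cohort)
        analysed = CohortDataset(
            name=cohort.name,
            phenotypes=df,
            dosages=None,
            prs=prs,
            has_time_to_event=cohort.has_time_to_event,
        )
        if len(df) < settings.min_complete_cases:
            raise ConfigurationError(
                f"cohort {cohort.name}: only {len(df)} complete cases"
            )
        first = fit_prs_effect_on_hr(
            analysed, prs, covariates=first_stage_covs, min_n=settings.min_complete_cases
        )
        merged = df.merge(prs[["sample_id", "prs"]], on="sample_id", validate="one_to_one")
        ivfree = compute_iv_free_hr(
            merged["heart_rate"].to_numpy(), merged["prs"].to_numpy(), first.beta
        )
        prepared.append((cohort, analysed, prs, first, merged, ivfree, n_prev, n_miss))

    if settings.stratum_mode == "tertiles":
        pooled_ivfree = np.concatenate([p[5] for p in prepared])
        spec = StratumSpec.from_tertiles(pooled_ivfree)
    elif settings.stratum_mode == "fixed":
        spec = StratumSpec(cutpoints=settings.cutpoints)
    else:
        raise ConfigurationError(f"unknown stratum_mode {settings.stratum_mode!r}")

    # Pass 2: stratum assignment and all per-cohort models.
    analyses: list[CohortAnalysis] = []
    for cohort, analysed, prs, first, merged, ivfree, n_prev, n_miss in prepared:
        assignments = assign_strata(ivfree, spec, list(merged["sample_id"]))
        quad = fit_quadratic_hr_model(
            analysed, covariates=settings.covariates, hr_center=settings.hr_center
        )
        stages = fit_stage_regressions(
            analysed, prs, assignments, covariates=settings.covariates
        )
        analyses.append(
            CohortAnalysis(
                name=cohort.name,
                n_input=len(cohort.phenotypes),
                n_analyzed=len(merged),
                n_excluded_prevalent=n_prev,
                n_excluded_missing=n_miss,
                first_stage=first,
                prs=prs,
                assignments=assignments,
                quadratic=quad,
                stages=stages,
            )
        )

    # Pass 3: pooling.
    metas: dict[tuple[str, str, str], MetaEstimate] = {}
    for model in STAGE_MODELS:
        for stratum in spec.labels:
            ests = [
                e for ca in analyses for e in ca.stages
                if e.model == model and e.stratum == stratum
            ]
            if not ests:
                logger.warning("no estimates to pool for %s/%s", model, stratum)
                continue
            for method in ("fixed", "random_dl"):
                metas[(model, stratum, method)] = ivw_meta(ests, method=method)
    for model, pick in (("hr_linear", "linear"), ("hr_quadratic", "quadratic")):
        ests = [getattr(ca.quadratic, pick) for ca in analyses]
        for method in ("fixed", "random_dl"):
            metas[(model, "all", method)] = ivw_meta(ests, method=method)

    method = settings.meta_method
    ratios = [
        ratio_estimate(
            metas[("prs_on_hr", s, method)],
            metas[("prs_on_af", s, method)],
            weak_f_threshold=settings.weak_f_threshold,
            z=settings.ci_z,
            n_tests=settings.bonferroni_n,
        )
        for s in spec.labels
        if ("prs_on_hr", s, method) in metas and ("prs_on_af", s, method) in metas
    ]

    pleiotropy_p = [
        metas[("prs_on_af_adj_hr", s, method)].p
        for s in spec.labels
        if ("prs_on_af_adj_hr", s, method) in metas
    ]
    fisher_p = fisher_combine(pleiotropy_p)
    ushape = ushape_summary(
        metas[("hr_linear", "all", method)],
        metas[("hr_quadratic", "all", method)],
        center=settings.hr_center,
    )
    summaries = pd.DataFrame([cohort_summary(c) for c in cohorts])
    pooled = pooled_descriptives(summaries)
    return ResultBundle(
        cohorts=analyses,
        metas=metas,
        ratios=ratios,
        ushape=ushape,
        fisher_pleiotropy_p=fisher_p,
        pooled=pooled,
        cohort_summaries=summaries,
        stratum_spec=spec,
        settings=settings,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike | None = None) -> ResultBundle:
    """File-level run: read manifest inputs, analyze, write tables.

    Fails before any model fit if a referenced file is missing, naming
    the file.
    """
    paths = [os.path.join(config.base_dir, config.weights)]
    for c in config.cohorts:
        paths.append(os.path.join(config.base_dir, c["dosages"]))
        paths.append(os.path.join(config.base_dir, c["phenotypes"]))
    missing = [p for p in paths if not os.path.exists(p)]
    if missing:
        raise ConfigurationError(f"missing input file(s): {missing}")

    weights = read_variant_weights(os.path.join(config.base_dir, config.weights))
    cohorts = []
    for c in config.cohorts:
        try:
            panel = read_dosages(
                os.path.join(config.base_dir, c["dosages"]),
                dialect=c.get("dialect", "matrix"),
            )
            pheno = read_phenotypes(os.path.join(config.base_dir, c["phenotypes"]))
            cohorts.append(
                CohortDataset(
                    name=c["name"],
                    phenotypes=pheno,
                    dosages=panel,
                    has_time_to_event="followup_time" in pheno.columns,
                )
            )
        except StratMRError as exc:
            raise type(exc)(f"[stage: load, cohort: {c['name']}] {exc}") from exc

    results = analyze_consortium(cohorts, weights, settings=config.settings)
    if out_dir is not None:
        write_results_tables(results, out_dir)
    return results
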