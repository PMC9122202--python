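"""Synthetic multi-cohort consortium generator.

Emulates the statistical structure the stratified MR analysis assumes:
several cohorts of unequal size with cohort-specific mean resting heart
rate, a shared variant-weight table whose polygenic score explains a
small fraction of heart-rate variance, an unmeasured confounder acting
on both heart rate and AF hazard, a piecewise-linear causal log-hazard
in heart rate with knots at the stratum cutpoints, exponential event
times under uniform censoring, and one cohort reporting only a binary
outcome (no follow-up time).

The PRS is a valid instrument by construction: the causal channel into
the hazard is the *genetic-plus-noise* component of heart rate, while
the confounder's contribution to observed heart rate affects the hazard
only directly. Default parameter values mirror the consortium scale the
design targets (eight cohorts of 2,000-9,000, heart-rate means 63-73
bpm, SD 11, score r^2 0.02, causal slopes at the published per-stratum
point estimates).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (
    CohortDataset,
    DosagePanel,
    DosageRecord,
    VariantWeight,
    write_dosage_matrix,
    write_phenotypes,
    write_variant_weights,
)

_LN = math.log

#: Published per-stratum per-bpm log-hazard point estimates used as the
#: default causal function: ln(0.82)/5, ln(0.82)/5, ln(1.16)/5.
DEFAULT_SLOPES = (_LN(0.82) / 5.0, _LN(0.82) / 5.0, _LN(1.16) / 5.0)

_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the study-scale conditions."""

    n_cohorts: int = 8
    cohort_sizes: tuple[int, ...] = (9000, 7800, 2500, 3500, 5200, 5000, 2000, 3900)
    n_variants: int = 50
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    weight_scale: float = 0.25  # bpm per allele scale of the raw weights
    prs_r2: float = 0.02  # target fraction of HR variance from the PRS
    hr_means: tuple[float, ...] = (67, 64, 63, 69, 66, 71, 69, 73)
    hr_sd: float = 11.0
    age_means: tuple[float, ...] = (54, 53, 63, 49, 75, 68, 65, 49)
    age_sd: float = 10.0
    confounder_effect_hr: float = 3.0  # bpm per unit U
    confounder_effect_af: float = 0.3  # log hazard per unit U
    slope_low: float = DEFAULT_SLOPES[0]  # per-bpm log hazard below 65
    slope_mid: float = DEFAULT_SLOPES[1]  # per-bpm log hazard in [65, 75)
    slope_high: float = DEFAULT_SLOPES[2]  # per-bpm log hazard at/above 75
    knots: tuple[float, float] = (65.0, 75.0)
    age_effect_af: float = 0.05  # log hazard per year (centred at 60)
    sex_effect_af: float = 0.4  # log hazard, male vs female
    baseline_hazard: float = 0.01  # events per year at the reference
    max_followup: float = 20.0  # years; censoring ~ Uniform(0, max)
    binary_only_cohort_index: int | None = 7  # emits af_event only
    missing_dose_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.cohort_sizes):
            raise ConfigurationError("cohort sizes must be positive")
        if not (0.0 <= self.prs_r2 < 0.5):
            raise ConfigurationError("prs_r2 must be in [0, 0.5)")
        lo, hi = self.allele_freq_range
        if not (0.05 < lo < hi < 0.95):
            raise ConfigurationError("allele frequencies must stay inside (0.05, 0.95)")
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ConfigurationError("cohort_sizes length must equal n_cohorts")
        if len(self.hr_means) != self.n_cohorts or len(self.age_means) != self.n_cohorts:
            raise ConfigurationError("hr_means/age_means length must equal n_cohorts")
        if self.binary_only_cohort_index is not None and not (
            0 <= self.binary_only_cohort_index < self.n_cohorts
        ):
            raise ConfigurationError("binary_only_cohort_index out of range")


@dataclass
class SimulationTruth:
    """Exact generator parameters, for recovery tests."""

    weights: list[VariantWeight]
    allele_freqs: np.ndarray
    gamma: float  # bpm of heart rate per unit PRS
    slopes: dict[str, float]  # true per-bpm causal log-hazard per stratum
    prs_sd: float  # theoretical SD of the raw PRS
    config: SimulationConfig


def causal_log_hazard(hr: np.ndarray, slopes: tuple[float, float, float],
                      knots: tuple[float, float] = (65.0, 75.0)) -> np.ndarray:
    """Integrated piecewise-linear causal function, anchored F(knot1)=0.

    The derivative is slope_low below the first knot, slope_mid between
    the knots, slope_high above the second; continuity is enforced at
    the knots so per-stratum slopes are the recovery targets.
    """
    hr = np.asarray(hr, dtype=float)
    k1, k2 = knots
    s_low, s_mid, s_high = slopes
    return np.where(
        hr < k1,
        s_low * (hr - k1),
        np.where(hr < k2, s_mid * (hr - k1), s_mid * (k2 - k1) + s_high * (hr - k2)),
    )


def _draw_shared_variants(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[VariantWeight], np.ndarray]:
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, config.n_variants)
    raw = rng.normal(0.0, 1.0, config.n_variants)
    pairs = [
        _ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), config.n_variants)
    ]
    weights = [
        VariantWeight(
            rsid=f"rs{100000 + i}",
            effect_allele=pairs[i][0],
            other_allele=pairs[i][1],
            weight=float(raw[i] * config.weight_scale),
        )
        for i in range(config.n_variants)
    ]
    return weights, freqs


def _theoretical_prs_moments(
    weights: list[VariantWeight], freqs: np.ndarray
) -> tuple[float, float]:
    w = np.array([vw.weight for vw in weights])
    mean = float(np.sum(w * 2.0 * freqs))
    var = float(np.sum(w**2 * 2.0 * freqs * (1.0 - freqs)))
    return mean, var


def generate_consortium(
    config: SimulationConfig,
) -> tuple[list[CohortDataset], SimulationTruth]:
    """Generate the full synthetic consortium.

    Returns the cohorts (each with a dosage panel and validated
    phenotypes) and the exact truth record. A single global seed fans
    out to one substream for the shared variants plus one per cohort,
    so adding a cohort never perturbs existing cohorts.
    """
    root = np.random.SeedSequence(config.seed)
    shared_ss, *cohort_ss = root.spawn(1 + config.n_cohorts)
    shared_rng = np.random.default_rng(shared_ss)
    weights, freqs = _draw_shared_variants(config, shared_rng)

    prs_mean, prs_var = _theoretical_prs_moments(weights, freqs)
    if config.prs_r2 > 0 and prs_var <= 0:
        raise ConfigurationError(
            "prs_r2 > 0 infeasible: PRS has zero variance (weight_scale 0?)"
        )
    gamma = (
        math.sqrt(config.prs_r2) * config.hr_sd / math.sqrt(prs_var)
        if prs_var > 0
        else 0.0
    )
    resid_var = config.hr_sd**2 * (1.0 - config.prs_r2) - config.confounder_effect_hr**2
    if resid_var <= 0:
        raise ConfigurationError(
            "confounder_effect_hr too large for hr_sd and prs_r2 "
            "(negative residual variance)"
        )

    slopes = (config.slope_low, config.slope_mid, config.slope_high)
    cohorts: list[CohortDataset] = []
    for i, ss in enumerate(cohort_ss):
        rng = np.random.default_rng(ss)
        n = config.cohort_sizes[i]
        name = f"cohort_{i + 1:02d}"
        sample_ids = [f"{name}_s{j:05d}" for j in range(n)]

        dose_matrix = rng.binomial(2, freqs[:, None], size=(config.n_variants, n)).astype(float)
        prs = np.array([vw.weight for vw in weights]) @ dose_matrix

        age = np.clip(rng.normal(config.age_means[i], config.age_sd, n), 30.0, 90.0)
        male = rng.integers(0, 2, n)
        u = rng.normal(0.0, 1.0, n)
        genetic = gamma * (prs - prs_mean)
        noise = rng.normal(0.0, math.sqrt(resid_var), n)
        hr_causal = config.hr_means[i] + genetic + noise
        heart_rate = np.maximum(hr_causal + config.confounder_effect_hr * u, 30.0)

        log_hazard = (
            math.log(config.baseline_hazard)
            + causal_log_hazard(hr_causal, slopes, config.knots)
            + config.confounder_effect_af * u
            + config.age_effect_af * (age - 60.0)
            + config.sex_effect_af * male
        )
        event_time = rng.exponential(1.0 / np.exp(log_hazard))
        censor_time = rng.uniform(0.0, config.max_followup, n)
        af_event = (event_time <= censor_time).astype(int)
        followup = np.minimum(event_time, censor_time)
        followup = np.maximum(followup, 1e-4)  # guard the strictly-positive contract

        # About half of the variants are stored as doses of the *other*
        # allele, so allele alignment is exercised on every run.
        flip = rng.integers(0, 2, config.n_variants).astype(bool)
        records = []
        for v, vw in enumerate(weights):
            doses = dose_matrix[v]
            counted = vw.effect_allele
            if flip[v]:
                doses = 2.0 - doses
                counted = vw.other_allele
            if config.missing_dose_rate > 0:
                mask = rng.random(n) < config.missing_dose_rate
                doses = np.where(mask, np.nan, doses)
            records.append(DosageRecord(rsid=vw.rsid, counted_allele=counted, doses=doses))
        panel = DosagePanel(sample_ids=sample_ids, records=records)

        binary_only = i == config.binary_only_cohort_index
        pheno = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age": age,
                "sex": np.where(male == 1, "male", "female"),
                "heart_rate": heart_rate,
                "af_event": af_event,
                "prevalent_af": 0,
            }
        )
        if not binary_only:
            pheno.insert(5, "followup_time", followup)
        cohorts.append(
            CohortDataset(
                name=name,
                phenotypes=pheno,
                dosages=panel,
                has_time_to_event=not binary_only,
            )
        )

    truth = SimulationTruth(
        weights=weights,
        allele_freqs=freqs,
        gamma=gamma,
        slopes={"low": slopes[0], "mid": slopes[1], "high": slopes[2]},
        prs_sd=math.sqrt(prs_var),
        config=config,
    )
    return cohorts, truth


def empirical_prs_r2(cohort: CohortDataset, prs: pd.DataFrame) -> float:
    """Squared correlation between the PRS and observed heart rate."""
    merged = cohort.phenotypes.merge(prs[["sample_id", "prs"]], on="sample_id")
    r = np.corrcoef(merged["prs"], merged["heart_rate"])[0, 1]
    return float(r**2)


def write_consortium(
    cohorts: list[CohortDataset],
    truth: SimulationTruth,
    out_dir: str | os.PathLike,
) -> str:
    """Write the file set a pipeline run consumes; returns the manifest path.

    Layout: ``weights.tsv``, per-cohort ``<name>_dosages.tsv`` and
    ``<name>_phenotypes.tsv``, ``truth.json``, and ``manifest.yaml``.
    """
    import yaml

    os.makedirs(out_dir, exist_ok=True)
    write_variant_weights(truth.weights, os.path.join(out_dir, "weights.tsv"))
    manifest: dict = {"weights": "weights.tsv", "cohorts": []}
    for cohort in cohorts:
        dpath = f"{cohort.name}_dosages.tsv"
        ppath = f"{cohort.name}_phenotypes.tsv"
        write_dosage_matrix(cohort.dosages, os.path.join(out_dir, dpath))
        write_phenotypes(cohort.phenotypes, os.path.join(out_dir, ppath))
        manifest["cohorts"].append(
            {"name": cohort.name, "dosages": dpath, "dialect": "matrix", "phenotypes": ppath}
        )
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(
            {
                "gamma": truth.gamma,
                "slopes": truth.slopes,
                "prs_sd": truth.prs_sd,
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(truth.config).items()
                },
            },
            fh,
            indent=2,
        )
    manifest_path = os.path.join(out_dir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
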