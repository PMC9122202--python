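"""Instrumental-variable-free heart rate and stratum assignment.

Stratifying a Mendelian randomization analysis on the raw exposure would
condition on a collider (the exposure is a common child of the
instrument and of confounders), biasing within-stratum PRS–outcome
associations. Instead each participant's heart rate is stripped of the
fitted PRS contribution — the "IV-free" heart rate — and strata are cut
on that quantity:

    ivfree_hr = heart_rate - slope * (prs - mean(prs))

where ``slope`` is the cohort's own fitted PRS-on-heart-rate
coefficient. Centring the PRS keeps the cohort mean heart rate
unchanged, so the bpm cutpoints (default 65 and 75) stay on the
observed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_models import (
    StageEstimate,
    build_covariate_frame,
    fit_linear,
    DEFAULT_COVARIATES,
)
from .errors import AlignmentError, ValidationError
from .io_formats import CohortDataset


@dataclass(frozen=True)
class StratumSpec:
    """Two bpm cutpoints defining three heart-rate strata."""

    cutpoints: tuple[float, float] = (65.0, 75.0)
    labels: tuple[str, str, str] = ("low", "mid", "high")

    def __post_init__(self) -> None:
        if len(self.cutpoints) != 2:
            raise ValidationError("exactly two cutpoints required")
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise ValidationError("cutpoints must be strictly increasing")

    @classmethod
    def from_tertiles(cls, ivfree_hr: np.ndarray) -> "StratumSpec":
        """Cutpoints at the empirical tertiles of the IV-free heart rate
        (pooled), for the equal-thirds variant of the design."""
        lo, hi = np.quantile(np.asarray(ivfree_hr, dtype=float), [1 / 3, 2 / 3])
        return cls(cutpoints=(float(lo), float(hi)))


def fit_prs_effect_on_hr(
    cohort: CohortDataset,
    prs: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_n: int = 10,
) -> StageEstimate:
    """First-stage regression: heart rate on the PRS (plus covariates),
    on the full cohort; the slope defines the IV-free heart rate."""
    df = cohort.phenotypes.merge(
        prs[["sample_id", "prs"]], on="sample_id", validate="one_to_one"
    )
    if len(df) < min_n:
        raise ValidationError(
            f"cohort {cohort.name}: {len(df)} complete cases < floor {min_n}"
        )
    design = build_covariate_frame(df, covariates)
    design.insert(0, "prs", df["prs"].to_numpy(dtype=float))
    return fit_linear(
        design,
        df["heart_rate"].to_numpy(dtype=float),
        "prs",
        cohort=cohort.name,
        stratum="all",
        model="prs_on_hr",
    )


def compute_iv_free_hr(
    heart_rate: np.ndarray, prs: np.ndarray, slope: float
) -> np.ndarray:
    """Heart rate with the centred PRS effect removed; preserves the
    cohort mean heart rate."""
    heart_rate = np.asarray(heart_rate, dtype=float)
    prs = np.asarray(prs, dtype=float)
    if heart_rate.shape != prs.shape:
        raise AlignmentError(
            f"heart_rate length {heart_rate.shape} != prs length {prs.shape}"
        )
    return heart_rate - slope * (prs - prs.mean())


def assign_strata(
    ivfree_hr: np.ndarray,
    spec: StratumSpec = StratumSpec(),
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each participant to a stratum by IV-free heart rate.

    Intervals are half-open on the right: low < c1 <= mid < c2 <= high,
    so a value exactly at a cutpoint belongs to the upper stratum.
    Returns a DataFrame (sample_id, ivfree_hr, stratum).
    """
    ivfree_hr = np.asarray(ivfree_hr, dtype=float)
    if not np.all(np.isfinite(ivfree_hr)):
        raise ValidationError("non-finite IV-free heart rate value(s)")
    c1, c2 = spec.cutpoints
    labels = np.where(
        ivfree_hr < c1,
        spec.labels[0],
        np.where(ivfree_hr < c2, spec.labels[1], spec.labels[2]),
    )
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(ivfree_hr))]
    return pd.DataFrame(
        {"sample_id": sample_ids, "ivfree_hr": ivfree_hr, "stratum": labels}
    )
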