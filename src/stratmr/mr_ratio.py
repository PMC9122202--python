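"""Per-stratum causal inference: the ratio (Wald) estimator.

Within each heart-rate stratum the causal log-hazard per bpm is
estimated as

    beta3 = beta2 / beta1

where beta1 is the pooled PRS-on-heart-rate slope (bpm per score unit)
and beta2 the pooled PRS-on-AF slope (log hazard per score unit). The
standard error comes from the first-order Taylor (delta-method)
expansion of the ratio, assuming independence of the two stage
estimates:

    se3^2 = se2^2 / beta1^2 + beta2^2 * se1^2 / beta1^4

Hazard ratios are reported per 1 bpm and per 5 bpm (exp(5*beta3)), and
significance is declared at the Bonferroni threshold for three strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort_models import wald_p
from .errors import ValidationError, WeakInstrumentError
from .meta_analysis import MetaEstimate

#: Printed Bonferroni threshold for three strata (0.05/3 to 3 d.p.).
BONFERRONI_3 = 0.017


@dataclass
class RatioEstimate:
    """Causal effect of resting heart rate on incident AF in one stratum."""

    stratum: str
    beta3: float  # log hazard per bpm
    se3: float
    p: float
    hr_per_bpm: float
    hr_per_5bpm: float
    ci_low_5bpm: float
    ci_high_5bpm: float
    significant: bool
    weak_instrument: bool = False
    first_stage_f: float = float("inf")

    def __post_init__(self) -> None:
        if self.se3 < 0:
            raise ValidationError("negative se3")


def bonferroni_decision(p: float, n_tests: int = 3, threshold: float | None = None) -> bool:
    """Strict comparison against the Bonferroni threshold.

    For three tests the printed convention 0.017 (0.05/3 rounded to
    3 d.p.) is used; otherwise 0.05/n_tests. A p exactly at the
    threshold is not significant.
    """
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if threshold is None:
        threshold = BONFERRONI_3 if n_tests == 3 else 0.05 / n_tests
    return p < threshold


def ratio_estimate(
    stage1: MetaEstimate,
    stage2: MetaEstimate,
    weak_f_threshold: float = 10.0,
    z: float = 1.96,
    n_tests: int = 3,
) -> RatioEstimate:
    """Combine the two pooled stage estimates into a causal estimate.

    ``stage1`` must be the prs_on_hr coefficient and ``stage2`` the
    prs_on_af coefficient of the same stratum. A zero first stage is an
    error; a first-stage F statistic (beta1/se1)^2 below
    ``weak_f_threshold`` attaches a weak-instrument flag rather than
    failing.
    """
    if stage1.model != "prs_on_hr" or stage2.model != "prs_on_af":
        raise ValidationError(
            f"expected (prs_on_hr, prs_on_af), got ({stage1.model}, {stage2.model})"
        )
    if stage1.stratum != stage2.stratum:
        raise ValidationError(
            f"stage strata differ: {stage1.stratum} vs {stage2.stratum}"
        )
    b1, se1 = stage1.beta, stage1.se
    b2, se2 = stage2.beta, stage2.se
    if b1 == 0:
        raise WeakInstrumentError(
            f"stratum {stage1.stratum}: first-stage coefficient is zero"
        )
    f_stat = (b1 / se1) ** 2 if se1 > 0 else float("inf")
    beta3 = b2 / b1
    se3 = math.sqrt(se2**2 / b1**2 + b2**2 * se1**2 / b1**4)
    p = wald_p(beta3, se3)
    return RatioEstimate(
        stratum=stage1.stratum,
        beta3=beta3,
        se3=se3,
        p=p,
        hr_per_bpm=math.exp(beta3),
        hr_per_5bpm=math.exp(5.0 * beta3),
        ci_low_5bpm=math.exp(5.0 * (beta3 - z * se3)),
        ci_high_5bpm=math.exp(5.0 * (beta3 + z * se3)),
        significant=bonferroni_decision(p, n_tests=n_tests),
        weak_instrument=f_stat < weak_f_threshold,
        first_stage_f=f_stat,
    )


def hr_per_k_bpm(estimate: RatioEstimate, k: float, z: float = 1.96) -> tuple[float, float, float]:
    """Hazard ratio (with 95% CI) per ``k`` bpm increase in heart rate."""
    if k <= 0:
        raise ValidationError("k must be > 0")
    return (
        math.exp(k * estimate.beta3),
        math.exp(k * (estimate.beta3 - z * estimate.se3)),
        math.exp(k * (estimate.beta3 + z * estimate.se3)),
    )


@dataclass
class UShapeSummary:
    """Pooled observational dose-response summary.

    ``beta_lin`` and ``beta_quad`` parameterise the log hazard as
    ``beta_lin*(hr - center) + beta_quad*(hr - center)^2``; for a convex
    curve (beta_quad > 0) the nadir sits at ``center - beta_lin /
    (2*beta_quad)`` bpm.
    """

    beta_lin: float
    beta_quad: float
    p_quad: float
    nadir_bpm: float | None
    center: float = 0.0


def ushape_summary(
    lin: MetaEstimate, quad: MetaEstimate, center: float = 0.0
) -> UShapeSummary:
    """Summarise the pooled quadratic model; nadir only when convex."""
    nadir = None
    if quad.beta > 0:
        nadir = center - lin.beta / (2.0 * quad.beta)
    return UShapeSummary(
        beta_lin=lin.beta,
        beta_quad=quad.beta,
        p_quad=quad.p,
        nadir_bpm=nadir,
        center=center,
    )
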