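"""Inverse-variance meta-analysis and Fisher p-value combination.

Fixed-effect pooling weights each cohort estimate by 1/se^2; the
DerSimonian–Laird random-effects variant adds the moment estimate of
the between-cohort variance tau^2. Cochran's Q and I^2 are reported in
either case. Log-odds estimates (from binary-only cohorts) are pooled
alongside log-hazard estimates without conversion, treating the odds
ratio as an approximation of the hazard ratio for a rare-ish outcome;
a warning is logged when scales are mixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_models import StageEstimate, wald_p
from .errors import ContractError, EmptyMetaError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MetaEstimate:
    """Pooled coefficient with heterogeneity statistics."""

    model: str
    stratum: str
    beta: float
    se: float
    p: float
    k: int
    Q: float
    i2: float  # percent, in [0, 100]
    tau2: float
    method: str  # fixed | random_dl

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("negative pooled se")


def ivw_meta(estimates: list[StageEstimate], method: str = "fixed") -> MetaEstimate:
    """Pool per-cohort estimates of one (model, stratum) coefficient.

    ``method="fixed"``: beta = sum(w_i b_i)/sum(w_i), w_i = 1/se_i^2,
    se = sum(w_i)^(-1/2). ``method="random_dl"``: DerSimonian–Laird,
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with the
    fixed-effect weights, then re-weighting by 1/(se_i^2 + tau2).
    With a single estimate the input is returned unchanged (Q=0, I2=0).
    """
    if method not in ("fixed", "random_dl"):
        raise ValueError(f"unknown meta method {method!r}")
    if len(estimates) == 0:
        raise EmptyMetaError("no estimates to pool")
    models = {e.model for e in estimates}
    strata = {e.stratum for e in estimates}
    if len(models) > 1 or len(strata) > 1:
        raise ContractError(
            f"mixed estimates in meta-analysis: models {models}, strata {strata}"
        )
    scales = {e.outcome_scale for e in estimates}
    if len(scales) > 1:
        logger.warning(
            "pooling mixed outcome scales %s for %s/%s (odds ratio treated as "
            "approximation of hazard ratio)",
            scales,
            estimates[0].model,
            estimates[0].stratum,
        )
    b = np.array([e.beta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValidationError("all standard errors must be > 0 for IVW pooling")
    k = len(b)
    w = 1.0 / se**2
    beta_fixed = float(np.sum(w * b) / np.sum(w))
    if k == 1:
        return MetaEstimate(
            model=estimates[0].model,
            stratum=estimates[0].stratum,
            beta=float(b[0]),
            se=float(se[0]),
            p=wald_p(float(b[0]), float(se[0])),
            k=1,
            Q=0.0,
            i2=0.0,
            tau2=0.0,
            method=method,
        )
    Q = float(np.sum(w * (b - beta_fixed) ** 2))
    i2 = float(max(0.0, (Q - (k - 1)) / Q) * 100.0) if Q > 0 else 0.0
    if method == "fixed":
        beta, pooled_se, tau2 = beta_fixed, float(np.sum(w) ** -0.5), 0.0
    else:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
        beta = float(np.sum(w_star * b) / np.sum(w_star))
        pooled_se = float(np.sum(w_star) ** -0.5)
    return MetaEstimate(
        model=estimates[0].model,
        stratum=estimates[0].stratum,
        beta=beta,
        se=pooled_se,
        p=wald_p(beta, pooled_se),
        k=k,
        Q=Q,
        i2=i2,
        tau2=tau2,
        method=method,
    )


def fisher_combine(pvalues: list[float]) -> float:
    """Combine independent p-values by Fisher's method.

    ``X = -2 * sum(ln p_i)`` is referred to a chi-square distribution
    with 2k degrees of freedom; returns the upper-tail probability.
    """
    if len(pvalues) == 0:
        raise EmptyMetaError("no p-values to combine")
    for p in pvalues:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    X = -2.0 * float(np.sum(np.log(pvalues)))
    return float(stats.chi2.sf(X, 2 * len(pvalues)))
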