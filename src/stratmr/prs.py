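"""Weighted resting-heart-rate polygenic risk score.

The score for sample *s* is the sum over variants of the dose of the
effect allele times the per-allele effect size (bpm per allele):
``prs_s = sum_i d_si * w_i``. The score is deliberately left on this
natural bpm-weighted scale — no standardisation — so the first-stage
slope (PRS on heart rate) is interpretable and the MR ratio comes out
per bpm of heart rate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .errors import AlleleMismatchError, EmptyInstrumentError, ValidationError
from .io_formats import DosagePanel, DosageRecord, VariantWeight

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(allele_a: str, allele_b: str) -> bool:
    """True for A/T and C/G variant pairs, which cannot be resolved
    across strand flips without frequency information."""
    return _COMPLEMENT.get(allele_a.upper()) == allele_b.upper()


def align_alleles(
    record: DosageRecord,
    weight: VariantWeight,
    allow_ambiguous: bool = False,
) -> DosageRecord | None:
    """Express a dosage record as doses of the weight's effect allele.

    If the counted allele already is the effect allele the record is
    returned unchanged; if it is the other allele, doses become
    ``2 - dose``. Strand-ambiguous variants (A/T, C/G) are excluded
    (``None``) unless ``allow_ambiguous``. A counted allele matching
    neither weight allele raises :class:`AlleleMismatchError`.
    """
    if record.rsid != weight.rsid:
        raise ValidationError(
            f"rsid mismatch: dosage {record.rsid} vs weight {weight.rsid}"
        )
    if is_strand_ambiguous(weight.effect_allele, weight.other_allele) and not allow_ambiguous:
        return None
    counted = record.counted_allele.upper()
    if counted == weight.effect_allele.upper():
        return record
    if counted == weight.other_allele.upper():
        return DosageRecord(
            rsid=record.rsid,
            counted_allele=weight.effect_allele,
            doses=2.0 - record.doses,
        )
    raise AlleleMismatchError(
        f"{record.rsid}: counted allele {record.counted_allele!r} matches "
        f"neither {weight.effect_allele!r} nor {weight.other_allele!r}"
    )


def compute_prs(
    dosages: DosagePanel,
    weights: list[VariantWeight],
    missing_policy: str = "mean_dose",
    allow_ambiguous: bool = False,
) -> pd.DataFrame:
    """Compute the weighted PRS for every sample in a panel.

    Parameters
    ----------
    missing_policy:
        ``"mean_dose"`` (default) imputes a missing dose with the cohort
        mean dose of that variant; ``"drop_variant"`` excludes any
        variant with at least one missing dose from every sample's score.

    Returns a DataFrame with columns ``sample_id``, ``prs``,
    ``n_variants_used`` (panel order preserved).
    """
    if missing_policy not in ("mean_dose", "drop_variant"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    by_rsid = {w.rsid: w for w in weights}
    n = dosages.n_samples
    total = np.zeros(n)
    used = 0
    n_ambiguous = 0
    for rec in dosages.records:
        w = by_rsid.get(rec.rsid)
        if w is None:
            continue
        aligned = align_alleles(rec, w, allow_ambiguous=allow_ambiguous)
        if aligned is None:
            n_ambiguous += 1
            continue
        doses = aligned.doses
        if np.isnan(doses).any():
            if missing_policy == "drop_variant":
                continue
            mean = np.nanmean(doses) if not np.isnan(doses).all() else None
            if mean is None:
                continue  # wholly missing variant carries no information
            doses = np.where(np.isnan(doses), mean, doses)
        total = total + doses * w.weight
        used += 1
    if used == 0:
        raise EmptyInstrumentError(
            "no usable variant overlap between dosage panel and weight table "
            f"({n_ambiguous} excluded as strand-ambiguous)"
        )
    if n_ambiguous:
        logger.info("excluded %d strand-ambiguous variant(s) from PRS", n_ambiguous)
    return pd.DataFrame(
        {
            "sample_id": dosages.sample_ids,
            "prs": total,
            "n_variants_used": used,
        }
    )
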