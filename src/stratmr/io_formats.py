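"""Readers and writers for the pipeline's file formats.

All formats are tab-separated text. Dosages additionally accept a VCF
dialect (per-genotype ``DS`` field, read through :mod:`cyvcf2`). Every
downstream module consumes only the in-memory types defined here:
:class:`VariantWeight`, :class:`DosageRecord` / :class:`DosagePanel`,
a validated phenotype :class:`pandas.DataFrame`, and
:class:`CohortDataset`.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ParseError,
    SchemaError,
    ValidationError,
)

_VALID_SEX = {"male", "female"}

#: Columns a phenotype table must provide.
REQUIRED_PHENOTYPE_COLUMNS = ("sample_id", "age", "sex", "heart_rate", "af_event")


@dataclass(frozen=True)
class VariantWeight:
    """One score variant: effect allele and its per-allele effect on
    resting heart rate (bpm per effect allele)."""

    rsid: str
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.rsid}: effect allele equals other allele "
                f"({self.effect_allele!r})"
            )
        if not math.isfinite(self.weight):
            raise ValidationError(f"{self.rsid}: non-finite weight {self.weight!r}")


@dataclass
class DosageRecord:
    """Per-sample dose of one counted allele, in [0, 2]; NaN = missing."""

    rsid: str
    counted_allele: str
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        bad = (self.doses < 0) | (self.doses > 2)
        if bool(np.any(bad & ~np.isnan(self.doses))):
            idx = int(np.where(bad & ~np.isnan(self.doses))[0][0])
            raise ValidationError(
                f"{self.rsid}: dose {self.doses[idx]} for sample index {idx} "
                "outside [0, 2]"
            )


@dataclass
class DosagePanel:
    """A cohort's dosage records with the (shared) sample ordering."""

    sample_ids: list[str]
    records: list[DosageRecord]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in dosage panel")
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValidationError(f"duplicate rsid {rec.rsid} in dosage panel")
            seen.add(rec.rsid)
            if len(rec.doses) != n:
                raise AlignmentError(
                    f"{rec.rsid}: {len(rec.doses)} doses for {n} samples"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.records)


@dataclass
class CohortDataset:
    """One cohort: validated phenotypes plus dosages and/or a PRS.

    ``has_time_to_event`` is False for cohorts that report only a binary
    incident-AF indicator (no follow-up time); those are analysed with
    logistic instead of Cox regression downstream.
    """

    name: str
    phenotypes: pd.DataFrame
    dosages: DosagePanel | None = None
    prs: pd.DataFrame | None = None
    has_time_to_event: bool = True

    def __post_init__(self) -> None:
        if self.has_time_to_event and "followup_time" not in self.phenotypes:
            raise SchemaError(
                f"cohort {self.name}: has_time_to_event is True but phenotypes "
                "lack a followup_time column"
            )
        if self.dosages is not None:
            pheno_ids = list(self.phenotypes["sample_id"])
            if pheno_ids != list(self.dosages.sample_ids):
                raise AlignmentError(
                    f"cohort {self.name}: phenotype and dosage sample ids differ"
                )

    @property
    def n_samples(self) -> int:
        return len(self.phenotypes)


def read_variant_weights(path: str | os.PathLike) -> list[VariantWeight]:
    """Read a TSV weight table (rsid, effect_allele, other_allele, weight).

    Raises :class:`ParseError` naming the line for malformed rows and
    :class:`ValidationError` for duplicate rsids or invalid alleles.
    """
    weights: list[VariantWeight] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["rsid", "effect_allele", "other_allele", "weight"]
        if header != expected:
            raise SchemaError(
                f"{path}: header {header} != expected {expected}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            rsid, ea, oa, w = parts
            try:
                weight = float(w)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {w!r}") from exc
            if rsid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate rsid {rsid}")
            seen.add(rsid)
            weights.append(VariantWeight(rsid, ea, oa, weight))
    return weights


def write_variant_weights(weights: Iterable[VariantWeight], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\teffect_allele\tother_allele\tweight\n")
        for w in weights:
            fh.write(f"{w.rsid}\t{w.effect_allele}\t{w.other_allele}\t{w.weight!r}\n")


def _read_dosage_matrix(path: str | os.PathLike) -> DosagePanel:
    # Layout: rows = variants, columns = samples; first two columns are
    # rsid and counted_allele; missing doses are the literal string "NA".
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:2] != ["rsid", "counted_allele"]:
        raise SchemaError(f"{path}: first columns must be rsid, counted_allele")
    sample_ids = header[2:]
    records: list[DosageRecord] = []
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            doses = np.array(
                [np.nan if v == "NA" else _parse_dose(v, path, lineno) for v in parts[2:]]
            )
            try:
                records.append(DosageRecord(parts[0], parts[1], doses))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return DosagePanel(sample_ids=sample_ids, records=records)


def _parse_dose(value: str, path, lineno: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad dose {value!r}") from exc


def _read_dosage_vcf(path: str | os.PathLike) -> DosagePanel:
    # Per-genotype dosage in the FORMAT/DS field; falls back on nothing:
    # a record without DS is an error, not a silent skip.
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records: list[DosageRecord] = []
    for var in vcf:
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        ds = var.format("DS")
        if ds is None:
            raise ParseError(f"{path}: variant {rsid} has no DS dosage field")
        doses = np.asarray(ds, dtype=float).reshape(-1)
        doses = np.where(doses < 0, np.nan, doses)  # cyvcf2 encodes missing as negative
        records.append(DosageRecord(rsid, var.ALT[0], doses))
    vcf.close()
    return DosagePanel(sample_ids=sample_ids, records=records)


def read_dosages(path: str | os.PathLike, dialect: str = "matrix") -> DosagePanel:
    """Read an allele-dosage panel.

    Parameters
    ----------
    dialect:
        ``"matrix"`` — TSV with variants as rows and samples as columns;
        ``"vcf"`` — VCF with a per-genotype ``DS`` field (the counted
        allele is the ALT allele).
    """
    if dialect == "matrix":
        return _read_dosage_matrix(path)
    if dialect == "vcf":
        return _read_dosage_vcf(path)
    raise ValueError(f"unknown dosage dialect {dialect!r}")


def write_dosage_matrix(panel: DosagePanel, path: str | os.PathLike) -> None:
    """Write a panel in the matrix dialect (missing doses as ``NA``)."""
    with open(path, "w") as fh:
        fh.write("rsid\tcounted_allele\t" + "\t".join(panel.sample_ids) + "\n")
        for rec in panel.records:
            vals = "\t".join(
                "NA" if np.isnan(d) else repr(float(d)) for d in rec.doses
            )
            fh.write(f"{rec.rsid}\t{rec.counted_allele}\t{vals}\n")


def validate_phenotypes(df: pd.DataFrame, source: str = "<phenotypes>") -> pd.DataFrame:
    """Validate a phenotype table against the schema; returns the frame."""
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{source}: duplicate sample ids")
    bad_sex = set(df["sex"].unique()) - _VALID_SEX
    if bad_sex:
        raise ValidationError(f"{source}: invalid sex value(s) {sorted(bad_sex)}")
    if (df["heart_rate"] <= 0).any():
        raise ValidationError(f"{source}: heart_rate must be > 0")
    if not df["af_event"].isin([0, 1]).all():
        raise ValidationError(f"{source}: af_event must be 0/1")
    if "followup_time" in df.columns:
        t = df["followup_time"].dropna()
        if (t <= 0).any():
            raise ValidationError(f"{source}: followup_time must be > 0 where present")
    if "prevalent_af" in df.columns:
        if not df["prevalent_af"].isin([0, 1]).all():
            raise ValidationError(f"{source}: prevalent_af must be 0/1")
    return df


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a phenotype TSV.

    Required columns: sample_id, age, sex, heart_rate, af_event.
    Optional: followup_time (absent for binary-only cohorts), pc1..pcK,
    center, prevalent_af.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_phenotypes(df, source=str(path))


def write_phenotypes(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def pc_columns(df: pd.DataFrame) -> list[str]:
    """Names of genetic principal-component covariate columns (pc1, pc2, ...)."""
    return [c for c in df.columns if c.startswith("pc") and c[2:].isdigit()]


def write_results_tables(results, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write the result bundle as TSV tables; returns {table: path}.

    Tables: the per-stratum causal table (Table-2 analogue), the
    per-cohort stage estimates (forest-plot data), meta-analysis rows
    with heterogeneity statistics, pooled descriptives, and a run
    summary (U-shape + pleiotropy).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    causal = results.causal_table()
    paths["causal"] = os.path.join(out_dir, "causal_estimates.tsv")
    causal.to_csv(paths["causal"], sep="\t", index=False)

    stages = results.stage_table()
    paths["stages"] = os.path.join(out_dir, "stage_estimates.tsv")
    stages.to_csv(paths["stages"], sep="\t", index=False)

    meta = results.meta_table()
    paths["meta"] = os.path.join(out_dir, "meta_estimates.tsv")
    meta.to_csv(paths["meta"], sep="\t", index=False)

    desc = results.descriptives_table()
    paths["descriptives"] = os.path.join(out_dir, "pooled_descriptives.tsv")
    desc.to_csv(paths["descriptives"], sep="\t", index=False)

    summary = results.summary_table()
    paths["summary"] = os.path.join(out_dir, "run_summary.tsv")
    summary.to_csv(paths["summary"], sep="\t", index=False)

    excl = results.exclusions_table()
    paths["exclusions"] = os.path.join(out_dir, "exclusions.tsv")
    excl.to_csv(paths["exclusions"], sep="\t", index=False)
    return paths
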