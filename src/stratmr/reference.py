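"""Published AFGen consortium summary numbers used as worked-example inputs.

These are transcribed aggregate characteristics of the seven AFGen
cohorts (ARIC, FHS, MESA, PREVEND, PROSPER, Rotterdam Study I and II,
SHIP) — cohort sizes, male counts, means of age / resting heart rate /
follow-up, and incident-AF counts — plus the published per-stratum
stage p-values and causal hazard ratios. They are aggregate inputs for
the descriptive and arithmetic-reconciliation steps of the analysis;
no individual-level data is included. SHIP reports no time-to-event
follow-up (binary outcome only), hence its missing follow-up entry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Baseline characteristics by cohort: n, male n, mean age (y), mean
#: resting heart rate (bpm), incident AF n, mean follow-up (y).
AFGEN_COHORTS = pd.DataFrame(
    [
        ("ARIC", 8994, 4214, 54, 67, 1817, 22.0),
        ("FHS", 7829, 3553, 53, 64, 757, 11.0),
        ("MESA", 2489, 1183, 63, 63, 448, 12.0),
        ("PREVEND", 3501, 1804, 49, 69, 169, 11.0),
        ("PROSPER", 5244, 2524, 75, 66, 505, 3.0),
        ("RS-I", 5043, 2021, 68, 71, 818, 15.0),
        ("RS-II", 1987, 899, 65, 69, 171, 12.0),
        ("SHIP", 3894, 1908, 49, 73, 94, np.nan),
    ],
    columns=[
        "cohort",
        "n",
        "n_male",
        "mean_age",
        "mean_heart_rate",
        "n_incident_af",
        "mean_followup",
    ],
)

#: Per-stratum p-values of the pleiotropy model (PRS on incident AF
#: adjusted for heart rate), as reported in the consortium results.
PLEIOTROPY_P = {"low": 0.052, "mid": 0.082, "high": 0.778}

#: Per-stratum p-values of the unadjusted PRS-on-AF stage.
STAGE2_P = {"low": 0.027, "mid": 0.017, "high": 0.293}

#: Published per-stratum causal hazard ratios per 5 bpm with 95% CI and p.
CAUSAL_TABLE = pd.DataFrame(
    [
        ("low", 0.82, 0.73, 0.95, 0.010),
        ("mid", 0.82, 0.59, 1.05, 0.133),
        ("high", 1.16, 0.95, 1.34, 0.150),
    ],
    columns=["stratum", "hr_per_5bpm", "ci_low", "ci_high", "p"],
)

#: Low-stratum per-1-bpm hazard ratio and CI (abstract-scale reporting).
LOW_STRATUM_PER_BPM = {"hr": 0.96, "ci_low": 0.94, "ci_high": 0.99}


def published_cohort_rows() -> pd.DataFrame:
    """The cohort table in the schema ``pooled_descriptives`` expects."""
    df = AFGEN_COHORTS.copy()
    df["n_women"] = df["n"] - df["n_male"]
    return df[
        ["cohort", "n", "n_women", "mean_age", "mean_heart_rate", "n_incident_af", "mean_followup"]
    ].rename(columns={"n_incident_af": "n_events"})
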