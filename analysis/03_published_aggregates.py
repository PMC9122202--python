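#!/usr/bin/env python
"""Reproduce the consortium-level arithmetic from published aggregates.

Three self-contained checks that need only the published per-cohort
summary rows and per-stratum p-values as inputs:

* pooled descriptives (total n, incident AF, % women, weighted means of
  age / heart rate / follow-up);
* Fisher's combination of the three per-stratum pleiotropy p-values;
* reconciliation of the per-bpm and per-5-bpm reporting scales of the
  low-stratum causal hazard ratio, plus the Bonferroni decisions.

Writes results/published_aggregates.tsv.

Run from the repository root:  python analysis/03_published_aggregates.py
"""

import math
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from stratmr import bonferroni_decision, fisher_combine, pooled_descriptives
from stratmr.reference import (
    CAUSAL_TABLE,
    LOW_STRATUM_PER_BPM,
    PLEIOTROPY_P,
    published_cohort_rows,
)


def main() -> int:
    rows = published_cohort_rows()
    d = pooled_descriptives(rows)
    print(f"pooled over {len(rows)} cohorts: n = {d['total_n']:.0f}, "
          f"incident AF = {d['total_events']:.0f} ({d['pct_incident_af']:.0f}%), "
          f"{d['pct_women']:.0f}% women")
    print(f"size-weighted means: age {d['mean_age']:.0f} y, heart rate "
          f"{d['mean_heart_rate']:.0f} bpm, follow-up {d['mean_followup']:.0f} y "
          "(over cohorts reporting follow-up)")

    fisher_p = fisher_combine(list(PLEIOTROPY_P.values()))
    print(f"Fisher combination of pleiotropy p-values "
          f"{tuple(PLEIOTROPY_P.values())}: p = {fisher_p:.3f} "
          "(no evidence the score acts on AF other than through heart rate)")

    per5 = {k: math.exp(5 * math.log(v)) for k, v in LOW_STRATUM_PER_BPM.items()}
    print(f"low stratum per-bpm HR {LOW_STRATUM_PER_BPM['hr']} "
          f"(CI {LOW_STRATUM_PER_BPM['ci_low']}-{LOW_STRATUM_PER_BPM['ci_high']}) "
          f"= per-5-bpm HR {per5['hr']:.2f} (CI {per5['ci_low']:.2f}-{per5['ci_high']:.2f})")

    decisions = {
        row["stratum"]: bonferroni_decision(row["p"], n_tests=3)
        for _, row in CAUSAL_TABLE.iterrows()
    }
    print(f"Bonferroni decisions at 0.017: {decisions} "
          "(only the low stratum is significant)")

    out_rows = [
        {"quantity": k, "value": v}
        for k, v in [
            ("total_n", d["total_n"]),
            ("total_incident_af", d["total_events"]),
            ("pct_incident_af", d["pct_incident_af"]),
            ("pct_women", d["pct_women"]),
            ("mean_age_years", d["mean_age"]),
            ("mean_heart_rate_bpm", d["mean_heart_rate"]),
            ("mean_followup_years", d["mean_followup"]),
            ("fisher_pleiotropy_p", fisher_p),
            ("low_hr_per_5bpm", per5["hr"]),
            ("low_ci_low_per_5bpm", per5["ci_low"]),
            ("low_ci_high_per_5bpm", per5["ci_high"]),
            *[(f"significant_{s}", float(v)) for s, v in decisions.items()],
        ]
    ]
    os.makedirs("results", exist_ok=True)
    pd.DataFrame(out_rows).to_csv("results/published_aggregates.tsv", sep="\t", index=False)
    print("table written to results/published_aggregates.tsv")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
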