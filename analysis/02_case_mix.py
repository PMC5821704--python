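#!/usr/bin/env python
"""Compare the two cohorts' case mix and tabulate non-satisfaction rates.

Reads the cohorts from step 01, codes the twelve candidate predictors,
and writes a case-mix comparison table (chi-squared for categorical,
Welch t for continuous, denominators excluding missing) plus
per-category non-satisfaction event rates.
"""

from pathlib import Path

import pandas as pd

from tkrsat import code_predictors, compare_cohorts, event_rates, \
    outcome_prevalence, read_cohort_csv

OUT = Path("results/analysis")
dev = code_predictors(read_cohort_csv(OUT / "development_cohort.csv"))
ext = code_predictors(read_cohort_csv(OUT / "external_cohort.csv"))

for label, coded in [("development", dev), ("external", ext)]:
    ev, n, pct = outcome_prevalence(coded)
    print(f"{label}: {ev}/{n} non-satisfied ({pct}%)")

table = compare_cohorts(dev, ext)
table.to_csv(OUT / "case_mix_comparison.csv", index=False)
print("\nCase-mix comparison (development vs external):")
print(table.to_string(index=False))

rates = pd.concat(
    [event_rates(dev, v).assign(cohort="development") for v in
     ("man", "anxiety", "smoker", "steroid")]
    + [event_rates(ext, v).assign(cohort="external") for v in
       ("man", "anxiety", "smoker", "steroid")],
    ignore_index=True)
rates.to_csv(OUT / "event_rates.csv", index=False)
print("\nNon-satisfaction rates by category written to event_rates.csv")
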