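#!/usr/bin/env python
"""Develop the prediction model on the UK-like cohort.

Multiply imputes the development cohort (chained equations, hospital as
auxiliary), runs 200 bootstrap backward selections at alpha = 0.157 with
sex and age forced, retains predictors selected at least 60% of the
time, and fits the final Rubin-pooled logistic model.  Ten imputations
are used here to keep the driver quick; the pipeline default is 50.
"""

from pathlib import Path

from tkrsat import bootstrap_select, code_predictors, fit_logistic, impute, \
    read_cohort_csv, rubin_pool

OUT = Path("results/analysis")
coded = code_predictors(read_cohort_csv(OUT / "development_cohort.csv"))

stack = impute(coded, m=10, seed=3001, auxiliary=("hospital",))
stack.to_long().to_csv(OUT / "development_imputed_long.csv", index=False)
print(f"imputed: m={stack.m} completed datasets of n={len(stack.datasets[0])}")

selection = bootstrap_select(stack, B=200, alpha=0.157, threshold=0.60, seed=3002)
selection.to_frame().to_csv(OUT / "selection_report.csv", index=False)
print("\nBootstrap inclusion frequencies (B=200):")
print(selection.to_frame().round(3).to_string(index=False))
print("\nretained:", ", ".join(selection.retained))

fits = [fit_logistic(d, selection.retained) for d in stack]
model = rubin_pool(fits)
model.to_json(OUT / "development_model.json")
model.summary().round(4).to_csv(OUT / "development_coefficients.csv")
print("\nPooled development model:")
print(model.summary().round(3).to_string())
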