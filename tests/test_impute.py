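"""Chained-equation imputation and Rubin's-rules pooling."""

import numpy as np
import pandas as pd
import pytest

from tkrsat import (
    ModelFit,
    coast_spec,
    code_predictors,
    generate_cohort,
    impute,
    inject_missingness,
    rubin_pool,
)
from tkrsat.errors import ImputationError, PoolingError


def _fit(coefs, variances, n=100):
    names = ["intercept"] + [k for k in coefs if k != "intercept"]
    coef = pd.Series({**coefs}).reindex(names)
    cov = pd.DataFrame(np.diag([variances[k] for k in names]),
                       index=names, columns=names)
    return ModelFit(predictors=names[1:], coefficients=coef, cov=cov, n=n)


def test_no_missing_input_returns_m_identical_copies(coast_coded):
    stack = impute(coast_coded, m=3, seed=1)
    assert stack.m == 3
    for d in stack.datasets:
        pd.testing.assert_frame_equal(
            d.reset_index(drop=True), coast_coded.reset_index(drop=True),
            check_like=True)


def test_requested_m_is_honoured_and_cells_completed():
    spec = coast_spec(n=150)
    df = inject_missingness(generate_cohort(spec, seed=2),
                            spec.missingness_rates, seed=3)
    stack = impute(code_predictors(df), m=50, seed=4, n_cycles=3)
    assert stack.m == 50
    analysis_cols = [c for c in stack.datasets[0].columns
                     if c not in ("id", "hospital", "cohort")]
    assert not any(d[analysis_cols].isna().any().any() for d in stack.datasets)


def test_observed_cells_identical_across_imputations():
    spec = coast_spec(n=300)
    coded = code_predictors(inject_missingness(
        generate_cohort(spec, seed=5), spec.missingness_rates, seed=6))
    stack = impute(coded, m=4, seed=7, n_cycles=3)
    observed = coded["anxiety"].notna()
    base = stack.datasets[0].loc[observed, "anxiety"]
    for d in stack.datasets[1:]:
        assert d.loc[observed, "anxiety"].equals(base)
        assert not d["anxiety"].isna().any()


def test_mcar_imputation_recovers_generating_prevalence():
    """Pooled imputed education prevalence lands near the generating truth."""
    spec = coast_spec(n=20000, missingness_rates={})
    df = generate_cohort(spec, seed=8)
    truth = spec.marginals["education_higher"]
    miss = inject_missingness(df, {"education": 1 - 377 / 450}, seed=9)
    stack = impute(code_predictors(miss), m=10, seed=10)
    pooled_prev = np.mean([d["education_higher"].mean() for d in stack.datasets])
    assert abs(pooled_prev - truth) < 0.02


def test_mar_imputation_beats_complete_case_bias():
    """Under MAR-on-age/sex missingness of an age-correlated score, the
    complete-case mean is biased while the imputation-based mean (whose
    model includes age) is closer to the generating truth.

    The default generator draws predictors independently, so the score is
    made age-dependent here on purpose; without that dependence
    MAR-on-age/sex cannot bias the score's complete-case mean.
    """
    spec = coast_spec(n=20000, missingness_rates={})
    df = generate_cohort(spec, seed=11)
    rng = np.random.default_rng(111)
    df["pain_function_raw"] = np.clip(
        20 + 0.8 * (df["age_at_operation"] - 70) + rng.normal(0, 6, len(df)),
        0, 48)
    truth = df["pain_function_raw"].mean()
    miss = inject_missingness(df, {"pain_function_raw": 0.30},
                              mechanism="MAR_on_age_sex", seed=12)
    coded = code_predictors(miss)
    cc_bias = abs(coded["pain_function_raw"].mean() - truth)
    stack = impute(coded, m=5, seed=13, n_cycles=5)
    imp_mean = np.mean([d["pain_function_raw"].mean() for d in stack.datasets])
    assert cc_bias > 0.3  # the mechanism really biases complete cases
    assert abs(imp_mean - truth) < cc_bias


def test_fully_missing_variable_is_impossible(coast_coded):
    broken = coast_coded.copy()
    broken["anxiety"] = np.nan
    with pytest.raises(ImputationError):
        impute(broken, m=2, seed=14)


def test_rubin_two_imputation_hand_computation():
    fits = [_fit({"intercept": 0.0, "x": 0.4}, {"intercept": 1.0, "x": 0.01}),
            _fit({"intercept": 0.0, "x": 0.6}, {"intercept": 1.0, "x": 0.01})]
    pooled = rubin_pool(fits)
    assert pooled.coefficients["x"] == pytest.approx(0.5)
    # W + (1 + 1/m) B = 0.01 + 1.5 * 0.02 = 0.04
    assert pooled.cov.loc["x", "x"] == pytest.approx(0.04)


def test_rubin_identical_fits_have_zero_between_variance():
    f = _fit({"intercept": -1.0, "x": 0.3}, {"intercept": 0.5, "x": 0.02})
    pooled = rubin_pool([f, f, f])
    assert pooled.coefficients.equals(f.coefficients)
    assert pooled.cov.loc["x", "x"] == pytest.approx(0.02)
    assert np.isinf(pooled.df["x"])


def test_rubin_order_invariant_and_dominates_within_variance():
    rng = np.random.default_rng(15)
    fits = [_fit({"intercept": rng.normal(), "x": rng.normal()},
                 {"intercept": 0.3, "x": 0.05}) for _ in range(6)]
    a = rubin_pool(fits)
    b = rubin_pool(fits[::-1])
    pd.testing.assert_series_equal(a.coefficients, b.coefficients)
    pd.testing.assert_frame_equal(a.cov, b.cov)
    assert (np.diag(a.cov) >= 0.05 - 1e-12).all()


def test_rubin_rejects_mismatched_predictors():
    with pytest.raises(PoolingError):
        rubin_pool([_fit({"intercept": 0, "x": 1}, {"intercept": 1, "x": 1}),
                    _fit({"intercept": 0, "y": 1}, {"intercept": 1, "y": 1})])


def test_long_format_roundtrip():
    spec = coast_spec(n=120)
    coded = code_predictors(inject_missingness(
        generate_cohort(spec, seed=16), spec.missingness_rates, seed=17))
    stack = impute(coded, m=3, seed=18, n_cycles=2)
    from tkrsat.impute import ImputedStack
    back = ImputedStack.from_long(stack.to_long())
    assert back.m == 3
    for a, b in zip(stack.datasets, back.datasets):
        pd.testing.assert_frame_equal(a, b, check_like=True)
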