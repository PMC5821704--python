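"""Logistic fitting, prediction, AUC, calibration and optimism correction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from tkrsat import (
    ModelFit,
    agresti_coull_interval,
    auc,
    calibration_table,
    fit_logistic,
    optimism_corrected_auc,
    predict_probability,
)
from tkrsat.errors import (
    FitError,
    ParameterError,
    PredictionError,
    SeparationError,
    UndefinedAUCError,
)
from tkrsat.published import DEVELOPMENT_COEF


def _published_fit():
    names = ["intercept", "man", "age", "anxiety", "smoker", "steroid", "std_score"]
    return ModelFit(
        predictors=names[1:],
        coefficients=pd.Series({k: DEVELOPMENT_COEF[k] for k in names}),
        cov=pd.DataFrame(np.eye(7) * 0.01, index=names, columns=names),
        n=450,
    )


def _brute_force_auc(p, y):
    """Exhaustive case-control pair enumeration; ties count one half."""
    cases = [pi for pi, yi in zip(p, y) if yi == 1]
    controls = [pi for pi, yi in zip(p, y) if yi == 0]
    wins = sum(1.0 if c > d else 0.5 if c == d else 0.0
               for c, d in itertools.product(cases, controls))
    return wins / (len(cases) * len(controls))


# ---------------------------------------------------------------------------
# fitting


def test_single_binary_predictor_matches_closed_form_log_odds_ratio():
    a, b, c, d = 30, 70, 15, 85  # exposed cases/controls, unexposed cases/controls
    rows = ([(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d)
    df = pd.DataFrame(rows, columns=["x", "outcome_nonsatisfied"]).astype(float)
    fit = fit_logistic(df, ["x"])
    assert fit.coefficients["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)


def test_one_class_outcome_is_an_error():
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "outcome_nonsatisfied": [0.0, 0.0, 0.0]})
    with pytest.raises(FitError):
        fit_logistic(df, ["x"])


def test_complete_separation_raises_and_names_predictor():
    n = 40
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"sep": np.r_[np.zeros(20), np.ones(20)],
                       "other": rng.normal(size=n),
                       "outcome_nonsatisfied": np.r_[np.zeros(20), np.ones(20)]})
    with pytest.raises(SeparationError, match="sep"):
        fit_logistic(df, ["sep", "other"])


# ---------------------------------------------------------------------------
# prediction


def test_published_reference_patient_probability():
    """Woman, 70 years, no anxiety/smoking/steroid, average score:
    1 / (1 + exp(1.89)) from the development equation."""
    fit = _published_fit()
    row = {"man": 0, "age": 70, "anxiety": 0, "smoker": 0, "steroid": 0,
           "std_score": 0.0}
    expected = 1 / (1 + np.exp(-(-3.29 + 0.02 * 70)))
    assert predict_probability(fit, row) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.131, abs=5e-4)


def test_intercept_only_at_zero_gives_half_and_score_odds_factor():
    fit = _published_fit()
    base = predict_probability(fit, {"man": 0, "age": 70, "anxiety": 0,
                                     "smoker": 0, "steroid": 0, "std_score": 0.0})
    worse = predict_probability(fit, {"man": 0, "age": 70, "anxiety": 0,
                                      "smoker": 0, "steroid": 0, "std_score": -1.0})
    odds = lambda p: p / (1 - p)
    assert odds(worse) / odds(base) == pytest.approx(np.exp(0.37), rel=1e-9)

    names = ["intercept"]
    trivial = ModelFit(predictors=[], coefficients=pd.Series({"intercept": 0.0}),
                       cov=pd.DataFrame([[1.0]], index=names, columns=names), n=1)
    assert predict_probability(trivial, {}) == pytest.approx(0.5)


def test_prediction_refuses_missing_values():
    fit = _published_fit()
    with pytest.raises(PredictionError):
        predict_probability(fit, {"man": 0, "age": 70, "anxiety": np.nan,
                                  "smoker": 0, "steroid": 0, "std_score": 0.0})
    with pytest.raises(PredictionError):
        predict_probability(fit, {"man": 0, "age": 70})


# ---------------------------------------------------------------------------
# AUC


def test_auc_extremes_and_undefined():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5
    with pytest.raises(UndefinedAUCError):
        auc([0.1, 0.2], [1, 1])


def test_auc_matches_pair_enumeration_and_sklearn_on_toys():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = int(rng.integers(6, 20))
        p = np.round(rng.random(n), 1)  # rounding forces ties
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        ours = auc(p, y)
        assert ours == pytest.approx(_brute_force_auc(p, y), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(y, p), abs=1e-12)


@given(st.lists(st.tuples(st.floats(0.01, 0.99), st.integers(0, 1)),
                min_size=6, max_size=40).filter(
                    lambda rows: 0 < sum(r[1] for r in rows) < len(rows)))
def test_auc_invariant_under_strictly_increasing_transforms(rows):
    p = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    base = auc(p, y)
    assert auc(np.exp(3 * p), y) == pytest.approx(base, abs=1e-12)
    assert auc(2 * p - 5, y) == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# calibration


def test_agresti_coull_hand_computed_interval():
    lo, hi = agresti_coull_interval(5, 10, z=1.96)
    assert lo == pytest.approx(0.2366, abs=5e-5)
    assert hi == pytest.approx(0.7634, abs=5e-5)


def test_agresti_coull_clips_at_zero():
    lo, hi = agresti_coull_interval(0, 10, z=1.96)
    assert lo == 0.0 and 0 < hi < 0.4


def test_calibration_bins_partition_with_near_equal_sizes():
    rng = np.random.default_rng(3)
    p = rng.random(1003)  # no ties
    y = (rng.random(1003) < p).astype(float)
    cal = calibration_table(p, y)
    assert cal["n"].sum() == 1003
    assert cal["n"].max() - cal["n"].min() <= 1
    # remainder spread from the lowest bin
    assert cal["n"].iloc[0] >= cal["n"].iloc[-1]
    assert cal["mean_predicted"].is_monotonic_increasing


def test_calibration_keeps_ties_in_one_bin():
    p = np.r_[np.full(55, 0.2), np.linspace(0.3, 0.9, 45)]
    y = np.zeros(100)
    y[::4] = 1
    cal = calibration_table(p, y)
    assert cal["n"].iloc[0] == 55  # all tied lowest predictions share bin 1
    assert cal["n"].sum() == 100


def test_calibration_coverage_on_perfectly_calibrated_data():
    for seed in (21, 22):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.02, 0.5, 50000)
        y = (rng.random(50000) < p).astype(float)
        cal = calibration_table(p, y)
        covered = ((cal["observed"] >= cal["ci_low"])
                   & (cal["observed"] <= cal["ci_high"])).sum()
        assert covered >= 9


def test_calibration_parameter_errors():
    with pytest.raises(ParameterError):
        calibration_table([0.1, 0.9], [0, 1], bins=1)
    with pytest.raises(ParameterError):
        calibration_table([0.1, 0.9], [0, 1], bins=10)


# ---------------------------------------------------------------------------
# optimism


def _sim_data(n, seed):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x1": rng.normal(size=n),
                       "x2": rng.integers(0, 2, n).astype(float)})
    df["outcome_nonsatisfied"] = (
        rng.random(n) < expit(-1 + 1.2 * df.x1 + 0.8 * df.x2)).astype(float)
    return df


def test_corrected_auc_identity_is_exact():
    df = _sim_data(600, 4)
    rep = optimism_corrected_auc(df, ["x1", "x2"], B=25, seed=5)
    assert rep.auc_corrected == pytest.approx(rep.auc_apparent - rep.optimism,
                                              abs=1e-12)
    assert 0 <= rep.auc_apparent <= 1
    # corrected never exceeds apparent when the optimism is non-negative
    assert (rep.optimism < 0) or (rep.auc_corrected <= rep.auc_apparent)


def test_degenerate_identity_resample_has_zero_optimism():
    """When the single bootstrap replicate equals the original sample the
    bootstrap and original AUCs coincide, so the optimism is exactly 0."""
    class IdentityRng:
        def integers(self, high, size=None):
            return np.arange(size) if size is not None else 0

    df = _sim_data(300, 6)
    rep = optimism_corrected_auc(df, ["x1", "x2"], B=1, rng=IdentityRng())
    assert rep.optimism == 0.0
    assert rep.auc_corrected == rep.auc_apparent
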