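"""Schema coding, outcome dichotomisation, exclusions and standardisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tkrsat import (
    apply_exclusions,
    code_predictors,
    dichotomise_outcome,
    read_cohort_csv,
    standardise_score,
    write_cohort_csv,
)
from tkrsat.cohort import ExclusionRule
from tkrsat.errors import (
    CodingError,
    DegenerateScaleError,
    InputValidationError,
    SchemaError,
)


@pytest.mark.parametrize("level,expected", [
    ("very_satisfied", 0),
    ("somewhat_satisfied", 0),
    ("neither", 1),
    ("somewhat_dissatisfied", 1),
    ("very_dissatisfied", 1),
])
def test_dichotomise_groups_satisfied_against_the_rest(level, expected):
    assert dichotomise_outcome(level) == expected


def test_dichotomise_missing_stays_missing_and_unknown_raises():
    assert np.isnan(dichotomise_outcome(np.nan))
    with pytest.raises(CodingError, match="ecstatic"):
        dichotomise_outcome("ecstatic")
    s = pd.Series(["neither", np.nan, "very_satisfied"])
    out = dichotomise_outcome(s)
    assert out.tolist()[0] == 1 and np.isnan(out[1]) and out[2] == 0


def _raw_table(n_rev=3, n_masked=2, n_nofollow=4, n_nosat=1, n_ok=5):
    rows = []
    for i in range(n_rev):
        rows.append(("revision", 0.0, 1.0, "very_satisfied"))
    for i in range(n_masked):
        rows.append(("primary_tkr", 1.0, 1.0, "neither"))
    for i in range(n_nofollow):
        rows.append(("primary_tkr", 0.0, 0.0, np.nan))
    for i in range(n_nosat):
        rows.append(("primary_tkr", 0.0, 1.0, np.nan))
    for i in range(n_ok):
        rows.append(("primary_tkr", 0.0, 1.0, "somewhat_satisfied"))
    df = pd.DataFrame(rows, columns=["operation_type", "dx_sciatica",
                                     "followup_returned", "satisfaction_5level"])
    return df.sample(frac=1, random_state=0).reset_index(drop=True)


def test_exclusion_cascade_counts_sum_and_order():
    raw = _raw_table()
    included, log = apply_exclusions(raw)
    assert log["step"].tolist() == ["primary_tkr_only", "masking_diagnosis",
                                    "followup_completers", "satisfaction_answered"]
    assert log["removed"].tolist() == [3, 2, 4, 1]
    assert len(included) + log["removed"].sum() == len(raw)
    assert log["remaining"].iloc[-1] == len(included) == 5


def test_exclusions_idempotent_and_passthrough():
    raw = _raw_table(n_rev=0, n_masked=0, n_nofollow=0, n_nosat=0, n_ok=7)
    included, log = apply_exclusions(raw)
    assert len(included) == 7 and log["removed"].sum() == 0
    again, log2 = apply_exclusions(included)
    pd.testing.assert_frame_equal(again, included)
    assert log2["removed"].sum() == 0


def test_exclusions_all_revisions_empty_output():
    raw = _raw_table(n_rev=6, n_masked=0, n_nofollow=0, n_nosat=0, n_ok=0)
    included, log = apply_exclusions(raw)
    assert included.empty
    assert log.loc[log["step"] == "primary_tkr_only", "removed"].item() == 6


def test_exclusions_schema_error():
    with pytest.raises(SchemaError):
        apply_exclusions(pd.DataFrame({"operation_type": ["primary_tkr"]}))


def test_standardise_symmetric_triple_and_published_arithmetic():
    std, mean, sd = standardise_score(pd.Series([10.0, 20.0, 30.0]))
    assert np.allclose(std, [-1, 0, 1])
    # a raw score of 12 in a cohort with mean 20, sd 8 sits exactly 1 sd low
    assert (12 - 20) / 8 == -1.0


def test_standardise_roundtrip_and_moments():
    rng = np.random.default_rng(3)
    x = pd.Series(rng.normal(20, 8, 500))
    std, mean, sd = standardise_score(x)
    assert abs(std.mean()) < 1e-9 and abs(std.std(ddof=1) - 1) < 1e-9
    assert np.allclose(std * sd + mean, x, atol=1e-9)


def test_standardise_degenerate_inputs():
    with pytest.raises(DegenerateScaleError):
        standardise_score(pd.Series([15.0, 15.0, 15.0]))
    with pytest.raises(DegenerateScaleError):
        standardise_score(pd.Series([15.0]))


def test_code_predictors_reference_categories(patients):
    coded = code_predictors(patients)
    # woman with BMI>=35
    assert coded.loc[0, "man"] == 0 and coded.loc[0, "bmi_ge35"] == 1
    # man treated for anxiety
    assert coded.loc[1, "man"] == 1 and coded.loc[1, "anxiety"] == 1
    # comorbidity 3plus -> ordinal 3, dummy set {0,0,1}
    assert coded.loc[1, "comorbidity"] == 3
    assert (coded.loc[1, ["comorb_1", "comorb_2", "comorb_3plus"]].tolist()
            == [0.0, 0.0, 1.0])
    # missing education/msk propagate as NaN
    assert np.isnan(coded.loc[2, "education_higher"])
    assert np.isnan(coded.loc[4, "condition_OA"])
    # outcome coding matches the satisfaction answers
    assert coded["outcome_nonsatisfied"].tolist() == [0, 1, 0, 1, 0, 1]
    # std_score scale is recorded
    assert coded.attrs["score_sd"] > 0


def test_code_predictors_rejects_bad_values(patients):
    bad = patients.copy()
    bad.loc[0, "age_at_operation"] = 15.0
    with pytest.raises(InputValidationError):
        code_predictors(bad)
    bad2 = patients.copy()
    bad2.loc[0, "comorbidity_count"] = "many"
    with pytest.raises(CodingError):
        code_predictors(bad2)


def test_csv_roundtrip_preserves_missing(tmp_path, patients):
    path = tmp_path / "cohort.csv"
    write_cohort_csv(patients, path)
    back = read_cohort_csv(path)
    assert back["education"].isna().tolist() == patients["education"].isna().tolist()
    assert back.loc[0, "sex"] == "woman"
    assert back["comorbidity_count"].tolist() == patients["comorbidity_count"].tolist()
    pd.testing.assert_series_equal(back["pain_function_raw"],
                                   patients["pain_function_raw"], check_names=False)


@given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=3, max_size=50)
       .filter(lambda xs: max(xs) - min(xs) > 1e-6))
def test_standardisation_is_affine_invertible(xs):
    x = pd.Series(xs, dtype=float)
    std, mean, sd = standardise_score(x)
    assert np.allclose(std * sd + mean, x, rtol=1e-9, atol=1e-6)
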