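import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tkrsat import code_predictors, coast_spec, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# statsmodels emits benign overflow/convergence warnings on bootstrap resamples
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def coast_complete():
    """Complete COASt-like cohort at the published size, no missingness."""
    return generate_cohort(coast_spec(missingness_rates={}), seed=42)


@pytest.fixture(scope="session")
def coast_coded(coast_complete):
    return code_predictors(coast_complete)


@pytest.fixture(scope="session")
def coast_large_coded():
    """Large complete cohort for asymptotic checks."""
    df = generate_cohort(coast_spec(n=20000, missingness_rates={}), seed=7)
    return code_predictors(df)


def small_patient_table():
    """Hand-written six-patient table covering the coding paths."""
    return pd.DataFrame({
        "id": [f"p{i}" for i in range(6)],
        "sex": ["woman", "man", "woman", "man", "woman", "man"],
        "age_at_operation": [70.0, 65.0, 80.0, 55.0, 72.0, 68.0],
        "education": ["higher", "lower", np.nan, "lower", "higher", "lower"],
        "bmi_class": ["ge35", "lt35", "lt35", "ge35", "lt35", "lt35"],
        "msk_condition": ["OA", "OA", "RA_other", "OA", np.nan, "OA"],
        "comorbidity_count": ["0", "3plus", "1", "2", "0", "1"],
        "treated_anxiety": [0.0, 1.0, 0.0, np.nan, 0.0, 1.0],
        "treated_depression": [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],
        "current_smoker": [0.0, 0.0, 0.0, 1.0, 0.0, 0.0],
        "steroid_injection": [1.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        "surgeon_experienced": [1.0, 0.0, 1.0, 0.0, np.nan, 1.0],
        "pain_function_raw": [10.0, 20.0, 30.0, 15.0, 25.0, np.nan],
        "satisfaction_5level": ["very_satisfied", "neither", "somewhat_satisfied",
                                "very_dissatisfied", "somewhat_satisfied",
                                "somewhat_dissatisfied"],
        "hospital": ["A", "A", "B", "B", "A", "B"],
        "cohort": ["development"] * 6,
    })


@pytest.fixture
def patients():
    return small_patient_table()
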