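"""Cohort schema, outcome dichotomisation, exclusion filtering and predictor coding.

Patient-level tables hold one row per patient with canonical snake_case
columns (:data:`PATIENT_COLUMNS`).  Missing values are empty cells in CSV
and NaN in memory.  Twelve candidate predictors known before surgery are
coded against the reference categories of the published model (woman,
not treated, non-smoker, no injection); age stays continuous and
uncentred, and the pain/function score (OKS or WOMAC, lower = worse) is
standardised to mean 0, sd 1 within its own cohort so that the two
instruments are comparable on the standardised scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CodingError,
    DegenerateScaleError,
    InputValidationError,
    SchemaError,
)

# ---------------------------------------------------------------------------
# Schema constants

SATISFACTION_LEVELS = (
    "very_satisfied",
    "somewhat_satisfied",
    "neither",
    "somewhat_dissatisfied",
    "very_dissatisfied",
)
_SATISFIED = {"very_satisfied", "somewhat_satisfied"}
_NON_SATISFIED = {"neither", "somewhat_dissatisfied", "very_dissatisfied"}

SEX_LEVELS = ("woman", "man")
EDUCATION_LEVELS = ("lower", "higher")
BMI_LEVELS = ("lt35", "ge35")
MSK_LEVELS = ("OA", "RA_other")
COMORBIDITY_LEVELS = ("0", "1", "2", "3plus")

#: Diagnoses that can mask the satisfaction outcome and exclude a patient.
MASKING_CONDITIONS = (
    "multiple_sclerosis",
    "leg_neuropathy",
    "sciatica",
    "stroke",
    "cerebellar_ataxia",
    "knee_septic_arthritis",
    "pseudo_gout",
    "avascular_necrosis",
    "polymyalgia",
    "sle",
    "fibromyalgia",
    "alzheimer",
    "poliomyelitis",
)

#: Canonical columns of a patient-record table.
PATIENT_COLUMNS = [
    "id",
    "sex",
    "age_at_operation",
    "education",
    "bmi_class",
    "msk_condition",
    "comorbidity_count",
    "treated_anxiety",
    "treated_depression",
    "current_smoker",
    "steroid_injection",
    "surgeon_experienced",
    "pain_function_raw",
    "satisfaction_5level",
    "hospital",
    "cohort",
]

#: The 12-candidate predictor pool, in declared order. Comorbidity enters
#: selection as a single ordinal 0-3 (no per-level coefficient is published;
#: dummies are kept for descriptive output).
CANDIDATE_PREDICTORS = [
    "man",
    "age",
    "education_higher",
    "bmi_ge35",
    "condition_OA",
    "comorbidity",
    "anxiety",
    "depression",
    "smoker",
    "steroid",
    "surgeon_experienced",
    "std_score",
]

FORCED_PREDICTORS = ("man", "age")

OUTCOME = "outcome_nonsatisfied"

# string categories as read from CSV
_STRING_COLUMNS = [
    "id", "sex", "education", "bmi_class", "msk_condition",
    "comorbidity_count", "satisfaction_5level", "hospital", "cohort",
    "operation_type",
]


# ---------------------------------------------------------------------------
# Outcome

def dichotomise_outcome(satisfaction):
    """Collapse the five-level satisfaction answer to binary non-satisfaction.

    Very/somewhat satisfied map to 0; neither and somewhat/very
    dissatisfied map to 1. Missing answers stay missing.

    Accepts a scalar or a Series; raises :class:`CodingError` on any value
    outside the five levels.
    """
    if isinstance(satisfaction, pd.Series):
        out = pd.Series(np.nan, index=satisfaction.index, dtype=float)
        notna = satisfaction.notna()
        vals = satisfaction[notna]
        bad = set(vals.unique()) - _SATISFIED - _NON_SATISFIED
        if bad:
            raise CodingError(f"unknown satisfaction level(s): {sorted(bad)!r}")
        out[notna] = vals.isin(_NON_SATISFIED).astype(float)
        return out
    if satisfaction is None or pd.isna(satisfaction):
        return np.nan
    if satisfaction in _SATISFIED:
        return 0
    if satisfaction in _NON_SATISFIED:
        return 1
    raise CodingError(f"unknown satisfaction level: {satisfaction!r}")


# ---------------------------------------------------------------------------
# Exclusion cascade

@dataclass(frozen=True)
class ExclusionRule:
    """Ordered filters applied to a raw registry extract.

    The same rule applied twice is a no-op on the already-filtered table.
    """

    masking_conditions: tuple = MASKING_CONDITIONS
    require_primary_tkr: bool = True
    require_followup_response: bool = True


def apply_exclusions(raw: pd.DataFrame, rule: ExclusionRule = ExclusionRule()):
    """Filter a raw cohort table down to the analysable set.

    Steps, in order: keep primary TKR; drop patients with a masking
    diagnosis; keep one-year follow-up completers; drop patients who did
    not answer the satisfaction question.  Returns ``(included, log)``
    where ``log`` has one row per step with the count removed and
    remaining.  The per-step removed counts plus the included count always
    sum to the raw row count.
    """
    required = {"operation_type", "followup_returned", "satisfaction_5level"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise SchemaError(f"raw table lacks required columns: {sorted(missing_cols)}")

    steps = []
    tab = raw

    if rule.require_primary_tkr:
        keep = tab["operation_type"] == "primary_tkr"
        steps.append(("primary_tkr_only", int((~keep).sum())))
        tab = tab[keep]

    dx_cols = [f"dx_{c}" for c in rule.masking_conditions if f"dx_{c}" in tab.columns]
    if rule.masking_conditions and not dx_cols and any(
        c.startswith("dx_") for c in raw.columns
    ):
        pass  # none of this rule's conditions are recorded; nothing to drop
    if dx_cols:
        masked = tab[dx_cols].fillna(0).astype(float).sum(axis=1) > 0
    else:
        masked = pd.Series(False, index=tab.index)
    steps.append(("masking_diagnosis", int(masked.sum())))
    tab = tab[~masked]

    if rule.require_followup_response:
        keep = tab["followup_returned"].fillna(0).astype(float) > 0
        steps.append(("followup_completers", int((~keep).sum())))
        tab = tab[keep]

    keep = tab["satisfaction_5level"].notna()
    steps.append(("satisfaction_answered", int((~keep).sum())))
    tab = tab[keep]

    log = pd.DataFrame(steps, columns=["step", "removed"])
    log["remaining"] = len(raw) - log["removed"].cumsum()
    return tab.copy(), log


# ---------------------------------------------------------------------------
# Score standardisation

def standardise_score(raw_scores: pd.Series):
    """Standardise a cohort's pain/function score to mean 0, sd 1.

    Uses the cohort's own complete-case mean and sample sd (ddof=1);
    missing values stay missing. Returns ``(std, mean, sd)`` so the scale
    used can be reported and the transform inverted.
    """
    scores = pd.Series(raw_scores, dtype=float)
    obs = scores.dropna()
    if len(obs) < 2:
        raise DegenerateScaleError("need at least 2 observed scores to standardise")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateScaleError("scores are constant; standardisation undefined")
    return (scores - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# Predictor coding

def _map_category(series: pd.Series, mapping: dict, name: str) -> pd.Series:
    out = pd.Series(np.nan, index=series.index, dtype=float)
    notna = series.notna()
    vals = series[notna].astype(str)
    bad = set(vals.unique()) - set(mapping)
    if bad:
        raise CodingError(f"unknown {name} value(s): {sorted(bad)!r}")
    out[notna] = vals.map(mapping).astype(float)
    return out


def _check_binary(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    obs = out.dropna()
    if not obs.isin([0, 1]).all():
        raise CodingError(f"{name} must be 0/1; got {sorted(obs.unique())!r}")
    bad_na = series.notna() & out.isna()
    if bad_na.any():
        raise CodingError(f"{name} contains non-numeric values")
    return out.astype(float)


def code_predictors(records: pd.DataFrame, standardise: bool = True) -> pd.DataFrame:
    """Map a patient-record table to the coded analysis table.

    Indicators use the published reference categories (woman, lower
    education, BMI<35, RA/other condition, not treated, non-smoker, no
    injection, less-experienced surgeon). Age stays in raw years.
    Comorbidity count is coded both as ordinal 0-3 (``comorbidity``, the
    form entering selection) and as three dummies against reference 0.
    With ``standardise=True`` the pain/function score is standardised
    within the table and the scale is stored in ``DataFrame.attrs``.

    Raises :class:`InputValidationError` for out-of-range age and
    :class:`CodingError` for illegal categories.
    """
    missing_cols = set(PATIENT_COLUMNS) - {"hospital", "cohort", "id"} - set(records.columns)
    if missing_cols:
        raise SchemaError(f"patient table lacks columns: {sorted(missing_cols)}")

    age = pd.to_numeric(records["age_at_operation"], errors="coerce")
    if age.isna().any():
        raise InputValidationError("age_at_operation must be complete and numeric")
    if (age <= 18).any() or (age > 110).any():
        raise InputValidationError("age_at_operation outside (18, 110]")

    coded = pd.DataFrame(index=records.index)
    for carry in ("id", "hospital", "cohort"):
        if carry in records.columns:
            coded[carry] = records[carry]

    coded[OUTCOME] = dichotomise_outcome(records["satisfaction_5level"])
    coded["man"] = _map_category(records["sex"], {"woman": 0, "man": 1}, "sex")
    if coded["man"].isna().any():
        raise InputValidationError("sex must never be missing")
    coded["age"] = age
    coded["education_higher"] = _map_category(
        records["education"], {"lower": 0, "higher": 1}, "education")
    bmi = _map_category(records["bmi_class"], {"lt35": 0, "ge35": 1}, "bmi_class")
    if bmi.isna().any():
        raise InputValidationError("bmi_class must never be missing")
    coded["bmi_ge35"] = bmi
    coded["condition_OA"] = _map_category(
        records["msk_condition"], {"OA": 1, "RA_other": 0}, "msk_condition")
    comorb = _map_category(
        records["comorbidity_count"], {"0": 0, "1": 1, "2": 2, "3plus": 3},
        "comorbidity_count")
    coded["comorbidity"] = comorb
    coded["comorb_1"] = (comorb == 1).astype(float).where(comorb.notna())
    coded["comorb_2"] = (comorb == 2).astype(float).where(comorb.notna())
    coded["comorb_3plus"] = (comorb == 3).astype(float).where(comorb.notna())
    coded["anxiety"] = _check_binary(records["treated_anxiety"], "treated_anxiety")
    coded["depression"] = _check_binary(records["treated_depression"], "treated_depression")
    coded["smoker"] = _check_binary(records["current_smoker"], "current_smoker")
    coded["steroid"] = _check_binary(records["steroid_injection"], "steroid_injection")
    coded["surgeon_experienced"] = _check_binary(
        records["surgeon_experienced"], "surgeon_experienced")

    raw_score = pd.to_numeric(records["pain_function_raw"], errors="coerce")
    coded["pain_function_raw"] = raw_score
    if standardise:
        std, mean, sd = standardise_score(raw_score)
        coded["std_score"] = std
        coded.attrs["score_mean"] = mean
        coded.attrs["score_sd"] = sd
    return coded


# ---------------------------------------------------------------------------
# CSV I/O  (UTF-8, comma-separated, header row, missing = empty cell)

def read_cohort_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a cohort CSV; `column_map` renames source columns to canonical names."""
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLUMNS if c != "id"},
                     keep_default_na=True)
    if column_map:
        df = df.rename(columns=column_map)
    for col in _STRING_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("string").astype(object).where(df[col].notna(), np.nan)
    if "id" in df.columns:
        df["id"] = df["id"].astype(str)
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")
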