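"""Synthetic COASt-like and GAR-like cohorts.

No public extract of either registry exists, so every downstream stage is
exercised on synthetic cohorts that emulate the published case mix: binary
predictors drawn independently at their marginal prevalences, age and the
raw pain/function score from truncated normals at the published
mean/sd/range, and the non-satisfaction outcome drawn from the published
logistic equation applied to the coded row.  Missingness is injected
afterwards, per variable, either completely at random (MCAR) or with
logistic dependence on the always-observed age and sex (MAR), calibrated
so the marginal missing fraction matches the requested rate.

Predictors are generated independently because only marginals are
published; an optional Gaussian-copula hook exists for sensitivity
analyses but defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from . import published
from .cohort import code_predictors
from .errors import ParameterError

#: Variables that are never missing in either registry.
NEVER_MISSING = ("sex", "age_at_operation", "bmi_class")

#: Patient-record columns eligible for missingness injection.
_MISSABLE = (
    "education", "msk_condition", "comorbidity_count", "treated_anxiety",
    "treated_depression", "current_smoker", "steroid_injection",
    "surgeon_experienced", "pain_function_raw", "satisfaction_5level",
)


@dataclass
class CohortSpec:
    """Generative description of one registry-like cohort.

    ``true_coefficients`` is the logistic equation (on the coded scale:
    man/anxiety/smoker/steroid indicators, raw age in years, standardised
    score) from which the outcome is drawn.
    """

    name: str
    n: int
    marginals: dict          # keys as in published.COAST_MARGINALS
    comorbidity_probs: list  # P(count = 0,1,2,3plus)
    age_mean: float
    age_sd: float
    age_range: tuple
    score_mean: float
    score_sd: float
    score_range: tuple
    true_coefficients: dict
    missingness_rates: dict = field(default_factory=dict)
    hospitals: dict = field(default_factory=lambda: {"H1": 1.0})
    cohort_label: str = "development"
    copula_corr: float | None = None  # optional latent correlation, default off

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("cohort size n must be >= 1")
        for k, p in self.marginals.items():
            if not 0 <= p <= 1:
                raise ParameterError(f"marginal prevalence {k}={p} outside [0,1]")
        if abs(sum(self.comorbidity_probs) - 1) > 1e-9:
            raise ParameterError("comorbidity_probs must sum to 1")
        if self.age_sd <= 0 or self.score_sd <= 0:
            raise ParameterError("age_sd and score_sd must be positive")
        _validate_rates(self.missingness_rates)


def _validate_rates(rates: dict) -> None:
    for k, r in rates.items():
        if not 0 <= r <= 1:
            raise ParameterError(f"missingness rate {k}={r} outside [0,1]")
        if k in NEVER_MISSING or k == "bmi_class":
            if r > 0:
                raise ParameterError(f"{k} is always observed; rate must be 0")


def coast_spec(n: int = 450, **overrides) -> CohortSpec:
    """COASt-like development cohort at the published case mix."""
    kw = dict(
        name="COASt",
        n=n,
        marginals=dict(published.COAST_MARGINALS),
        comorbidity_probs=list(published.COAST_COMORBIDITY_PROBS),
        age_mean=published.COAST_AGE["mean"], age_sd=published.COAST_AGE["sd"],
        age_range=(published.COAST_AGE["min"], published.COAST_AGE["max"]),
        score_mean=published.COAST_SCORE["mean"], score_sd=published.COAST_SCORE["sd"],
        score_range=(published.COAST_SCORE["min"], published.COAST_SCORE["max"]),
        true_coefficients=dict(published.DEVELOPMENT_COEF),
        missingness_rates=dict(published.COAST_MISSINGNESS),
        hospitals=dict(published.COAST_HOSPITALS),
        cohort_label="development",
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def gar_spec(n: int = 791, **overrides) -> CohortSpec:
    """GAR-like external cohort at the published case mix."""
    kw = dict(
        name="GAR",
        n=n,
        marginals=dict(published.GAR_MARGINALS),
        comorbidity_probs=list(published.GAR_COMORBIDITY_PROBS),
        age_mean=published.GAR_AGE["mean"], age_sd=published.GAR_AGE["sd"],
        age_range=(published.GAR_AGE["min"], published.GAR_AGE["max"]),
        score_mean=published.GAR_SCORE["mean"], score_sd=published.GAR_SCORE["sd"],
        score_range=(published.GAR_SCORE["min"], published.GAR_SCORE["max"]),
        true_coefficients=dict(published.GENEVA_COEF),
        missingness_rates=dict(published.GAR_MISSINGNESS),
        hospitals=dict(published.GAR_HOSPITALS),
        cohort_label="external",
    )
    kw.update(overrides)
    return CohortSpec(**kw)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _bernoulli_columns(rng, spec: CohortSpec, n: int) -> dict:
    """Draw all binary marginals; independent unless a copula correlation is set."""
    names = ["women", "education_higher", "bmi_ge35", "condition_RA", "anxiety",
             "depression", "smoker", "steroid", "surgeon_experienced"]
    if spec.copula_corr:
        k = len(names)
        cov = np.full((k, k), spec.copula_corr) + np.eye(k) * (1 - spec.copula_corr)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n)
        u = stats.norm.cdf(z)
        return {nm: (u[:, j] < spec.marginals[nm]).astype(int) for j, nm in enumerate(names)}
    return {nm: (rng.random(n) < spec.marginals[nm]).astype(int) for nm in names}


def generate_cohort(spec: CohortSpec, seed=None, rng=None) -> pd.DataFrame:
    """Generate a complete analysable cohort in the patient-record schema.

    The outcome is Bernoulli with probability from the inverse-logit of
    the spec's true coefficients applied to the coded row; the
    standardised score uses the generated cohort's own sample mean/sd,
    matching how the analysis standardises.  The drawn binary outcome is
    expressed as a five-level satisfaction answer (split between the
    levels on each side) so downstream dichotomisation is exercised.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n = spec.n
    b = _bernoulli_columns(rng, spec, n)
    age = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, size=n)
    score = _truncnorm(rng, spec.score_mean, spec.score_sd, *spec.score_range, size=n)
    comorb = rng.choice(np.array(["0", "1", "2", "3plus"]), size=n,
                        p=np.asarray(spec.comorbidity_probs) / sum(spec.comorbidity_probs))
    hosp_names = list(spec.hospitals)
    hosp_p = np.asarray([spec.hospitals[h] for h in hosp_names], dtype=float)
    hospital = rng.choice(hosp_names, size=n, p=hosp_p / hosp_p.sum())

    df = pd.DataFrame({
        "id": [f"{spec.name}-{i:06d}" for i in range(n)],
        "sex": np.where(b["women"] == 1, "woman", "man"),
        "age_at_operation": age,
        "education": np.where(b["education_higher"] == 1, "higher", "lower"),
        "bmi_class": np.where(b["bmi_ge35"] == 1, "ge35", "lt35"),
        "msk_condition": np.where(b["condition_RA"] == 1, "RA_other", "OA"),
        "comorbidity_count": comorb,
        "treated_anxiety": b["anxiety"].astype(float),
        "treated_depression": b["depression"].astype(float),
        "current_smoker": b["smoker"].astype(float),
        "steroid_injection": b["steroid"].astype(float),
        "surgeon_experienced": b["surgeon_experienced"].astype(float),
        "pain_function_raw": score,
        "satisfaction_5level": "very_satisfied",  # placeholder, set below
        "hospital": hospital,
        "cohort": spec.cohort_label,
    })

    std = (score - score.mean()) / score.std(ddof=1)
    coef = spec.true_coefficients
    lp = (coef["intercept"]
          + coef["man"] * (1 - b["women"])
          + coef["age"] * age
          + coef["anxiety"] * b["anxiety"]
          + coef["smoker"] * b["smoker"]
          + coef["steroid"] * b["steroid"]
          + coef["std_score"] * std)
    nonsat = rng.random(n) < expit(lp)

    # express the binary outcome as 5-level answers; dichotomisation recovers it
    sat_levels = rng.choice(np.array(["very_satisfied", "somewhat_satisfied"]),
                            size=n, p=[0.65, 0.35])
    nonsat_levels = rng.choice(
        np.array(["neither", "somewhat_dissatisfied", "very_dissatisfied"]),
        size=n, p=[0.5, 0.3, 0.2])
    df["satisfaction_5level"] = np.where(nonsat, nonsat_levels, sat_levels)
    return df


def generate_raw_cohort(spec: CohortSpec, cascade: dict, seed=None) -> pd.DataFrame:
    """Generate a raw registry extract whose exclusion cascade is exact.

    The analysable core (follow-up completers with a satisfaction answer)
    comes from :func:`generate_cohort`; around it the extract adds, with
    exact counts from ``cascade``: non-primary operations, primary
    patients with a masking diagnosis, follow-up non-completers, and
    completers who did not answer the satisfaction question.  Row order is
    shuffled.  ``cascade`` has the shape of
    :data:`tkrsat.published.COAST_CASCADE`.
    """
    rng = np.random.default_rng(seed)
    ops = cascade["operation_counts"]
    n_primary = ops["primary_tkr"]
    n_masking = cascade["n_masking"]
    n_completers = cascade["n_followup_completers"]
    n_sat_missing = cascade["n_satisfaction_missing"]
    n_analysed = n_completers - n_sat_missing
    n_noncompleters = n_primary - n_masking - n_completers
    if min(n_analysed, n_noncompleters) < 0:
        raise ParameterError("cascade counts are inconsistent")
    if spec.n != n_analysed:
        spec = CohortSpec(**{**spec.__dict__, "n": n_analysed})

    def _blank_records(n, op):
        filler = generate_cohort(
            CohortSpec(**{**spec.__dict__, "n": max(n, 1)}), rng=rng).head(n)
        filler = filler.assign(operation_type=op, followup_returned=0.0)
        return filler

    parts = []
    core = generate_cohort(spec, rng=rng)
    core["operation_type"] = "primary_tkr"
    core["followup_returned"] = 1.0

    missing_sat = _blank_records(n_sat_missing, "primary_tkr")
    missing_sat["followup_returned"] = 1.0
    missing_sat["satisfaction_5level"] = np.nan

    noncompleters = _blank_records(n_noncompleters, "primary_tkr")
    noncompleters["satisfaction_5level"] = np.nan

    masked = _blank_records(n_masking, "primary_tkr")
    masked["followup_returned"] = rng.integers(0, 2, size=n_masking).astype(float)
    dx = rng.choice(
        [f"dx_{c}" for c in ("sciatica", "stroke", "fibromyalgia", "avascular_necrosis")],
        size=n_masking)
    parts = [core, missing_sat, noncompleters, masked]
    for op, cnt in ops.items():
        if op == "primary_tkr":
            continue
        parts.append(_blank_records(cnt, op))

    raw = pd.concat(parts, ignore_index=True)
    for c in ("dx_sciatica", "dx_stroke", "dx_fibromyalgia", "dx_avascular_necrosis"):
        raw[c] = 0.0
    mask_rows = raw.index[len(core) + len(missing_sat) + len(noncompleters):
                          len(core) + len(missing_sat) + len(noncompleters) + n_masking]
    for i, col in zip(mask_rows, dx):
        raw.loc[i, col] = 1.0
    raw["id"] = [f"{spec.name}-raw-{i:06d}" for i in range(len(raw))]
    return raw.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Missingness injection

def inject_missingness(table: pd.DataFrame, rates: dict, mechanism: str = "MCAR",
                       seed=None) -> pd.DataFrame:
    """Blank cells of a complete patient-record table.

    MCAR blanks each eligible cell independently at its variable's rate.
    MAR_on_age_sex blanks with probability ``expit(a + 0.8 z_age + 0.5 man)``
    where ``z_age`` is the within-table standardised age and the intercept
    ``a`` is solved so the marginal missing fraction equals the requested
    rate; the mechanism depends only on always-observed variables, so the
    imputation model's assumptions hold by construction.  Sex, age and BMI
    can never be blanked.
    """
    if mechanism not in {"MCAR", "MAR_on_age_sex"}:
        raise ParameterError(f"unknown mechanism {mechanism!r}")
    _validate_rates(rates)
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    if mechanism == "MAR_on_age_sex":
        z_age = (out["age_at_operation"] - out["age_at_operation"].mean()) \
            / out["age_at_operation"].std(ddof=1)
        man = (out["sex"] == "man").astype(float).to_numpy()
        eta = 0.8 * z_age.to_numpy() + 0.5 * man

    for col, rate in rates.items():
        if col not in out.columns or rate == 0:
            continue
        if col not in _MISSABLE:
            raise ParameterError(f"column {col!r} is not eligible for missingness")
        if mechanism == "MCAR":
            blank = rng.random(n) < rate
        else:
            def marginal(a):
                return expit(a + eta).mean() - rate
            a = optimize.brentq(marginal, -30, 30)
            blank = rng.random(n) < expit(a + eta)
        if out[col].dtype == object or str(out[col].dtype) == "string":
            out.loc[blank, col] = np.nan
        else:
            out[col] = out[col].astype(float)
            out.loc[blank, col] = np.nan
    return out
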