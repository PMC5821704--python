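"""Descriptive case-mix comparison between two cohorts.

Categorical variables are compared with the chi-squared test (no
continuity correction by default), continuous ones with Welch's
unequal-variance t-test.  Percentages use the non-missing denominator
(the "86/377" convention) and round half-up to one decimal, as clinical
tables do.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OUTCOME

#: Default comparison variables on the coded schema: name -> kind.
DEFAULT_VARIABLES = {
    OUTCOME: "binary",
    "man": "binary",
    "age": "continuous",
    "education_higher": "binary",
    "bmi_ge35": "binary",
    "condition_OA": "binary",
    "comorbidity": "categorical",
    "smoker": "binary",
    "anxiety": "binary",
    "depression": "binary",
    "steroid": "binary",
    "surgeon_experienced": "binary",
    "std_score": "continuous",
}


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up, the convention of printed clinical tables."""
    if denominator == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(100 * numerator / denominator)).quantize(
        q, rounding=ROUND_HALF_UP))


@dataclass
class ComparisonRow:
    variable: str
    summary_a: str
    summary_b: str
    test: str
    statistic: float
    p_value: float
    note: str = ""


def _chi2(table: np.ndarray):
    """Uncorrected chi-squared on a 2 x k count table; flags degenerate tables."""
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan, "chi-square undefined (empty category)"
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    note = "" if (expected > 0).all() else "expected count of zero"
    return float(chi2), float(p), note


def compare_cohorts(a: pd.DataFrame, b: pd.DataFrame,
                    variables: dict | None = None,
                    correction: bool = False) -> pd.DataFrame:
    """Case-mix comparison table between cohorts ``a`` and ``b``.

    ``variables`` maps coded column name to kind (binary, categorical,
    continuous); defaults to :data:`DEFAULT_VARIABLES` restricted to the
    shared columns.  Denominators exclude missing values.  Returns one
    row per variable with formatted summaries, the test used, its
    statistic and p-value; degenerate chi-squared tables are flagged in
    ``note`` rather than raising.
    """
    if variables is None:
        variables = {k: v for k, v in DEFAULT_VARIABLES.items()
                     if k in a.columns and k in b.columns}
    rows = []
    for var, kind in variables.items():
        xa, xb = a[var].dropna(), b[var].dropna()
        if kind == "continuous":
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(ComparisonRow(
                var,
                f"{xa.mean():.1f} ± {xa.std(ddof=1):.1f}",
                f"{xb.mean():.1f} ± {xb.std(ddof=1):.1f}",
                "welch_t", float(t), float(p)))
            continue
        if kind == "binary":
            ca = np.array([(xa == 0).sum(), (xa == 1).sum()])
            cb = np.array([(xb == 0).sum(), (xb == 1).sum()])
            summary_a = f"{ca[1]}/{len(xa)} ({percent(ca[1], len(xa))})"
            summary_b = f"{cb[1]}/{len(xb)} ({percent(cb[1], len(xb))})"
        else:
            levels = sorted(set(xa.unique()) | set(xb.unique()))
            ca = np.array([(xa == l).sum() for l in levels])
            cb = np.array([(xb == l).sum() for l in levels])
            summary_a = "/".join(str(c) for c in ca)
            summary_b = "/".join(str(c) for c in cb)
        if correction and len(ca) == 2:
            tab = np.vstack([ca, cb])
            if (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
                chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
                rows.append(ComparisonRow(var, summary_a, summary_b,
                                          "chi_square_corrected", float(chi2), float(p)))
                continue
        chi2, p, note = _chi2(np.vstack([ca, cb]))
        rows.append(ComparisonRow(var, summary_a, summary_b, "chi_square",
                                  chi2, p, note))
    return pd.DataFrame([r.__dict__ for r in rows])


def outcome_prevalence(df: pd.DataFrame, outcome: str = OUTCOME):
    """(events, n, percent) of non-satisfaction among analysable patients."""
    obs = df[outcome].dropna()
    events = int(obs.sum())
    return events, len(obs), percent(events, len(obs))


def event_rates(df: pd.DataFrame, variable: str, outcome: str = OUTCOME) -> pd.DataFrame:
    """Non-satisfaction events per category of one coded predictor."""
    sub = df[[variable, outcome]].dropna()
    rows = []
    for level, g in sub.groupby(variable):
        events = int(g[outcome].sum())
        rows.append({"variable": variable, "level": level, "n": len(g),
                     "events": events, "rate_percent": percent(events, len(g))})
    return pd.DataFrame(rows)
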