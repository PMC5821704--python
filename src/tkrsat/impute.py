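"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing predictor values are filled by cycling per-variable regression
models over the coded table: binary indicators by Bayesian logistic
draws (coefficients drawn from the approximate normal posterior, values
drawn Bernoulli), the continuous standardised score by Bayesian linear
draws with a scaled-inverse-chi-squared variance, and the ordinal
comorbidity count by a linear draw rounded and clipped to 0-3.  The
outcome always enters every imputation model, and an auxiliary variable
(hospital) can be added.  Each of the m chains starts from a random fill
of observed values and runs a fixed number of cycles (default 10), with
variables visited in order of increasing missingness.

Per-imputation model fits are combined with Rubin's rules: pooled
coefficient = mean; pooled variance = mean within-imputation variance
plus (1 + 1/m) times the between-imputation coefficient variance, with
the classical per-coefficient degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CANDIDATE_PREDICTORS, OUTCOME
from .errors import ImputationError, ParameterError, PoolingError
from .validate import ModelFit

#: Coded columns that may contain missing values, with their model family.
IMPUTABLE = {
    "education_higher": "logistic",
    "condition_OA": "logistic",
    "comorbidity": "ordinal",
    "anxiety": "logistic",
    "depression": "logistic",
    "smoker": "logistic",
    "steroid": "logistic",
    "surgeon_experienced": "logistic",
    "std_score": "linear",
}

_ALWAYS_COMPLETE = ("man", "age", "bmi_ge35")


@dataclass
class ImputedStack:
    """m completed copies of one coded cohort, sharing ids and observed cells."""

    datasets: list
    seed: object = None
    auxiliary: tuple = ()

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def to_long(self) -> pd.DataFrame:
        """Stack the m datasets with a 1-based imputation-index column."""
        parts = []
        for i, d in enumerate(self.datasets, start=1):
            part = d.copy()
            part.insert(0, "imputation", i)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_long(cls, long_df: pd.DataFrame) -> "ImputedStack":
        datasets = [g.drop(columns="imputation").reset_index(drop=True)
                    for _, g in long_df.groupby("imputation", sort=True)]
        return cls(datasets=datasets)


def _design(df: pd.DataFrame, cols: list) -> np.ndarray:
    X = df[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def _draw_mvn(rng, mean, cov):
    # guard tiny asymmetries from finite-precision covariance
    cov = (cov + cov.T) / 2
    try:
        return rng.multivariate_normal(mean, cov, method="cholesky")
    except np.linalg.LinAlgError:
        return rng.multivariate_normal(mean, cov, method="svd")


def _impute_logistic(rng, y_obs, X_obs, X_mis):
    from scipy.special import expit
    try:
        with np.errstate(over="ignore"):
            res = sm.GLM(y_obs, X_obs, family=sm.families.Binomial()).fit()
            beta = _draw_mvn(rng, np.asarray(res.params), np.asarray(res.cov_params()))
            p = expit(X_mis @ beta)
    except Exception:
        p = np.full(len(X_mis), y_obs.mean())  # fallback: marginal draw
    return (rng.random(len(X_mis)) < p).astype(float)


def _impute_linear(rng, y_obs, X_obs, X_mis):
    n, k = X_obs.shape
    beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - k, 1)
    sigma2_hat = float(resid @ resid) / dof
    sigma2 = sigma2_hat * dof / rng.chisquare(dof)
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    beta = _draw_mvn(rng, beta_hat, sigma2 * xtx_inv)
    return X_mis @ beta + rng.normal(0, np.sqrt(sigma2), size=len(X_mis))


def impute(coded: pd.DataFrame, m: int = 50, seed=None, n_cycles: int = 10,
           auxiliary: tuple = ("hospital",), outcome: str = OUTCOME) -> ImputedStack:
    """Chained-equation multiple imputation of a coded cohort table.

    Requires sex, age and BMI complete; the outcome is included as a
    predictor in every imputation model (it is part of the observed data
    and omitting it would bias associations towards zero).  Returns an
    :class:`ImputedStack` of ``m`` independently-seeded chains.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    for col in _ALWAYS_COMPLETE + (outcome,):
        if coded[col].isna().any():
            raise ImputationError(f"{col} must be complete before imputation")

    targets = [c for c in IMPUTABLE if c in coded.columns and coded[c].isna().any()]
    for c in targets:
        if coded[c].isna().all():
            raise ImputationError(f"variable {c!r} is 100% missing; cannot impute")
    # visit order: least missing first
    targets.sort(key=lambda c: coded[c].isna().sum())

    aux_cols = []
    work_base = coded.copy()
    for a in auxiliary:
        if a in coded.columns and coded[a].notna().all() and coded[a].nunique() > 1:
            dummies = pd.get_dummies(coded[a].astype(str), prefix=f"aux_{a}",
                                     drop_first=True, dtype=float)
            for c in dummies.columns:
                work_base[c] = dummies[c]
                aux_cols.append(c)

    model_vars = [c for c in CANDIDATE_PREDICTORS if c in coded.columns]
    master = np.random.default_rng(seed)
    chain_seeds = master.integers(2**31, size=m)

    datasets = []
    for s in chain_seeds:
        rng = np.random.default_rng(int(s))
        work = work_base.copy()
        # initial fill: random draw from the observed values
        for c in targets:
            miss = work[c].isna()
            obs_vals = work.loc[~miss, c].to_numpy(dtype=float)
            work.loc[miss, c] = rng.choice(obs_vals, size=int(miss.sum()))
        if targets:
            for _ in range(n_cycles):
                for c in targets:
                    miss = coded[c].isna()
                    preds = [v for v in model_vars if v != c] + [outcome] + aux_cols
                    X_obs = _design(work.loc[~miss], preds)
                    X_mis = _design(work.loc[miss], preds)
                    y_obs = work.loc[~miss, c].to_numpy(dtype=float)
                    kind = IMPUTABLE[c]
                    if kind == "logistic":
                        vals = _impute_logistic(rng, y_obs, X_obs, X_mis)
                    else:
                        vals = _impute_linear(rng, y_obs, X_obs, X_mis)
                        if kind == "ordinal":
                            vals = np.clip(np.round(vals), 0, 3)
                    work.loc[miss, c] = vals
        done = work.drop(columns=aux_cols)
        # back-transform the imputed standardised score onto the raw scale
        if "pain_function_raw" in done.columns and "std_score" in done.columns:
            raw_miss = done["pain_function_raw"].isna()
            if raw_miss.any():
                mean = coded.attrs.get("score_mean",
                                       float(coded["pain_function_raw"].mean()))
                sd = coded.attrs.get("score_sd",
                                     float(coded["pain_function_raw"].std(ddof=1)))
                done.loc[raw_miss, "pain_function_raw"] = \
                    done.loc[raw_miss, "std_score"] * sd + mean
        # keep comorbidity dummies consistent with the imputed ordinal
        if "comorbidity" in done.columns and "comorb_1" in done.columns:
            for lvl, col in ((1, "comorb_1"), (2, "comorb_2"), (3, "comorb_3plus")):
                done[col] = (done["comorbidity"] == lvl).astype(float)
        datasets.append(done.reset_index(drop=True))
    return ImputedStack(datasets=datasets, seed=seed, auxiliary=tuple(auxiliary))


# ---------------------------------------------------------------------------
# Rubin's rules


def rubin_pool(fits: list) -> ModelFit:
    """Pool per-imputation logistic fits with Rubin's rules.

    Pooled coefficients are the mean of the per-imputation coefficients;
    the pooled covariance is W + (1 + 1/m) B where W is the mean
    within-imputation covariance and B the between-imputation covariance
    of the coefficient vectors.  Per-coefficient degrees of freedom use
    the classical formula (m-1)(1 + W_jj / ((1+1/m) B_jj))^2, infinite
    when the between-variance vanishes.
    """
    if not fits:
        raise PoolingError("no fits to pool")
    ref = fits[0]
    for f in fits[1:]:
        if list(f.predictors) != list(ref.predictors):
            raise PoolingError(
                f"mismatched predictor lists: {f.predictors} vs {ref.predictors}")
    m = len(fits)
    names = ref.names
    Q = np.stack([f.coefficients.reindex(names).to_numpy() for f in fits])
    W = np.mean([f.cov.reindex(index=names, columns=names).to_numpy()
                 for f in fits], axis=0)
    qbar = Q.mean(axis=0)
    if m == 1:
        B = np.zeros_like(W)
    else:
        dev = Q - qbar
        B = dev.T @ dev / (m - 1)
    T = W + (1 + 1 / m) * B
    b_diag = np.diag(B)
    w_diag = np.diag(W)
    with np.errstate(divide="ignore"):
        r = (1 + 1 / m) * b_diag / w_diag
        df = np.where(b_diag > 0, (m - 1) * (1 + 1 / np.where(r > 0, r, np.inf)) ** 2,
                      np.inf)
    return ModelFit(
        predictors=list(ref.predictors),
        coefficients=pd.Series(qbar, index=names),
        cov=pd.DataFrame(T, index=names, columns=names),
        n=ref.n,
        converged=all(f.converged for f in fits),
        df=pd.Series(df, index=names),
        m=m,
    )
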