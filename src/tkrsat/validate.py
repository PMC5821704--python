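"""Logistic model fitting, discrimination, calibration and internal validation.

The model is ordinary maximum-likelihood logistic regression.  Discrimination
is the area under the ROC curve computed as the Mann-Whitney concordance
(midrank) estimator; tied predictions count 0.5 per case-control pair.
Internal validation follows the bootstrap optimism procedure: refit (and,
by default, re-select) the model on B bootstrap resamples, measure how much
better each bootstrap model does on its own sample than on the original,
average that excess as the optimism, and subtract it from the apparent AUC.
Calibration splits patients into deciles of predicted risk and compares the
mean predicted probability with the observed event proportion, with 95%
Agresti-Coull intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)
from scipy import stats
from scipy.special import expit

from .cohort import OUTCOME
from .errors import (
    FitError,
    ParameterError,
    PredictionError,
    SeparationError,
    UndefinedAUCError,
    ValidationRunError,
)

# ---------------------------------------------------------------------------
# Model container


@dataclass
class ModelFit:
    """A fitted (or pooled) logistic model.

    ``coefficients`` is indexed by ``['intercept'] + predictors``; ``cov``
    is the matching covariance.  ``df`` carries per-coefficient degrees of
    freedom (infinite for a single maximum-likelihood fit; finite after
    Rubin pooling).
    """

    predictors: list
    coefficients: pd.Series
    cov: pd.DataFrame
    n: int
    converged: bool = True
    df: pd.Series | None = None
    m: int = 1  # imputations pooled into this fit

    @property
    def names(self):
        return list(self.coefficients.index)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.names)

    def _dof(self) -> pd.Series:
        if self.df is None:
            return pd.Series(np.inf, index=self.names)
        return self.df

    @property
    def pvalues(self) -> pd.Series:
        t = self.coefficients / self.se
        return pd.Series(2 * stats.t.sf(np.abs(t), self._dof()), index=self.names)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        q = stats.t.ppf(0.5 + level / 2, self._dof())
        lo = self.coefficients - q * self.se
        hi = self.coefficients + q * self.se
        return pd.DataFrame({"low": lo, "high": hi})

    def summary(self) -> pd.DataFrame:
        """Coefficient table with SE, 95% CI, odds ratios and p-values."""
        ci = self.conf_int()
        return pd.DataFrame({
            "coefficient": self.coefficients,
            "se": self.se,
            "ci_low": ci["low"],
            "ci_high": ci["high"],
            "odds_ratio": np.exp(self.coefficients),
            "or_low": np.exp(ci["low"]),
            "or_high": np.exp(ci["high"]),
            "p_value": self.pvalues,
        })

    def to_json(self, path=None):
        payload = {
            "predictors": self.predictors,
            "coefficients": self.coefficients.to_dict(),
            "cov": self.cov.to_dict(),
            "n": int(self.n),
            "converged": bool(self.converged),
            "df": None if self.df is None else self.df.to_dict(),
            "m": int(self.m),
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, source):
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        names = ["intercept"] + payload["predictors"]
        coef = pd.Series(payload["coefficients"]).reindex(names)
        cov = pd.DataFrame(payload["cov"]).reindex(index=names, columns=names)
        df = payload.get("df")
        return cls(
            predictors=payload["predictors"], coefficients=coef, cov=cov,
            n=payload["n"], converged=payload["converged"],
            df=None if df is None else pd.Series(df).reindex(names),
            m=payload.get("m", 1),
        )


# ---------------------------------------------------------------------------
# Fitting


def _find_separating(X: pd.DataFrame, y: np.ndarray):
    """Name a predictor that perfectly separates the outcome, if any."""
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if len(np.unique(v)) <= 1:
            continue
        lo = y[v <= np.median(v)]
        hi = y[v > np.median(v)]
        if len(lo) and len(hi) and lo.max() < hi.min() or \
           len(lo) and len(hi) and hi.max() < lo.min():
            return col
        if set(np.unique(v)) <= {0.0, 1.0}:
            if y[v == 1].size and len(set(y[v == 1])) == 1 and \
               y[v == 0].size and len(set(y[v == 0])) == 1 and \
               y[v == 1][0] != y[v == 0][0]:
                return col
    return None


def fit_logistic(data: pd.DataFrame, predictors: list, outcome: str = OUTCOME,
                 tol: float = 1e-8, maxiter: int = 200) -> ModelFit:
    """Maximum-likelihood logistic fit of ``outcome`` on ``predictors``.

    Iteratively reweighted least squares with convergence tolerance
    ``tol``; covariance from the observed information.  Degenerate
    (constant or collinear) columns get minimum-norm coefficients with
    very large standard errors rather than a hard failure, which lets
    backward elimination discard them.
    Raises :class:`FitError` for a one-class outcome or missing values and
    :class:`SeparationError` (naming the offending predictor when it can
    be identified) when separation prevents convergence.
    """
    missing = [p for p in predictors if p not in data.columns]
    if missing:
        raise FitError(f"predictors absent from data: {missing}")
    X = data[list(predictors)].astype(float)
    y = data[outcome].to_numpy(dtype=float)
    if np.isnan(y).any() or X.isna().any().any():
        raise FitError("fitting data contain missing values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError(f"outcome has a single class ({classes.tolist()})")

    design = sm.add_constant(X, prepend=True, has_constant="add")
    names = ["intercept"] + list(predictors)
    design.columns = names
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                tol=tol, maxiter=maxiter)
    except (np.linalg.LinAlgError, PerfectSeparationError,
            PerfectSeparationWarning, ValueError) as e:
        culprit = _find_separating(X, y)
        raise SeparationError(
            f"logistic fit failed ({e}); separating predictor: {culprit or 'unidentified'}"
        ) from e
    converged = bool(getattr(res, "converged", True))
    params = np.asarray(res.params, dtype=float)
    if not converged or not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        culprit = _find_separating(X, y)
        raise SeparationError(
            "logistic fit did not converge"
            + (f"; separating predictor: {culprit}" if culprit else ""))
    coef = pd.Series(params, index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return ModelFit(predictors=list(predictors), coefficients=coef, cov=cov,
                    n=len(y), converged=converged)


def predict_probability(fit: ModelFit, rows):
    """Predicted non-satisfaction probability, ``expit`` of the linear predictor.

    ``rows`` may be a DataFrame or a single Series/mapping. Any missing
    predictor (column or value) raises :class:`PredictionError` — no
    silent imputation.
    """
    single = not isinstance(rows, pd.DataFrame)
    df = pd.DataFrame([rows]) if single else rows
    missing = [p for p in fit.predictors if p not in df.columns]
    if missing:
        raise PredictionError(f"rows lack predictor(s): {missing}")
    X = df[fit.predictors].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise PredictionError(f"missing value(s) in predictor(s): {bad}")
    lp = fit.coefficients["intercept"] + X.to_numpy() @ \
        fit.coefficients[fit.predictors].to_numpy()
    p = expit(lp)
    return float(p[0]) if single else np.asarray(p)


# ---------------------------------------------------------------------------
# Discrimination


def auc(probabilities, outcomes) -> float:
    """Mann-Whitney concordance AUC with midrank handling of ties."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ParameterError("probabilities and outcomes must be equal-length 1-D")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("both outcome classes required for AUC")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Calibration


def agresti_coull_interval(x: int, n: int, z: float = 1.96):
    """95% (for z=1.96) Agresti-Coull interval for x successes in n trials."""
    if n <= 0:
        raise ParameterError("n must be positive")
    n_t = n + z ** 2
    p_t = (x + z ** 2 / 2) / n_t
    half = z * np.sqrt(p_t * (1 - p_t) / n_t)
    return max(0.0, p_t - half), min(1.0, p_t + half)


def _decile_bins(p: np.ndarray, bins: int) -> np.ndarray:
    """Assign near-equal rank bins; ties share a bin, remainder fills low bins."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    base, rem = divmod(n, bins)
    sizes = np.array([base + (1 if i < rem else 0) for i in range(bins)])
    raw_bin = np.repeat(np.arange(bins), sizes)
    sorted_p = p[order]
    for i in range(1, n):  # keep tied predictions together (earlier bin wins)
        if sorted_p[i] == sorted_p[i - 1]:
            raw_bin[i] = raw_bin[i - 1]
    out = np.empty(n, dtype=int)
    out[order] = raw_bin
    return out


def calibration_table(probabilities, outcomes, bins: int = 10,
                      z: float = 1.96) -> pd.DataFrame:
    """Observed vs mean predicted risk per decile with Agresti-Coull intervals.

    Patients are ranked by predicted probability and split into ``bins``
    near-equal groups (sizes differing by at most one; any remainder is
    spread from the lowest bin; tied predictions stay in one bin, so with
    heavy ties bins can deviate from n/10 and empty bins are dropped).
    """
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < bins:
        raise ParameterError("need at least one patient per bin")
    b = _decile_bins(p, bins)
    rows = []
    for k in range(bins):
        sel = b == k
        nk = int(sel.sum())
        if nk == 0:
            continue
        x = int(y[sel].sum())
        lo, hi = agresti_coull_interval(x, nk, z)
        rows.append({"bin": k + 1, "n": nk, "mean_predicted": float(p[sel].mean()),
                     "events": x, "observed": x / nk, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Internal validation


@dataclass
class ValidationReport:
    """Apparent and optimism-corrected discrimination plus calibration."""

    auc_apparent: float
    optimism: float
    auc_corrected: float
    calibration: pd.DataFrame
    B: int
    seed: object = None
    auc_per_imputation: list = field(default_factory=list)
    auc_median: float = float("nan")
    n_failed_replicates: int = 0

    def to_dict(self):
        return {
            "auc_apparent": self.auc_apparent,
            "optimism": self.optimism,
            "auc_corrected": self.auc_corrected,
            "auc_median": self.auc_median,
            "B": self.B,
            "n_failed_replicates": self.n_failed_replicates,
            "calibration": self.calibration.to_dict(orient="records"),
        }


def _as_datasets(data) -> list:
    """Accept an ImputedStack or a single completed DataFrame."""
    if hasattr(data, "datasets"):
        return list(data.datasets)
    return [data]


def apparent_performance(data, predictors, outcome: str = OUTCOME, bins: int = 10):
    """Pooled fit, per-imputation AUCs and calibration on the original data.

    Per-imputation models are pooled by Rubin's rules; the pooled model is
    then applied to every completed dataset.  The apparent AUC is the mean
    over imputations (the median is reported alongside); calibration uses
    each patient's predicted probability averaged over imputations.
    """
    from .impute import rubin_pool  # local import to avoid a cycle

    datasets = _as_datasets(data)
    fits = [fit_logistic(d, predictors, outcome) for d in datasets]
    pooled = rubin_pool(fits)
    aucs, probs = [], []
    for d in datasets:
        p = predict_probability(pooled, d)
        probs.append(p)
        aucs.append(auc(p, d[outcome]))
    mean_p = np.mean(probs, axis=0)
    cal = calibration_table(mean_p, datasets[0][outcome], bins=bins)
    return pooled, aucs, cal, mean_p


def optimism_corrected_auc(data, predictors, B: int = 200, seed=None, rng=None,
                           candidates=None, alpha: float = 0.157,
                           forced=("man", "age"), outcome: str = OUTCOME,
                           bins: int = 10, max_failed: float = 0.10) -> ValidationReport:
    """Bootstrap optimism-corrected AUC (with calibration) for a chosen model.

    Each replicate resamples patients with replacement (replicate size =
    original n), taking values from one completed dataset chosen uniformly
    at random when ``data`` is an imputed stack.  When ``candidates`` is
    given, the selection procedure (backward elimination at ``alpha`` with
    ``forced`` covariates) is repeated inside every replicate so the
    optimism estimate charges for selection; otherwise the fixed
    ``predictors`` are refit.  Replicates whose refit fails are dropped
    and counted; more than ``max_failed`` of B failing raises
    :class:`ValidationRunError`.

    The identity ``auc_corrected = auc_apparent - optimism`` holds exactly.
    """
    from .select import backward_eliminate  # local import to avoid a cycle

    if B < 1:
        raise ParameterError("B must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    datasets = _as_datasets(data)
    n = len(datasets[0])

    pooled, aucs, cal, _ = apparent_performance(data, predictors, outcome, bins)
    auc_apparent = float(np.mean(aucs))

    optimisms = []
    failed = 0
    for _ in range(B):
        d = datasets[int(rng.integers(len(datasets)))]
        idx = rng.integers(n, size=n)
        boot = d.iloc[idx]
        try:
            if candidates is not None:
                sel = backward_eliminate(boot, candidates, alpha=alpha,
                                         forced=forced, outcome=outcome)
            else:
                sel = list(predictors)
            bfit = fit_logistic(boot, sel, outcome)
            a_boot = auc(predict_probability(bfit, boot), boot[outcome])
            a_orig = auc(predict_probability(bfit, d), d[outcome])
        except (FitError, UndefinedAUCError):
            failed += 1
            continue
        optimisms.append(a_boot - a_orig)
    if failed > max_failed * B:
        raise ValidationRunError(
            f"{failed}/{B} bootstrap replicates failed to converge")

    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return ValidationReport(
        auc_apparent=auc_apparent,
        optimism=optimism,
        auc_corrected=auc_apparent - optimism,
        calibration=cal,
        B=B,
        seed=seed,
        auc_per_imputation=[float(a) for a in aucs],
        auc_median=float(np.median(aucs)),
        n_failed_replicates=failed,
    )
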