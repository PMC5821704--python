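"""Cross-setting transport of a frozen model and re-estimation.

Transportability asks how a model developed in one health system performs
in another.  Two assessments mirror common practice: (1) apply the frozen
development coefficients unchanged to the external cohort (whose
pain/function score is standardised within that cohort) and measure
discrimination and calibration; (2) refit the same predictor list on the
external multiply-imputed data (no re-selection) and pool with Rubin's
rules, yielding setting-specific coefficients and their AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OUTCOME
from .errors import FitError, ReestimationError, TransportError
from .impute import rubin_pool
from .validate import (
    ModelFit,
    auc,
    calibration_table,
    fit_logistic,
    predict_probability,
)


def _as_datasets(data):
    return list(data.datasets) if hasattr(data, "datasets") else [data]


def transport_model(frozen: ModelFit, external, outcome: str = OUTCOME,
                    bins: int = 10):
    """Apply frozen coefficients to an external cohort; no refitting.

    Returns ``(auc_transported, calibration, mean_probabilities)``: the
    AUC averaged over the external imputed datasets and a decile
    calibration table built from each patient's probability averaged over
    imputations.  The frozen fit is never mutated.
    """
    datasets = _as_datasets(external)
    missing = [p for p in frozen.predictors if p not in datasets[0].columns]
    if missing:
        raise TransportError(f"external data lack predictor(s): {missing}")
    aucs, probs = [], []
    for d in datasets:
        p = predict_probability(frozen, d)
        probs.append(p)
        aucs.append(auc(p, d[outcome]))
    mean_p = np.mean(probs, axis=0)
    cal = calibration_table(mean_p, datasets[0][outcome], bins=bins)
    return float(np.mean(aucs)), cal, mean_p


def reestimate(external, predictors, outcome: str = OUTCOME,
               max_failed: float = 0.10) -> ModelFit:
    """Refit the frozen model's predictors on the external stack, Rubin-pooled.

    No re-selection: exactly the given predictor list is fit on each
    completed dataset.  More than ``max_failed`` non-convergent
    imputations raise :class:`ReestimationError`.
    """
    datasets = _as_datasets(external)
    fits, failed = [], 0
    for d in datasets:
        try:
            fits.append(fit_logistic(d, predictors, outcome))
        except FitError:
            failed += 1
    if not fits or failed > max_failed * len(datasets):
        raise ReestimationError(
            f"re-estimation failed on {failed}/{len(datasets)} imputations")
    return rubin_pool(fits)


@dataclass
class TransportReport:
    """Frozen-coefficient external performance plus the re-estimated fit."""

    frozen_fit: ModelFit
    auc_transported: float
    calibration_transported: pd.DataFrame
    reestimated_fit: ModelFit
    auc_reestimated: float

    def coefficient_table(self) -> pd.DataFrame:
        """Side-by-side development vs re-estimated coefficients."""
        dev = self.frozen_fit.summary()
        ext = self.reestimated_fit.summary()
        return pd.DataFrame({
            "development_coef": dev["coefficient"],
            "development_p": dev["p_value"],
            "reestimated_coef": ext["coefficient"],
            "reestimated_ci_low": ext["ci_low"],
            "reestimated_ci_high": ext["ci_high"],
            "reestimated_or": ext["odds_ratio"],
            "reestimated_p": ext["p_value"],
        })

    def to_dict(self):
        return {
            "auc_transported": self.auc_transported,
            "auc_reestimated": self.auc_reestimated,
            "calibration_transported":
                self.calibration_transported.to_dict(orient="records"),
            "reestimated_coefficients":
                self.reestimated_fit.coefficients.to_dict(),
        }


def assess_transport(frozen: ModelFit, external, outcome: str = OUTCOME,
                     bins: int = 10) -> TransportReport:
    """Full transport assessment: frozen application plus re-estimation."""
    auc_t, cal_t, _ = transport_model(frozen, external, outcome, bins)
    refit = reestimate(external, frozen.predictors, outcome)
    aucs = [auc(predict_probability(refit, d), d[outcome])
            for d in _as_datasets(external)]
    return TransportReport(
        frozen_fit=frozen,
        auc_transported=auc_t,
        calibration_transported=cal_t,
        reestimated_fit=refit,
        auc_reestimated=float(np.mean(aucs)),
    )
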