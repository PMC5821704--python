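"""Bootstrap inclusion-frequency predictor selection.

Candidate predictors are screened by backward elimination (drop the
non-forced predictor with the largest Wald p-value while it exceeds
alpha = 0.157, one at a time) run on B = 200 bootstrap replicates drawn
from the multiply-imputed development data; predictors retained in at
least 60% of replicates, plus the forced sex and age, form the final
model.  Forcing guarantees the two covariates of known clinical
relevance are present regardless of significance.

"Drawn with replacement from the combined imputed datasets" is read as
patient-level resampling: each replicate samples n patients with
replacement and takes their values from one completed dataset chosen
uniformly at random, so every replicate has the original sample size and
internally coherent patients.  A stacked-row mode (sampling n rows from
the m*n stacked table) is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CANDIDATE_PREDICTORS, FORCED_PREDICTORS, OUTCOME
from .errors import FitError, ParameterError
from .validate import fit_logistic


def backward_eliminate(data: pd.DataFrame, candidates=None, alpha: float = 0.157,
                       forced=FORCED_PREDICTORS, outcome: str = OUTCOME) -> list:
    """Backward elimination at Wald significance ``alpha`` on one dataset.

    Iteratively refits the logistic model and removes the non-forced
    predictor with the largest p-value while that p-value exceeds
    ``alpha``; forced predictors are never removed.  Ties on the largest
    p-value drop the candidate latest in the declared order
    (deterministic).  Returns the selected predictors in declared order.
    A non-convergent fit propagates as :class:`FitError` with the
    elimination step in its message.
    """
    candidates = list(CANDIDATE_PREDICTORS if candidates is None else candidates)
    forced = [f for f in forced]
    if not set(forced) <= set(candidates):
        raise ParameterError("forced predictors must be among the candidates")
    current = list(candidates)
    step = 0
    while True:
        step += 1
        try:
            fit = fit_logistic(data, current, outcome)
        except FitError as e:
            raise FitError(f"elimination step {step} ({len(current)} predictors): {e}") from e
        removable = [p for p in current if p not in forced]
        if not removable:
            return current
        pvals = fit.pvalues[removable]
        worst_p = pvals.max()
        if not (worst_p > alpha):
            return current
        # drop the latest-declared candidate among exact ties
        tied = [p for p in removable if pvals[p] == worst_p]
        current.remove(tied[-1])


@dataclass
class SelectionResult:
    """Per-candidate bootstrap inclusion frequencies and the retained set."""

    inclusion_frequency: pd.Series
    retained: list
    B: int
    alpha: float
    threshold: float
    forced: tuple
    seed: object = None
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "candidate": self.inclusion_frequency.index,
            "frequency": self.inclusion_frequency.values,
            "retained": [c in self.retained for c in self.inclusion_frequency.index],
        })


def bootstrap_select(stack, B: int = 200, alpha: float = 0.157,
                     threshold: float = 0.60, forced=FORCED_PREDICTORS,
                     seed=None, candidates=None, outcome: str = OUTCOME,
                     mode: str = "patient") -> SelectionResult:
    """Inclusion-frequency selection over bootstrap replicates of a stack.

    ``stack`` is an :class:`~tkrsat.impute.ImputedStack` (or a single
    completed DataFrame).  Per replicate: resample (see module docstring
    for the two modes), run :func:`backward_eliminate`, and record the
    selected set.  A candidate's inclusion frequency is the fraction of
    replicates retaining it; forced predictors are 1 by construction.
    ``retained`` applies the threshold (and always contains the forced
    set).
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    if mode not in {"patient", "stacked"}:
        raise ParameterError(f"unknown resampling mode {mode!r}")
    candidates = list(CANDIDATE_PREDICTORS if candidates is None else candidates)
    datasets = list(stack.datasets) if hasattr(stack, "datasets") else [stack]
    n = len(datasets[0])
    rng = np.random.default_rng(seed)
    stacked = pd.concat(datasets, ignore_index=True) if mode == "stacked" else None

    counts = pd.Series(0.0, index=candidates)
    failed = 0
    for _ in range(B):
        if mode == "patient":
            d = datasets[int(rng.integers(len(datasets)))]
            boot = d.iloc[rng.integers(n, size=n)]
        else:
            boot = stacked.iloc[rng.integers(len(stacked), size=n)]
        try:
            selected = backward_eliminate(boot, candidates, alpha=alpha,
                                          forced=forced, outcome=outcome)
        except FitError:
            failed += 1  # degenerate resample (e.g. one-class outcome)
            continue
        counts[selected] += 1

    completed = B - failed
    if completed == 0 or failed > 0.10 * B:
        raise FitError(f"backward selection failed on {failed}/{B} replicates")
    freq = counts / completed
    freq[list(forced)] = 1.0
    retained = [c for c in candidates if freq[c] >= threshold or c in forced]
    return SelectionResult(inclusion_frequency=freq, retained=retained, B=B,
                           alpha=alpha, threshold=threshold,
                           forced=tuple(forced), seed=seed, n_failed=failed)
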