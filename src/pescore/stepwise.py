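"""Stepwise forward/reverse selection with AIC back-pruning.

Model building follows a forward/reverse stepwise procedure on a
Bonferroni-culled candidate pool: at each iteration the best absent
candidate (smallest Wald p) enters if its p-value is below the addition
cutoff (0.049), then the worst in-model variable leaves if its p-value has
risen to or above the removal cutoff (0.05).  Equal p-values break
lexicographically by variable name, so the procedure is deterministic for a
given input.  Oscillating add/remove cycles are detected by tracking
visited variable sets and terminate the search with a warning.

The stepwise model is then pruned by Akaike's information criterion: each
variable is removed in turn and discarded if the refit without it has a
strictly lower AIC, repeating passes until no removal helps.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .logit import (
    FitResult,
    RankDeficientError,
    fit_binary_logit,
    fit_ordinal_logit,
    wald_test,
)

Trace = List[Dict[str, object]]


def _fit(X: pd.DataFrame, y, kind: str, variables: Sequence[str]) -> FitResult:
    sub = X[list(variables)] if variables else None
    if kind == "ordinal":
        return fit_ordinal_logit(sub, y)
    if kind == "binary":
        return fit_binary_logit(sub if variables else None, y)
    raise ValueError(f"unknown model kind {kind!r}")


def stepwise_fit(
    X: pd.DataFrame,
    y,
    candidates: Sequence[str],
    kind: str = "binary",
    p_add: float = 0.049,
    p_remove: float = 0.05,
    max_steps: int = 200,
) -> Tuple[FitResult, Trace]:
    """Forward/reverse stepwise selection over a candidate pool.

    Returns the final fit (intercept-/thresholds-only if nothing enters)
    and the full selection trace.  Missing outcome rows are dropped
    listwise before selection so every candidate fit sees identical
    observations.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    mask = y.notna() & X[list(candidates)].notna().all(axis=1) \
        if len(candidates) else y.notna()
    Xm, ym = X.loc[mask], y.loc[mask]
    current: List[str] = []
    trace: Trace = []
    seen = {frozenset()}
    fit = _fit(Xm, ym, kind, current)
    for _ in range(max_steps):
        changed = False
        # forward: best candidate not in the model
        best_name, best_p = None, np.inf
        for name in sorted(set(candidates) - set(current)):
            try:
                trial = _fit(Xm, ym, kind, current + [name])
                p = wald_test(trial, name).p
            except (RankDeficientError, RuntimeError):
                continue
            if p < best_p - 1e-15 or (
                    abs(p - best_p) <= 1e-15
                    and (best_name is None or name < best_name)):
                best_name, best_p = name, p
        if best_name is not None and best_p < p_add:
            current = current + [best_name]
            fit = _fit(Xm, ym, kind, current)
            trace.append({"action": "add", "variable": best_name,
                          "p": best_p, "model": list(current),
                          "aic": fit.aic})
            changed = True
        # reverse: worst in-model variable
        if current:
            ps = {name: wald_test(fit, name).p for name in current}
            worst = max(sorted(ps), key=lambda n: ps[n])
            if ps[worst] >= p_remove:
                current = [v for v in current if v != worst]
                fit = _fit(Xm, ym, kind, current)
                trace.append({"action": "remove", "variable": worst,
                              "p": ps[worst], "model": list(current),
                              "aic": fit.aic})
                changed = True
        if not changed:
            break
        state = frozenset(current)
        if state in seen:
            warnings.warn("stepwise selection cycled; terminating with the "
                          "current model", stacklevel=2)
            break
        seen.add(state)
    return fit, trace


def aic_prune(
    X: pd.DataFrame,
    y,
    kind: str,
    fit: FitResult,
) -> Tuple[FitResult, Trace]:
    """Drop every variable whose removal strictly lowers the AIC.

    Single passes over the current variables in input order, repeated
    until a full pass removes nothing.  The result's AIC is never above
    the input fit's.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    variables = list(fit.names)
    mask = y.notna() & (X[variables].notna().all(axis=1)
                        if variables else True)
    Xm, ym = X.loc[mask], y.loc[mask]
    trace: Trace = []
    best = fit
    while True:
        dropped = False
        for name in list(variables):
            reduced = [v for v in variables if v != name]
            trial = _fit(Xm, ym, kind, reduced)
            if trial.aic < best.aic:
                variables = reduced
                best = trial
                trace.append({"action": "aic-drop", "variable": name,
                              "model": list(variables), "aic": best.aic})
                dropped = True
        if not dropped:
            break
    return best, trace


class StepwiseLogit(BaseEstimator):
    """Stepwise-selected logistic model (binary or proportional-odds).

    Parameters
    ----------
    kind : "binary" or "ordinal"
    p_add, p_remove : Wald p-value cutoffs for addition (0.049) and
        removal (0.05).
    prune : whether to apply the AIC back-pruning pass.

    Fitted attributes: ``selected_`` (final variable list), ``result_``
    (final :class:`FitResult`), ``trace_`` (selection + pruning log).
    """

    def __init__(self, kind: str = "binary", p_add: float = 0.049,
                 p_remove: float = 0.05, prune: bool = True):
        self.kind = kind
        self.p_add = p_add
        self.p_remove = p_remove
        self.prune = prune

    def fit(self, X: pd.DataFrame, y, candidates: Optional[Sequence[str]] = None):
        if candidates is None:
            candidates = list(X.columns)
        fit, trace = stepwise_fit(X, y, candidates, kind=self.kind,
                                  p_add=self.p_add, p_remove=self.p_remove)
        if self.prune and fit.names:
            fit, prune_trace = aic_prune(X, y, self.kind, fit)
            trace = trace + prune_trace
        self.result_ = fit
        self.trace_ = trace
        self.selected_ = list(fit.names)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self
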