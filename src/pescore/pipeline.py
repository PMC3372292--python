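"""End-to-end model building: screen, cull, stepwise, AIC, coefficient set.

The analysis chain for one outcome:

1. aggregate clone scores into a per-construct dataset (``aggregate``);
2. screen all sequence parameters with single regressions
   (ordinal for E and S, binary for usability); S screens use only
   constructs with E > 0, since S is unrecorded without expression;
3. cull redundant variables (exposure splits, whole-vs-fractional charge)
   and drop everything not Bonferroni-significant;
4. stepwise forward/reverse multiple regression with AIC back-pruning;
5. package the surviving coefficients as a :class:`CoefficientSet` for
   scoring new sequences.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import make_dataset, round_half_up_scores
from .predictor import CoefficientSet
from .screen import bonferroni_threshold, cull_candidates, single_screen
from .stepwise import StepwiseLogit

OUTCOME_KINDS = {"E": "ordinal", "S": "ordinal", "usability": "binary"}


def outcome_vector(dataset: pd.DataFrame, outcome: str) -> pd.Series:
    """Extract and prepare the outcome column for modeling.

    S is restricted to constructs with E > 0; averaged (non-integer)
    ordinal scores are rounded half-up to integer levels before
    cumulative-logit fitting.
    """
    if outcome == "usability":
        return dataset["usable"].astype(float)
    if outcome == "E":
        y = dataset["E"].astype(float)
    elif outcome == "S":
        y = dataset.loc[dataset["E"] > 0, "S"].astype(float)
        y = y.reindex(dataset.index)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    if not np.allclose(y.dropna() % 1, 0.0):
        y = round_half_up_scores(y)
    return y


def screen_outcome(
    features: pd.DataFrame,
    dataset: pd.DataFrame,
    outcome: str,
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Single-regression screen of every parameter against one outcome."""
    kind = OUTCOME_KINDS[outcome]
    y = outcome_vector(dataset, outcome)
    feats = features.reindex(dataset.index)
    mask = y.notna()
    return single_screen(feats.loc[mask], y.loc[mask], kind=kind,
                         alpha=alpha, n_tests=n_tests)


def build_model(
    features: pd.DataFrame,
    dataset: pd.DataFrame,
    outcome: str,
    alpha: float = 0.05,
    p_add: float = 0.049,
    p_remove: float = 0.05,
    n_tests: Optional[int] = None,
    candidates: Optional[Sequence[str]] = None,
    metadata: Optional[dict] = None,
) -> Dict[str, object]:
    """Run the full screen -> cull -> stepwise -> AIC chain for one outcome.

    Returns a dict with the screen table, the culled candidate list, the
    final fit, the selection trace, and a serializable coefficient set.
    """
    kind = OUTCOME_KINDS[outcome]
    screen = screen_outcome(features, dataset, outcome,
                            alpha=alpha, n_tests=n_tests)
    threshold = screen.attrs["threshold"]
    if candidates is None:
        candidates = cull_candidates(screen, threshold)
    y = outcome_vector(dataset, outcome)
    feats = features.reindex(dataset.index)
    mask = y.notna()
    model = StepwiseLogit(kind=kind, p_add=p_add, p_remove=p_remove)
    model.fit(feats.loc[mask], y.loc[mask], candidates=list(candidates))
    meta = {
        "outcome": outcome,
        "alpha": alpha,
        "n_tests": screen.attrs["n_tests"],
        "bonferroni_threshold": threshold,
        "p_add": p_add,
        "p_remove": p_remove,
        "candidates": list(candidates),
    }
    if metadata:
        meta.update(metadata)
    coeffs = CoefficientSet.from_fit(model.result_, metadata=meta)
    return {
        "screen": screen,
        "candidates": list(candidates),
        "fit": model.result_,
        "trace": model.trace_,
        "coefficients": coeffs,
    }


def build_datasets(
    outcomes: pd.DataFrame,
    variant: str = "analysis-max",
    split: Optional[pd.Series] = None,
    targets: Optional[pd.Series] = None,
) -> Dict[str, pd.DataFrame]:
    """Aggregate clone outcomes and partition into analysis/test datasets."""
    dataset = make_dataset(outcomes, variant=variant, targets=targets)
    if split is None:
        return {"analysis": dataset}
    split = split.reindex(dataset.index)
    return {
        "analysis": dataset.loc[split == "analysis"],
        "test": dataset.loc[split == "test"],
    }
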