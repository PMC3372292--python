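"""Clone-score aggregation and the usability outcome.

Each construct was scored in replicate small-scale expression trials
(clones), each yielding an integer expression level E (0-5) and, whenever
E > 0, a solubility score S (0-5).  About a quarter of constructs show
discrepant scores between clones, and several aggregation strategies exist
for collapsing replicates to one (E, S) per construct:

``max-each``
    componentwise maxima of E and of the recorded S values (the primary
    analysis convention: most pipeline failures lower scores, so the
    maximum is the best estimate of the construct's potential);
``blind-average``
    arithmetic means of E and of recorded S (possibly non-integer);
``max-exs``
    the (E, S) pair of the replicate with the highest E*S product
    (ties resolved by stable clone order);
``consistent``
    the common value if all replicates agree exactly, otherwise the
    construct is dropped.

A construct is *usable* when E*S > 11 (equivalently >= 12 on integers),
the operational threshold for scale-up; an unrecorded S (no expression)
means not usable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

USABILITY_THRESHOLD = 11

AGGREGATION_STRATEGIES = ("max-each", "blind-average", "max-exs", "consistent")

#: Dataset variants and the aggregation they imply.
DATASET_VARIANTS = {
    "analysis-max": "max-each",
    "blind-average": "blind-average",
    "max-exs": "max-exs",
    "max-exs-one-construct": "max-exs",
    "consistent-cull": "consistent",
    "filtered": "max-each",
}


@dataclass(frozen=True)
class OutcomePair:
    """Aggregated outcome for one construct."""

    E: float
    S: Optional[float]
    usable: bool


def usability(E: float, S: Optional[float]) -> bool:
    """True iff the expression-solubility product exceeds the threshold."""
    if S is None or (isinstance(S, float) and math.isnan(S)):
        return False
    return E * S > USABILITY_THRESHOLD


def _product(e: float, s: Optional[float]) -> float:
    if s is None or (isinstance(s, float) and math.isnan(s)):
        return 0.0
    return e * s


def aggregate_clone_scores(
    replicates: Sequence[Tuple[float, Optional[float]]],
    strategy: str = "max-each",
) -> Optional[OutcomePair]:
    """Collapse replicate (E, S) scores to one OutcomePair.

    Returns ``None`` under the ``consistent`` strategy when replicates
    disagree (the construct is culled).
    """
    if not replicates:
        raise ValueError("no replicates to aggregate")
    if strategy not in AGGREGATION_STRATEGIES:
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    es = [float(e) for e, _ in replicates]
    ss = [s for _, s in replicates]
    recorded = [float(s) for s in ss
                if s is not None and not (isinstance(s, float) and math.isnan(s))]
    if strategy == "max-each":
        E = max(es)
        S = max(recorded) if recorded else None
    elif strategy == "blind-average":
        E = float(np.mean(es))
        S = float(np.mean(recorded)) if recorded else None
    elif strategy == "max-exs":
        prods = [_product(e, s) for e, s in replicates]
        best = int(np.argmax(prods))  # argmax keeps the first clone on ties
        E = es[best]
        S = None if ss[best] is None or (
            isinstance(ss[best], float) and math.isnan(ss[best])
        ) else float(ss[best])
    else:  # consistent
        s_key = [None if s is None or (isinstance(s, float) and math.isnan(s))
                 else float(s) for s in ss]
        if len(set(es)) > 1 or len(set(s_key)) > 1:
            return None
        E = es[0]
        S = s_key[0]
    return OutcomePair(E=E, S=S, usable=usability(E, S))


def make_dataset(
    outcomes: pd.DataFrame,
    variant: str = "analysis-max",
    targets: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Aggregate a clone-level outcome table into a per-construct dataset.

    Parameters
    ----------
    outcomes : DataFrame with columns ``id``, ``clone_id``, ``E``, ``S``
        (S NaN where unrecorded).  Clone order within a construct is the
        row order, which makes tie-breaking deterministic.
    variant : one of ``DATASET_VARIANTS``.
    targets : optional Series mapping construct id -> target id, required
        for the one-construct variant (keep the construct with maximal E*S
        per target; ties resolved by construct id).

    Returns
    -------
    DataFrame indexed by construct id with columns ``E``, ``S``, ``usable``.
    """
    if variant not in DATASET_VARIANTS:
        raise ValueError(f"unknown dataset variant {variant!r}")
    strategy = DATASET_VARIANTS[variant]
    rows = {}
    for cid, grp in outcomes.groupby("id", sort=True):
        reps = [(e, None if pd.isna(s) else float(s))
                for e, s in zip(grp["E"], grp["S"])]
        pair = aggregate_clone_scores(reps, strategy)
        if pair is None:
            continue
        rows[cid] = (pair.E, np.nan if pair.S is None else pair.S, pair.usable)
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["E", "S", "usable"])
    df.index.name = "id"
    df["usable"] = df["usable"].astype(bool)
    if variant == "max-exs-one-construct":
        if targets is None:
            raise ValueError("one-construct variant requires a target mapping")
        df = _dedupe_by_target(df, targets)
    return df


def _dedupe_by_target(df: pd.DataFrame, targets: pd.Series) -> pd.DataFrame:
    prod = (df["E"] * df["S"].fillna(0.0)).rename("exs")
    tmp = df.assign(exs=prod, target=targets.reindex(df.index))
    keep: List[str] = []
    for _, grp in tmp.groupby("target", sort=True):
        grp = grp.sort_index()  # ties -> first by construct id
        keep.append(grp["exs"].idxmax())
    return df.loc[sorted(keep)]


def round_half_up_scores(values: pd.Series) -> pd.Series:
    """Round averaged (non-integer) scores half-up to integer levels."""
    return np.floor(values + 0.5)
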