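"""The pES usability predictor and ordinal score predictors.

``pES`` — the probability of Expressed and Soluble protein — scores a
sequence as ``p = 1 / (1 + exp(-theta))`` where ``theta`` is the fitted
linear combination of the selected sequence parameters.  Ordinal
coefficient sets predict the full distribution over the 0-5 score levels
through the cumulative-logit form.  Calibration curves bin constructs by
``theta`` and compare the observed usable fraction with the predicted
probability, with Bayesian (Jeffreys-prior) binomial 95% confidence
intervals; cutoff trade-off tables quantify the usable-yield increase
obtained by discarding low-scoring targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .logit import FitResult


@dataclass
class CoefficientSet:
    """Serializable fitted model: named coefficients + intercept/thresholds.

    ``kind`` is ``"binary"`` (usability / pES) or ``"ordinal"`` (E or S
    score predictors).  Ordinal sets carry strictly increasing thresholds
    and the outcome levels they separate; binary sets carry an intercept.
    ``metadata`` records how the set was produced (training variant,
    scales, rare-codon set, culling record, ...).
    """

    kind: str
    coefficients: Dict[str, float]
    intercept: Optional[float] = None
    thresholds: Optional[List[float]] = None
    levels: Optional[List[int]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "ordinal"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "binary" and self.intercept is None:
            raise ValueError("binary coefficient set requires an intercept")
        if self.kind == "ordinal":
            if not self.thresholds:
                raise ValueError("ordinal coefficient set requires thresholds")
            t = np.asarray(self.thresholds, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("ordinal thresholds must be strictly "
                                 "increasing")
            if self.levels is None:
                self.levels = list(range(len(t) + 1))

    @classmethod
    def from_fit(cls, fit: FitResult, metadata: Optional[dict] = None
                 ) -> "CoefficientSet":
        coeffs = {n: float(c) for n, c in zip(fit.names, fit.coef)}
        if fit.kind == "binary":
            return cls(kind="binary", coefficients=coeffs,
                       intercept=float(fit.intercept),
                       metadata=metadata or {})
        return cls(kind="ordinal", coefficients=coeffs,
                   thresholds=[float(t) for t in fit.thresholds],
                   levels=[int(v) for v in fit.levels],
                   metadata=metadata or {})

    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "thresholds": self.thresholds,
            "levels": self.levels,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, bytes]) -> "CoefficientSet":
        try:
            payload = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
        return cls(kind=payload["kind"],
                   coefficients=dict(payload["coefficients"]),
                   intercept=payload.get("intercept"),
                   thresholds=payload.get("thresholds"),
                   levels=payload.get("levels"),
                   metadata=payload.get("metadata", {}))


def linear_score(
    features: Union[pd.Series, pd.DataFrame, Dict[str, float]],
    coeffs: CoefficientSet,
) -> Union[float, pd.Series]:
    """theta = intercept + sum of coefficient * feature.

    Every coefficient-named feature must be present (and non-missing);
    absent features raise rather than being silently imputed.
    """
    names = list(coeffs.coefficients)
    beta = np.array([coeffs.coefficients[n] for n in names])
    base = coeffs.intercept if coeffs.kind == "binary" else 0.0
    if isinstance(features, pd.DataFrame):
        missing = [n for n in names if n not in features.columns]
        if missing:
            raise KeyError(f"features required by the model are missing: "
                           f"{missing}")
        sub = features[names]
        if sub.isna().any().any():
            bad = sorted(sub.columns[sub.isna().any()])
            raise KeyError(f"features required by the model are missing "
                           f"(NaN) for some records: {bad}")
        return pd.Series(base + sub.to_numpy(float) @ beta,
                         index=features.index, name="theta")
    if isinstance(features, pd.Series):
        features = features.to_dict()
    missing = [n for n in names if n not in features
               or pd.isna(features[n])]
    if missing:
        raise KeyError(f"features required by the model are missing: "
                       f"{missing}")
    return float(base + sum(coeffs.coefficients[n] * features[n]
                            for n in names))


def pes_score(
    features: Union[pd.Series, pd.DataFrame, Dict[str, float]],
    coeffs: CoefficientSet,
) -> Union[float, pd.Series]:
    """Usability probability p = 1 / (1 + exp(-theta))."""
    if coeffs.kind != "binary":
        raise ValueError("pES scoring requires a binary coefficient set")
    theta = linear_score(features, coeffs)
    if isinstance(theta, pd.Series):
        return pd.Series(special.expit(theta.to_numpy()),
                         index=theta.index, name="pes")
    return float(special.expit(theta))


def predict_score_distribution(
    features: Union[pd.Series, pd.DataFrame, Dict[str, float]],
    coeffs: CoefficientSet,
) -> pd.DataFrame:
    """Probability of each ordinal score level under a cumulative-logit set.

    Rows sum to one; columns are the model's outcome levels.
    """
    if coeffs.kind != "ordinal":
        raise ValueError("score-distribution prediction requires an ordinal "
                         "coefficient set")
    theta = linear_score(features, coeffs)
    if not isinstance(theta, pd.Series):
        theta = pd.Series([theta], index=[0])
    t = np.asarray(coeffs.thresholds, dtype=float)
    cum = special.expit(t[None, :] - theta.to_numpy()[:, None])
    cum = np.column_stack([np.zeros(len(theta)), cum, np.ones(len(theta))])
    probs = np.diff(cum, axis=1)
    return pd.DataFrame(probs, index=theta.index, columns=coeffs.levels)


def binomial_ci(
    successes: int,
    n: int,
    prior: str = "jeffreys",
) -> tuple:
    """Central 95% Bayesian posterior interval for a binomial proportion.

    Default prior is Jeffreys Beta(1/2, 1/2); ``prior="uniform"`` uses
    Beta(1, 1).  By convention the lower bound is exactly 0 when no
    successes were observed, and the upper bound exactly 1 when all trials
    succeeded.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    if prior == "jeffreys":
        a0 = b0 = 0.5
    elif prior == "uniform":
        a0 = b0 = 1.0
    else:
        raise ValueError(f"unknown prior {prior!r}")
    a = successes + a0
    b = n - successes + b0
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(0.025, a, b))
    upper = 1.0 if successes == n else float(stats.beta.ppf(0.975, a, b))
    return lower, upper


@dataclass(frozen=True)
class CalibrationBin:
    """One theta-interval bin of a calibration curve."""

    lower: float
    upper: float
    count: int
    observed_fraction: float
    predicted_mean: float
    ci_lower: float
    ci_upper: float


def calibration_curve(
    theta: Sequence[float],
    usable: Sequence[bool],
    bin_width: float = 0.1,
    origin: float = 0.0,
    prior: str = "jeffreys",
) -> List[CalibrationBin]:
    """Bin constructs at equal theta intervals and compare observed vs
    predicted usable fractions.

    Bins are anchored at ``origin`` (bin edges at origin + k * width);
    empty bins are omitted.  Each bin reports the observed usable fraction
    with its 95% binomial CI and the mean predicted probability
    ``expit(theta)`` of its members.
    """
    theta = np.asarray(theta, dtype=float)
    usable = np.asarray(usable, dtype=bool)
    if theta.shape != usable.shape:
        raise ValueError("theta and usable must have the same length")
    idx = np.floor((theta - origin) / bin_width).astype(int)
    bins: List[CalibrationBin] = []
    for k in np.unique(idx):
        mask = idx == k
        n = int(mask.sum())
        s = int(usable[mask].sum())
        lo, hi = binomial_ci(s, n, prior=prior)
        bins.append(CalibrationBin(
            lower=origin + k * bin_width,
            upper=origin + (k + 1) * bin_width,
            count=n,
            observed_fraction=s / n,
            predicted_mean=float(np.mean(special.expit(theta[mask]))),
            ci_lower=lo,
            ci_upper=hi,
        ))
    return bins


def cutoff_tradeoff(
    pes: Sequence[float],
    usable: Sequence[bool],
    cutoffs: Sequence[float] = (0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Yield-vs-coverage trade-off of selecting targets by pES cutoff.

    For each cutoff: the fraction of the pool kept (pES > cutoff), the
    usable rate among kept targets, and the percentage increase of that
    rate over the whole-pool usable rate.  An empty kept set is flagged
    undefined (NaN row).
    """
    pes = np.asarray(pes, dtype=float)
    usable = np.asarray(usable, dtype=bool)
    overall = usable.mean()
    rows = []
    for cut in cutoffs:
        kept = pes > cut
        n_kept = int(kept.sum())
        if n_kept == 0:
            rows.append({"cutoff": cut, "fraction_kept": 0.0,
                         "usable_rate_kept": np.nan,
                         "yield_increase_pct": np.nan, "defined": False})
            continue
        rate = usable[kept].mean()
        rows.append({
            "cutoff": cut,
            "fraction_kept": n_kept / len(pes),
            "usable_rate_kept": rate,
            "yield_increase_pct": 100.0 * (rate / overall - 1.0),
            "defined": True,
        })
    return pd.DataFrame(rows).set_index("cutoff")


class PESPredictor(BaseEstimator):
    """Estimator wrapper around a fitted coefficient set.

    Can be constructed directly from a :class:`CoefficientSet` (e.g. loaded
    from JSON) or fitted via :func:`pescore.pipeline.build_model` output.
    """

    def __init__(self, coefficients: Optional[CoefficientSet] = None):
        self.coefficients = coefficients

    def fit(self, X=None, y=None):
        if self.coefficients is None:
            raise ValueError("PESPredictor requires a coefficient set; "
                             "fit models with pescore.pipeline.build_model")
        self.coefficients_ = self.coefficients
        return self

    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        self.fit()
        return linear_score(X, self.coefficients_)

    def predict_proba(self, X: pd.DataFrame):
        self.fit()
        if self.coefficients_.kind == "binary":
            p1 = pes_score(X, self.coefficients_)
            return np.column_stack([1.0 - p1, p1])
        return predict_score_distribution(X, self.coefficients_).to_numpy()

    def predict(self, X: pd.DataFrame):
        proba = self.predict_proba(X)
        if self.coefficients_.kind == "binary":
            return (proba[:, 1] > 0.5).astype(int)
        levels = np.asarray(self.coefficients_.levels)
        return levels[np.argmax(proba, axis=1)]
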