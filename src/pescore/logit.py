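"""Maximum-likelihood binary and proportional-odds ordinal logistic regression.

Parameterizations
-----------------
Binary (usability) model::

    Pr(Y = 1) = exp(theta) / (1 + exp(theta)),   theta = b0 + x @ beta

Ordinal (cumulative-logit, proportional-odds) model for J ordered levels::

    P(Y <= j) = exp(t_j - theta) / (1 + exp(t_j - theta)),   theta = x @ beta

with strictly increasing thresholds ``t_1 < ... < t_{J-1}`` and no separate
intercept.  Under this sign convention a larger linear predictor ``theta``
shifts probability mass toward *higher* outcome levels, so positive slopes
mean "more of this feature, better scores".  For J = 2 the ordinal model is
the binary model with ``t_1 = -b0``.

Fitting is Newton-Raphson with step-halving on the exact log-likelihood
(analytic gradient and Hessian; the observed information is the negative
Hessian at the optimum), with a BFGS fallback.  Convergence requires a gradient
infinity-norm below ``tol`` (default 1e-8).  Standard errors come from the
observed information matrix.  Complete separation is flagged — any
standardized slope (slope times predictor SD) exceeding 50 during
iteration, or a saturated likelihood at convergence — instead of being
allowed to diverge silently, and rank-deficient designs raise an error
naming the collinear columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from sklearn.base import BaseEstimator

_LOG10 = np.log(10.0)


class SeparationError(RuntimeError):
    """The likelihood is unbounded: the data are (quasi-)completely separated."""


class RankDeficientError(ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"collinear predictor columns: {self.columns}")


class DegenerateFitError(RuntimeError):
    """A test statistic could not be formed (zero or non-finite SE)."""


@dataclass
class FitResult:
    """A fitted binary or ordinal logistic model.

    ``coef``/``se_coef`` are aligned with ``names``.  Binary fits carry an
    intercept; ordinal fits carry strictly increasing thresholds (one per
    non-top outcome level) and the outcome levels they separate.
    """

    kind: str  # "binary" | "ordinal"
    names: List[str]
    coef: np.ndarray
    se_coef: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int
    intercept: Optional[float] = None
    se_intercept: Optional[float] = None
    thresholds: Optional[np.ndarray] = None
    se_thresholds: Optional[np.ndarray] = None
    levels: Optional[np.ndarray] = None

    @property
    def k_params(self) -> int:
        extra = 1 if self.kind == "binary" else len(self.thresholds)
        return len(self.names) + extra

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def coef_named(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names, dtype=float)

    def se_named(self) -> pd.Series:
        return pd.Series(self.se_coef, index=self.names, dtype=float)

    def to_dict(self) -> dict:
        out = {
            "kind": self.kind,
            "coefficients": dict(zip(self.names, map(float, self.coef))),
            "se": dict(zip(self.names, map(float, self.se_coef))),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
        }
        if self.kind == "binary":
            out["intercept"] = float(self.intercept)
            out["se_intercept"] = float(self.se_intercept)
        else:
            out["thresholds"] = [float(t) for t in self.thresholds]
            out["se_thresholds"] = [float(t) for t in self.se_thresholds]
            out["levels"] = [int(v) for v in self.levels]
        return out


@dataclass
class TestResult:
    """A Wald Z or likelihood-ratio chi-squared test."""

    statistic: float
    p: float
    df: Optional[int] = None
    log10_p: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# design-matrix handling


def _as_matrix(
    X: Union[pd.DataFrame, np.ndarray, None], names: Optional[Sequence[str]]
) -> Tuple[np.ndarray, List[str]]:
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if names is None:
            names = [f"x{i}" for i in range(arr.shape[1])]
    # canonical memory layout: keeps results bit-identical regardless of
    # whether the caller handed over C- or F-ordered data
    return np.ascontiguousarray(arr), list(names)


def _check_design(X: np.ndarray, names: List[str], with_intercept: bool) -> None:
    if X.shape[1] == 0:
        return
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    stds = X.std(axis=0)
    constant = [n for n, s in zip(names, stds) if s == 0.0]
    if constant:
        raise RankDeficientError(constant)
    mat = np.column_stack([np.ones(len(X)), X]) if with_intercept else X
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns via pivoted QR
        _, _, piv = linalg.qr(mat, pivoting=True, mode="economic")
        dropped = sorted(piv[rank:])
        offset = 1 if with_intercept else 0
        cols = [names[j - offset] for j in dropped if j >= offset]
        raise RankDeficientError(cols or names)


# ---------------------------------------------------------------------------
# binary log-likelihood


def _binary_ll_grad_hess(params, X1, y):
    eta = X1 @ params
    p = special.expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    grad = X1.T @ (y - p)
    w = p * (1.0 - p)
    hess = -(X1 * w[:, None]).T @ X1
    return ll, grad, hess


# ---------------------------------------------------------------------------
# ordinal log-likelihood

def _ordinal_ll(params, X, y, J):
    K = J - 1
    t = params[:K]
    theta = X @ params[K:] if X.shape[1] else np.zeros(len(y))
    eta_hi = np.where(y < K, t[np.minimum(y, K - 1)] - theta, np.inf)
    eta_lo = np.where(y > 0, t[np.maximum(y - 1, 0)] - theta, -np.inf)
    pi = special.expit(eta_hi) - special.expit(eta_lo)
    if np.any(pi <= 0.0):
        return -np.inf
    return float(np.sum(np.log(pi)))


def _ordinal_ll_grad(params, X, y, J):
    K = J - 1
    t = params[:K]
    p = X.shape[1]
    theta = X @ params[K:] if p else np.zeros(len(y))
    hi_idx = np.minimum(y, K - 1)
    lo_idx = np.maximum(y - 1, 0)
    eta_hi = np.where(y < K, t[hi_idx] - theta, np.inf)
    eta_lo = np.where(y > 0, t[lo_idx] - theta, -np.inf)
    F_hi = special.expit(eta_hi)
    F_lo = special.expit(eta_lo)
    pi = F_hi - F_lo
    if np.any(pi <= 0.0):
        return -np.inf, np.full(K + p, np.nan)
    ll = float(np.sum(np.log(pi)))
    g_hi = np.where(y < K, F_hi * (1.0 - F_hi), 0.0) / pi
    g_lo = np.where(y > 0, F_lo * (1.0 - F_lo), 0.0) / pi
    grad_t = (
        np.bincount(hi_idx, weights=g_hi, minlength=K)
        - np.bincount(lo_idx, weights=np.where(y > 0, g_lo, 0.0), minlength=K)
    )
    # bincount over hi_idx also accumulates top-level obs at K-1, but their
    # weight g_hi is zero there; same for bottom-level obs in the lo sum.
    grad = np.empty(K + p)
    grad[:K] = grad_t
    if p:
        grad[K:] = -X.T @ (g_hi - g_lo)
    return ll, grad


def _ordinal_hessian(params, X, y, J):
    """Analytic Hessian of the ordinal log-likelihood at ``params``.

    Blocks over (thresholds, slopes); derived from
    d2 log pi = (pi * d2 pi - (d pi)(d pi)^T) / pi^2 with
    d pi/dt_j = F'(eta_hi) [j = y] - F'(eta_lo) [j = y-1] and
    d pi/d beta = -(F'(eta_hi) - F'(eta_lo)) x.
    """
    K = J - 1
    t = params[:K]
    p = X.shape[1]
    theta = X @ params[K:] if p else np.zeros(len(y))
    hi_idx = np.minimum(y, K - 1)
    lo_idx = np.maximum(y - 1, 0)
    has_hi = y < K
    has_lo = y > 0
    F_hi = np.where(has_hi, special.expit(t[hi_idx] - theta), 1.0)
    F_lo = np.where(has_lo, special.expit(t[lo_idx] - theta), 0.0)
    pi = F_hi - F_lo
    a = np.where(has_hi, F_hi * (1.0 - F_hi), 0.0)       # F'(eta_hi)
    b = np.where(has_lo, F_lo * (1.0 - F_lo), 0.0)       # F'(eta_lo)
    da = np.where(has_hi, a * (1.0 - 2.0 * F_hi), 0.0)   # F''(eta_hi)
    db = np.where(has_lo, b * (1.0 - 2.0 * F_lo), 0.0)   # F''(eta_lo)

    inv = 1.0 / pi
    inv2 = inv * inv
    H = np.zeros((K + p, K + p))

    # t-t block: diagonal gets pi^-1 * F'' terms; pairs (y, y-1) interact
    # through the outer-product part only
    w_hi_diag = da * inv - a * a * inv2
    w_lo_diag = -db * inv - b * b * inv2
    np.add.at(H, (hi_idx, hi_idx), np.where(has_hi, w_hi_diag, 0.0))
    np.add.at(H, (lo_idx, lo_idx), np.where(has_lo, w_lo_diag, 0.0))
    cross = a * b * inv2  # -(dpi/dt_y)(dpi/dt_{y-1})/pi^2 with signs: +ab/pi^2
    both = has_hi & has_lo
    np.add.at(H, (hi_idx[both], lo_idx[both]), cross[both])
    np.add.at(H, (lo_idx[both], hi_idx[both]), cross[both])

    if p:
        # t-beta block: d2 pi/dt_j dbeta = -F''_hi [j=y] x + F''_lo [j=y-1] x
        # full term: (pi * d2pi - dpi_t * dpi_b) / pi^2
        dpi_b_coef = -(a - b)  # dpi/dbeta = dpi_b_coef * x
        w_hi = (-da) * inv - a * dpi_b_coef * inv2
        w_lo = db * inv + b * dpi_b_coef * inv2
        for j in range(K):
            mask_hi = has_hi & (hi_idx == j)
            mask_lo = has_lo & (lo_idx == j)
            row = np.where(mask_hi, w_hi, 0.0) + np.where(mask_lo, w_lo, 0.0)
            Hj = X.T @ row
            H[j, K:] += Hj
            H[K:, j] += Hj
        # beta-beta block
        w_bb = (da - db) * inv - dpi_b_coef * dpi_b_coef * inv2
        H[K:, K:] += (X * w_bb[:, None]).T @ X
    return H


def _fd_hessian(grad_fn, params, h=1e-5):
    """Central finite differences of an analytic gradient."""
    k = len(params)
    H = np.empty((k, k))
    for j in range(k):
        step = h * max(1.0, abs(params[j]))
        hi = params.copy()
        lo = params.copy()
        hi[j] += step
        lo[j] -= step
        H[:, j] = (grad_fn(hi) - grad_fn(lo)) / (2.0 * step)
    return 0.5 * (H + H.T)


def _thresholds_increasing(params, K):
    t = params[:K]
    return K <= 1 or bool(np.all(np.diff(t) > 1e-10))


def _newton(
    ll_grad,
    hess,
    params0,
    *,
    n_slopes,
    slope_offset,
    slope_scales=None,
    K_thresholds=0,
    tol=1e-8,
    max_iter=200,
):
    """Maximize a log-likelihood by damped Newton iterations.

    ``ll_grad(p) -> (ll, grad)``; ``hess(p) -> Hessian of ll`` (may be a
    finite-difference approximation).  Step-halving enforces an increasing
    log-likelihood and, for ordinal fits, strictly increasing thresholds —
    the monotonicity repair for wayward iterates.
    """
    params = np.asarray(params0, dtype=float).copy()
    ll, grad = ll_grad(params)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = hess(params)
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H + 1e-8 * np.eye(len(grad)), grad,
                                   rcond=None)[0]
        lam = 1.0
        accepted = False
        for _ in range(40):
            trial = params + lam * step
            if _thresholds_increasing(trial, K_thresholds):
                ll_t, grad_t = ll_grad(trial)
                if np.isfinite(ll_t) and ll_t >= ll - 1e-13:
                    params, ll, grad = trial, ll_t, grad_t
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            break
        slopes = params[slope_offset:slope_offset + n_slopes]
        if n_slopes and _std_slope_max(slopes, slope_scales) > 50.0:
            raise SeparationError(
                "standardized slope magnitude exceeded 50 during iteration; "
                "the data are likely completely separated")
    else:
        n_iter = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    return params, ll, grad, converged, n_iter


def _std_slope_max(slopes, scales):
    """Largest |slope| on the standardized-predictor scale.

    Separation is flagged on standardized slopes (slope times predictor SD):
    fraction-valued sequence parameters legitimately carry raw slopes in the
    tens to hundreds, so a raw-scale cutoff would misfire.
    """
    slopes = np.abs(np.asarray(slopes, dtype=float))
    if scales is not None:
        slopes = slopes * np.asarray(scales, dtype=float)
    return float(slopes.max()) if slopes.size else 0.0


def fit_binary_logit(
    X: Union[pd.DataFrame, np.ndarray, None],
    y: Union[pd.Series, np.ndarray],
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """MLE for the binary logistic model (intercept + slopes)."""
    Xm, names = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    if Xm.size == 0:
        Xm = np.empty((len(y), 0))
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binary outcome must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("need at least one observation of each outcome class")
    _check_design(Xm, names, with_intercept=True)
    X1 = np.column_stack([np.ones(len(y)), Xm])

    def ll_grad(p):
        ll, g, _ = _binary_ll_grad_hess(p, X1, y)
        return ll, g

    def hess(p):
        return _binary_ll_grad_hess(p, X1, y)[2]

    scales = Xm.std(axis=0) if Xm.shape[1] else None
    params0 = np.zeros(X1.shape[1])
    params0[0] = special.logit(np.clip(y.mean(), 1e-8, 1 - 1e-8))
    params, ll, grad, converged, n_iter = _newton(
        ll_grad, hess, params0,
        n_slopes=Xm.shape[1], slope_offset=1, slope_scales=scales,
        tol=tol, max_iter=max_iter)
    if not converged:
        res = optimize.minimize(
            lambda p: -ll_grad(p)[0], params,
            jac=lambda p: -ll_grad(p)[1], method="BFGS",
            options={"gtol": tol / 10, "maxiter": 500})
        if np.max(np.abs(res.jac)) < np.max(np.abs(grad)):
            params, ll = res.x, -res.fun
            converged = bool(np.max(np.abs(res.jac)) < tol)
        if _std_slope_max(params[1:], scales) > 50.0:
            raise SeparationError(
                "standardized slope magnitude exceeded 50; the data are "
                "likely separated")
    _check_saturated(ll, n_slopes=Xm.shape[1])
    info = -hess(params)
    se = _se_from_information(info)
    return FitResult(
        kind="binary", names=names, coef=params[1:], se_coef=se[1:],
        loglik=ll, n_obs=len(y), converged=converged, n_iter=n_iter,
        intercept=float(params[0]), se_intercept=float(se[0]))


def fit_ordinal_logit(
    X: Union[pd.DataFrame, np.ndarray, None],
    y: Union[pd.Series, np.ndarray],
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> FitResult:
    """MLE for the proportional-odds cumulative-logit model."""
    Xm, names = _as_matrix(X, names)
    y_arr = np.asarray(y)
    mask = ~pd.isna(y_arr)
    if not mask.all():
        y_arr = y_arr[mask]
        if Xm.size:
            Xm = Xm[mask]
    if Xm.size == 0:
        Xm = np.empty((len(y_arr), 0))
    levels = np.unique(y_arr)
    if len(levels) < 2:
        raise ValueError("ordinal outcome must have at least two observed levels")
    expected = np.arange(levels.min(), levels.max() + 1)
    if len(levels) < len(expected):
        warnings.warn(
            f"outcome levels {sorted(set(expected) - set(levels))} absent "
            "from data; fitting on the observed levels only",
            stacklevel=2)
    codes = np.searchsorted(levels, y_arr)
    J = len(levels)
    K = J - 1
    _check_design(Xm, names, with_intercept=False)
    p = Xm.shape[1]

    def ll_grad(par):
        return _ordinal_ll_grad(par, Xm, codes, J)

    def hess(par):
        return _ordinal_hessian(par, Xm, codes, J)

    scales = Xm.std(axis=0) if p else None
    cum = np.cumsum(np.bincount(codes, minlength=J))[:-1] / len(codes)
    params0 = np.concatenate([special.logit(cum), np.zeros(p)])
    params, ll, grad, converged, n_iter = _newton(
        ll_grad, hess, params0,
        n_slopes=p, slope_offset=K, slope_scales=scales, K_thresholds=K,
        tol=tol, max_iter=max_iter)
    if not converged:
        params, ll, converged = _ordinal_bfgs_fallback(
            params, Xm, codes, J, tol, grad_now=grad, ll_now=ll)
        if p and _std_slope_max(params[K:], scales) > 50.0:
            raise SeparationError(
                "standardized slope magnitude exceeded 50; the data are "
                "likely separated")
    _check_saturated(ll, n_slopes=p)
    info = -hess(params)
    se = _se_from_information(info)
    return FitResult(
        kind="ordinal", names=names, coef=params[K:], se_coef=se[K:],
        loglik=ll, n_obs=len(y_arr), converged=converged, n_iter=n_iter,
        thresholds=params[:K], se_thresholds=se[:K],
        levels=levels)


def _ordinal_bfgs_fallback(params, Xm, codes, J, tol, grad_now, ll_now):
    """Reparameterized fallback: thresholds as t1 + cumulative exp-increments.

    The exp-increment parameterization keeps thresholds strictly increasing
    for any unconstrained iterate, so BFGS cannot wander into an invalid
    region even when the Newton path stalled.
    """
    K = J - 1
    p = Xm.shape[1]
    t = params[:K]
    incr = np.diff(t)
    incr = np.clip(incr, 1e-6, None)
    z0 = np.concatenate([[t[0]], np.log(incr), params[K:]])

    def unpack(z):
        t_ = np.concatenate([[z[0]], z[0] + np.cumsum(np.exp(z[1:K]))])
        return np.concatenate([t_, z[K:]])

    def negll(z):
        return -_ordinal_ll(unpack(z), Xm, codes, J)

    res = optimize.minimize(negll, z0, method="BFGS",
                            options={"gtol": tol / 10, "maxiter": 1000})
    cand = unpack(res.x)
    ll_cand, grad_cand = _ordinal_ll_grad(cand, Xm, codes, J)
    if np.isfinite(ll_cand) and ll_cand > ll_now:
        return cand, ll_cand, bool(np.max(np.abs(grad_cand)) < tol)
    return params, ll_now, False


def _check_saturated(ll: float, n_slopes: int) -> None:
    """A saturated likelihood (every outcome predicted with probability
    ~1) is only reachable under complete separation; the gradient also
    vanishes there, so the convergence test alone cannot catch it."""
    if n_slopes and ll > -1e-6:
        raise SeparationError(
            "likelihood saturated (all outcomes predicted perfectly); "
            "the data are completely separated")


def _se_from_information(info: np.ndarray) -> np.ndarray:
    if info.size == 0:
        return np.array([])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    diag = np.diag(cov)
    if np.any(diag < 0):
        warnings.warn("observed information not positive definite; "
                      "standard errors may be unreliable", stacklevel=3)
    return np.sqrt(np.abs(diag))


# ---------------------------------------------------------------------------
# tests


def wald_test(fit: FitResult, name: str) -> TestResult:
    """Two-sided Wald Z test for one predictor's slope."""
    if name not in fit.names:
        raise KeyError(f"predictor {name!r} not in fit")
    i = fit.names.index(name)
    se = fit.se_coef[i]
    if not np.isfinite(se) or se == 0.0:
        raise DegenerateFitError(f"non-usable standard error for {name!r}")
    z = fit.coef[i] / se
    # log-space survival function keeps extreme p-values exact
    log10_p = (stats.norm.logsf(abs(z)) + np.log(2.0)) / _LOG10
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    p = max(p, np.nextafter(0.0, 1.0))
    return TestResult(statistic=float(z), p=float(p), df=None,
                      log10_p=float(log10_p))


def lr_test(full: FitResult, nested: FitResult) -> TestResult:
    """Likelihood-ratio chi-squared test of nested models."""
    if full.kind != nested.kind:
        raise ValueError("models are of different kinds")
    if full.n_obs != nested.n_obs:
        raise ValueError("models were fitted on different observation counts")
    if not set(nested.names) <= set(full.names):
        raise ValueError("nested model's predictors are not a subset of the "
                         "full model's")
    df = full.k_params - nested.k_params
    if df < 0:
        raise ValueError("nested model has more parameters than full model")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    if df == 0:
        return TestResult(statistic=stat, p=1.0, df=0, log10_p=0.0)
    p = float(stats.chi2.sf(stat, df))
    log10_p = float(stats.chi2.logsf(stat, df) / _LOG10)
    if not np.isfinite(log10_p):
        # chi2.logsf underflows in linear space for very large statistics;
        # leading term of the upper-tail asymptotic expansion
        half = stat / 2.0
        log10_p = (-half + (df / 2.0 - 1.0) * np.log(half)
                   - special.gammaln(df / 2.0)) / _LOG10
    p = max(p, np.nextafter(0.0, 1.0))
    return TestResult(statistic=float(stat), p=p, df=df, log10_p=log10_p)


# ---------------------------------------------------------------------------
# estimator layer


class BinaryLogit(BaseEstimator):
    """Binary logistic regression estimator (Newton-Raphson MLE).

    Fitted attributes: ``coef_``, ``intercept_``, ``se_``, ``loglik_``,
    ``aic_``, ``result_`` (the full :class:`FitResult`).
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        result = fit_binary_logit(X, y, tol=self.tol, max_iter=self.max_iter)
        self.result_ = result
        self.feature_names_in_ = np.asarray(result.names, dtype=object)
        self.n_features_in_ = len(result.names)
        self.coef_ = result.coef
        self.intercept_ = result.intercept
        self.se_ = result.se_coef
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.converged_ = result.converged
        return self

    def decision_function(self, X):
        Xm, _ = _as_matrix(X, list(self.feature_names_in_))
        return self.intercept_ + Xm @ self.coef_

    def predict_proba(self, X):
        p1 = special.expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0.0).astype(int)


class OrdinalLogit(BaseEstimator):
    """Proportional-odds cumulative-logit estimator.

    Fitted attributes: ``coef_``, ``thresholds_`` (strictly increasing),
    ``classes_`` (the observed outcome levels), ``se_``, ``loglik_``,
    ``aic_``, ``result_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        result = fit_ordinal_logit(X, y, tol=self.tol, max_iter=self.max_iter)
        self.result_ = result
        self.feature_names_in_ = np.asarray(result.names, dtype=object)
        self.n_features_in_ = len(result.names)
        self.coef_ = result.coef
        self.thresholds_ = result.thresholds
        self.classes_ = result.levels
        self.se_ = result.se_coef
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.converged_ = result.converged
        return self

    def decision_function(self, X):
        Xm, _ = _as_matrix(X, list(self.feature_names_in_))
        return Xm @ self.coef_

    def predict_proba(self, X):
        """Per-level probabilities P(Y = j), columns ordered as ``classes_``."""
        theta = self.decision_function(X)
        cum = special.expit(self.thresholds_[None, :] - theta[:, None])
        cum = np.column_stack([np.zeros(len(theta)), cum, np.ones(len(theta))])
        return np.diff(cum, axis=1)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
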