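"""Independent oracles used by the tests.

These deliberately avoid the package's fitting code: log-likelihoods are
written out directly from the model definitions and optimized by refining
grid search, so they can adjudicate the Newton/BFGS fits.
"""

import numpy as np


def binary_loglik(intercept, slope, x, y):
    eta = intercept + slope * np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def ordinal_loglik(thresholds, slope, x, y):
    """Cumulative-logit log-likelihood, levels coded 0..J-1."""
    t = np.asarray(thresholds, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    theta = slope * x
    K = len(t)
    hi = np.where(y < K, 1.0 / (1.0 + np.exp(-(t[np.minimum(y, K - 1)] - theta))), 1.0)
    lo = np.where(y > 0, 1.0 / (1.0 + np.exp(-(t[np.maximum(y - 1, 0)] - theta))), 0.0)
    pi = hi - lo
    if np.any(pi <= 0):
        return -np.inf
    return float(np.sum(np.log(pi)))


def _refine_grid(loglik_fn, center, span, n_rounds=7, n_points=21):
    """Coordinate-wise refining grid search maximizing loglik_fn(params).

    Each round lays an n_points grid per dimension across +/- span around
    the current best and shrinks the span; final resolution is below 1e-4
    for the default spans used in the tests.
    """
    best = np.asarray(center, dtype=float)
    best_ll = loglik_fn(best)
    for _ in range(n_rounds):
        axes = [np.linspace(b - s, b + s, n_points)
                for b, s in zip(best, span)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        lls = np.array([loglik_fn(p) for p in pts])
        i = int(np.argmax(lls))
        if lls[i] > best_ll:
            best, best_ll = pts[i], lls[i]
        span = [s * (2.2 / (n_points - 1)) for s in span]
    return best, best_ll


def grid_binary_mle(x, y, span=6.0):
    """Brute-force MLE of the 1-predictor binary logit by refining grid."""
    return _refine_grid(
        lambda p: binary_loglik(p[0], p[1], x, y),
        center=[0.0, 0.0], span=[span, span])


def grid_ordinal_mle(x, y, J, span=6.0):
    """Brute-force MLE of the 1-predictor cumulative-logit model.

    Parameterized directly as (t_1, ..., t_{J-1}, slope); non-monotone
    threshold combinations score -inf and are never selected.
    """
    K = J - 1
    counts = np.bincount(np.asarray(y, dtype=int), minlength=J)
    cum = np.cumsum(counts)[:-1] / len(y)
    cum = np.clip(cum, 0.05, 0.95)
    center = list(np.log(cum / (1 - cum))) + [0.0]

    def fn(p):
        t = p[:K]
        if np.any(np.diff(t) <= 0):
            return -np.inf
        return ordinal_loglik(t, p[K], x, y)

    return _refine_grid(fn, center=center, span=[span] * (K + 1))


def beta_quantile_numeric(q, a, b, grid=200001):
    """Beta quantile by numeric CDF inversion on a dense grid
    (independent of scipy.stats.beta.ppf)."""
    x = np.linspace(0.0, 1.0, grid)
    # trapezoid CDF of the unnormalized density; endpoints handled by
    # excluding the singular first/last points for a, b < 1
    eps = 1.0 / (grid * 10)
    xs = np.clip(x, eps, 1 - eps)
    pdf = xs ** (a - 1) * (1 - xs) ** (b - 1)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5
                                           * np.diff(x))])
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, x))
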