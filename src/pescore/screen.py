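"""Single-regression screening and variable-culling rules.

Each sequence parameter is screened one at a time against an outcome —
ordinal regressions for the 0-5 E and S scores, binary for usability.  The
screen reports, per parameter:

* the regression slope and its Wald p-value;
* ``signed_log_p`` = -log10(p) times the sign of the slope, so positive
  correlations plot upward and negative ones downward;
* the ``predictive_value`` = slope times the parameter's standard deviation
  in the screened dataset, a scale-free effect size;
* a Bonferroni significance flag at alpha / n_tests.

Redundant-variable culling then reduces the parameter set before multiple
regression: a buried/exposed split replaces the total fraction only when
both split members are significant with opposite-signed slopes; for each
whole-vs-fractional charge pair the more significant member is kept (ties
favor the length-normalized version).
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .features import AA_COLUMNS
from .logit import (
    FitResult,
    RankDeficientError,
    fit_binary_logit,
    fit_ordinal_logit,
    wald_test,
)

SCREEN_COLUMNS = ["slope", "se", "p", "signed_log_p", "predictive_value",
                  "significant"]

CHARGE_PAIRS = [
    ("numcharge", "fracnumcharge"),
    ("netcharge", "fracnetcharge"),
    ("absnetcharge", "fracabsnetcharge"),
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _fit_one(x: pd.Series, y, kind: str) -> FitResult:
    X = x.to_frame()
    if kind == "ordinal":
        return fit_ordinal_logit(X, y)
    if kind == "binary":
        return fit_binary_logit(X, y)
    raise ValueError(f"unknown model kind {kind!r}")


def single_screen(
    features: pd.DataFrame,
    y,
    kind: str,
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Screen every feature column against the outcome, one regression each.

    Rows with a missing outcome or missing feature value are excluded
    listwise per regression.  Constant columns are flagged and excluded from
    the result (listed in ``result.attrs["excluded"]``).  The Bonferroni
    count defaults to the number of columns screened and is recorded in
    ``result.attrs``.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=features.index)
    if n_tests is None:
        n_tests = features.shape[1]
    threshold = bonferroni_threshold(alpha, n_tests)
    rows = {}
    excluded: List[str] = []
    for col in features.columns:
        x = features[col]
        mask = x.notna() & y.notna()
        xm, ym = x[mask], y[mask]
        sd = float(xm.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            excluded.append(col)
            continue
        fit = _fit_one(xm, ym, kind)
        test = wald_test(fit, col)
        slope = float(fit.coef[0])
        sign = float(np.sign(slope))
        rows[col] = {
            "slope": slope,
            "se": float(fit.se_coef[0]),
            "p": test.p,
            "signed_log_p": -test.log10_p * sign,
            "predictive_value": slope * sd,
            "significant": test.p < threshold,
        }
    result = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=SCREEN_COLUMNS)
    result.index.name = "parameter"
    result.attrs["excluded"] = excluded
    result.attrs["alpha"] = alpha
    result.attrs["n_tests"] = n_tests
    result.attrs["threshold"] = threshold
    result.attrs["kind"] = kind
    if excluded:
        warnings.warn(f"constant parameters excluded from screen: {excluded}",
                      stacklevel=2)
    return result


def select_exposure_variables(
    screen: pd.DataFrame,
    threshold: float,
) -> List[str]:
    """Resolve total vs buried/exposed amino-acid fractions.

    Per amino acid: keep the {buried, exposed} pair only when both members
    are significant at ``threshold`` with opposite-signed slopes; otherwise
    keep the total fraction.  Returns the retained amino-acid variable
    names.  Raises if a needed screen row is missing (constant-excluded
    members count as unavailable and force the total).
    """
    retained: List[str] = []
    excluded = set(screen.attrs.get("excluded", []))
    present = set(screen.index) | excluded
    for col in AA_COLUMNS:
        bcol, ecol = col + "b", col + "e"
        if not {col, bcol, ecol} & present:
            continue  # amino acid not part of this screen at all
        if bcol in screen.index and ecol in screen.index:
            b, e = screen.loc[bcol], screen.loc[ecol]
            if (np.sign(b["slope"]) != np.sign(e["slope"])
                    and b["p"] < threshold and e["p"] < threshold):
                retained.extend([bcol, ecol])
                continue
        if col in screen.index:
            retained.append(col)
        elif col not in excluded:
            raise KeyError(f"no screen results for amino acid {col!r}")
    return retained


def select_charge_variables(screen: pd.DataFrame) -> List[str]:
    """Keep the more significant member of each whole/fractional charge pair.

    Ties keep the fractional (length-normalized) version; a member excluded
    from the screen (constant) concedes to the other.
    """
    retained: List[str] = []
    for whole, frac in CHARGE_PAIRS:
        have_whole = whole in screen.index
        have_frac = frac in screen.index
        if have_whole and have_frac:
            retained.append(
                whole if screen.loc[whole, "p"] < screen.loc[frac, "p"]
                else frac)
        elif have_whole:
            retained.append(whole)
        elif have_frac:
            retained.append(frac)
    return retained


def cull_candidates(
    screen: pd.DataFrame,
    threshold: Optional[float] = None,
) -> List[str]:
    """Apply the exposure and charge culls, then the Bonferroni filter.

    Returns the candidate-variable list for stepwise multiple regression,
    in screen (input) order.
    """
    if threshold is None:
        threshold = screen.attrs["threshold"]
    keep = set(select_exposure_variables(screen, threshold))
    keep |= set(select_charge_variables(screen))
    aa_related = set(AA_COLUMNS)
    aa_related |= {c + "b" for c in AA_COLUMNS} | {c + "e" for c in AA_COLUMNS}
    charge_related = {v for pair in CHARGE_PAIRS for v in pair}
    for col in screen.index:
        if col not in aa_related and col not in charge_related:
            keep.add(col)
    return [c for c in screen.index
            if c in keep and screen.loc[c, "p"] < threshold]


def paired_rare_common_screen(
    features: pd.DataFrame,
    y,
    kind: str,
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Joint rare/common codon-fraction regressions for Arg, Ile, Leu, Pro.

    For each amino acid the rare- and common-codon fractions enter one
    two-predictor regression together, so each slope is adjusted for the
    other usage class.  A constant member (e.g. no rare codons anywhere) is
    excluded and the other fitted alone.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=features.index)
    pairs = [(f"{aa}_rare", f"{aa}_common") for aa in "rilp"]
    wanted = [c for pair in pairs for c in pair]
    missing = [c for c in wanted if c not in features.columns]
    if missing:
        raise KeyError(f"codon-split features missing: {missing}")
    if n_tests is None:
        n_tests = len(wanted)
    threshold = bonferroni_threshold(alpha, n_tests)
    rows = {}
    for rare_col, common_col in pairs:
        sub = features[[rare_col, common_col]]
        mask = sub.notna().all(axis=1) & y.notna()
        subm, ym = sub[mask], y[mask]
        cols = [c for c in (rare_col, common_col)
                if float(subm[c].std(ddof=1)) > 0.0]
        if not cols:
            continue
        fit = (fit_ordinal_logit if kind == "ordinal"
               else fit_binary_logit)(subm[cols], ym)
        for c in cols:
            test = wald_test(fit, c)
            slope = float(fit.coef[fit.names.index(c)])
            rows[c] = {
                "slope": slope,
                "se": float(fit.se_coef[fit.names.index(c)]),
                "p": test.p,
                "signed_log_p": -test.log10_p * float(np.sign(slope)),
                "predictive_value": slope * float(subm[c].std(ddof=1)),
                "significant": test.p < threshold,
            }
    result = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=SCREEN_COLUMNS)
    result.index.name = "parameter"
    result.attrs["threshold"] = threshold
    result.attrs["kind"] = kind
    return result


def permissive_enhancing_screen(
    features: pd.DataFrame,
    scores,
    top_level: int = 5,
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
    boundaries: Sequence[str] = ("permissive", "enhancing"),
) -> Dict[str, pd.DataFrame]:
    """Screen the extreme-score boundaries of an ordinal outcome.

    ``permissive``: binary regressions on indicator(score > 0) — parameters
    gating whether anything happens at all.  ``enhancing``: binary
    regressions on indicator(score == top level) — parameters pushing good
    outcomes to the top score.  A requested boundary whose extreme class is
    empty raises; request a single boundary to screen the other alone.
    """
    s = pd.Series(np.asarray(scores, dtype=float), index=features.index)
    s = s.dropna()
    feats = features.loc[s.index]
    indicators = {
        "permissive": (s > 0).astype(int),
        "enhancing": (s == top_level).astype(int),
    }
    out: Dict[str, pd.DataFrame] = {}
    for name in boundaries:
        indicator = indicators[name]
        if indicator.nunique() < 2:
            raise ValueError(
                f"{name} screen impossible: outcome class is empty")
        out[name] = single_screen(feats, indicator, kind="binary",
                                  alpha=alpha, n_tests=n_tests)
    return out
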