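"""Sequence parameters: amino-acid fractions, hydropathy, side-chain entropy,
charge metrics, isoelectric point, disorder fraction, and rare-codon splits.

The full parameter set comprises 72 core variables per construct — the 20
total amino-acid fractions (columns ``a`` .. ``y``), the 20 predicted-buried
(``ab`` .. ``yb``) and 20 predicted-exposed (``ae`` .. ``ye``) fractions, and
12 compound parameters (``gravy``, ``sce``, ``esce``, six charge variables,
``diso``, ``length``, ``pi``).  When an in-frame CDS is available, eight
additional rare/common codon fractions are computed for Arg, Ile, Leu, Pro.

Denominator conventions follow the source analysis: every fraction —
including the buried/exposed splits and the disorder fraction — divides by
total chain length, while the two entropy means divide by the number of
residues actually averaged (all residues for ``sce``, predicted-exposed
residues only for ``esce``).

Residue codes outside the 20-letter alphabet (X, U, B, Z, ...) count toward
chain length but appear in no fraction numerator and are skipped by the
scale means; a warning is emitted per record.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import ProteinRecord
from .scales import (
    DEFAULT_SCALES,
    NEGATIVE_GROUPS,
    POSITIVE_GROUPS,
    STANDARD_AA,
    ScaleConfig,
)

#: Feature-column order for the 20 amino acids (lowercase one-letter codes).
AA_COLUMNS = [aa.lower() for aa in STANDARD_AA]
BURIED_COLUMNS = [c + "b" for c in AA_COLUMNS]
EXPOSED_COLUMNS = [c + "e" for c in AA_COLUMNS]
COMPOUND_COLUMNS = [
    "gravy", "sce", "esce",
    "numcharge", "netcharge", "absnetcharge",
    "fracnumcharge", "fracnetcharge", "fracabsnetcharge",
    "diso", "length", "pi",
]
CORE_COLUMNS = AA_COLUMNS + BURIED_COLUMNS + EXPOSED_COLUMNS + COMPOUND_COLUMNS
CODON_SPLIT_COLUMNS = [
    "r_rare", "r_common", "i_rare", "i_common",
    "l_rare", "l_common", "p_rare", "p_common",
]

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

# Charge variables: numcharge = R+K+D+E, netcharge = R+K-D-E, plus |net|
# and the three chain-length-normalized versions.
_CHARGE_POS = ("R", "K")
_CHARGE_NEG = ("D", "E")


def _seq_counts(seq: str) -> Tuple[np.ndarray, int]:
    """(counts over the 20 standard residues, number of standard residues)."""
    counts = np.zeros(20)
    n_std = 0
    for aa in seq:
        idx = _AA_INDEX.get(aa)
        if idx is not None:
            counts[idx] += 1
            n_std += 1
    return counts, n_std


def _warn_nonstandard(record: ProteinRecord, n_std: int) -> None:
    if n_std < len(record):
        warnings.warn(
            f"{record.id}: {len(record) - n_std} nonstandard residue(s) "
            "counted in chain length but excluded from fractions and scale "
            "means",
            stacklevel=3,
        )


def amino_acid_fractions(record: ProteinRecord) -> Dict[str, float]:
    """Fractional content of each of the 20 amino acids.

    The denominator is total chain length; nonstandard residues therefore
    depress every fraction slightly rather than being redistributed.
    """
    if not record.aa_seq:
        raise ValueError("empty sequence")
    counts, n_std = _seq_counts(record.aa_seq)
    _warn_nonstandard(record, n_std)
    frac = counts / len(record)
    return {aa: frac[i] for aa, i in _AA_INDEX.items()}


def exposure_split_fractions(
    record: ProteinRecord,
) -> Dict[str, Tuple[float, float]]:
    """Per amino acid, (buried fraction, exposed fraction).

    Both denominators are total chain length, so the buried and exposed
    fractions of an amino acid sum exactly to its total fraction.
    """
    exposure = record.require_exposure()
    buried = np.zeros(20)
    exposed = np.zeros(20)
    for aa, label in zip(record.aa_seq, exposure):
        idx = _AA_INDEX.get(aa)
        if idx is None:
            continue
        if label == "B":
            buried[idx] += 1
        else:
            exposed[idx] += 1
    n = len(record)
    return {aa: (buried[i] / n, exposed[i] / n) for aa, i in _AA_INDEX.items()}


def gravy(
    record: ProteinRecord,
    scale: ScaleConfig = DEFAULT_SCALES,
    on_missing: str = "fail",
) -> float:
    """Grand average of hydropathy: mean per-residue Kyte-Doolittle value.

    ``on_missing`` controls residues absent from the scale: ``"fail"``
    raises, ``"skip"`` drops them from the mean.
    """
    values = []
    for aa in record.aa_seq:
        if aa in scale.hydropathy:
            values.append(scale.hydropathy[aa])
        elif aa in STANDARD_AA or on_missing == "fail":
            if on_missing == "fail":
                raise KeyError(
                    f"{record.id}: residue {aa!r} missing from hydropathy scale")
    if not values:
        raise ValueError(f"{record.id}: no residues with hydropathy values")
    return float(np.mean(values))


def sidechain_entropy(
    record: ProteinRecord,
    scale: ScaleConfig = DEFAULT_SCALES,
    exposed_only: bool = False,
) -> float:
    """Mean side-chain conformational entropy.

    With ``exposed_only`` the mean runs over predicted-exposed residues only
    (denominator = number of exposed residues).  A record with zero exposed
    residues yields NaN with a warning rather than an arbitrary zero.
    """
    if exposed_only:
        exposure = record.require_exposure()
        values = [
            scale.sce[aa]
            for aa, lab in zip(record.aa_seq, exposure)
            if lab == "E" and aa in scale.sce
        ]
        if not values:
            warnings.warn(
                f"{record.id}: no exposed residues; esce undefined",
                stacklevel=2,
            )
            return float("nan")
    else:
        values = [scale.sce[aa] for aa in record.aa_seq if aa in scale.sce]
        if not values:
            raise ValueError(f"{record.id}: no residues with SCE values")
    return float(np.mean(values))


def charge_metrics(record: ProteinRecord) -> Dict[str, float]:
    """Whole and fractional charge counts from R, K, D, E content."""
    counts, _ = _seq_counts(record.aa_seq)
    pos = sum(counts[_AA_INDEX[aa]] for aa in _CHARGE_POS)
    neg = sum(counts[_AA_INDEX[aa]] for aa in _CHARGE_NEG)
    n = len(record)
    num = pos + neg
    net = pos - neg
    return {
        "numcharge": float(num),
        "netcharge": float(net),
        "absnetcharge": float(abs(net)),
        "fracnumcharge": num / n,
        "fracnetcharge": net / n,
        "fracabsnetcharge": abs(net) / n,
    }


def net_charge_at_ph(
    record: ProteinRecord,
    ph: float,
    scale: ScaleConfig = DEFAULT_SCALES,
) -> float:
    """Henderson-Hasselbalch net charge of the chain at a given pH."""
    counts, _ = _seq_counts(record.aa_seq)
    group_counts = _charge_group_counts(counts[None, :])
    return float(_net_charge(group_counts, np.array([ph]), scale.pka)[0])


def isoelectric_point(
    record: ProteinRecord,
    scale: ScaleConfig = DEFAULT_SCALES,
    tol: float = 1e-4,
) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero.

    The charge curve is strictly decreasing in pH, so simple bisection on
    [0, 14] converges unconditionally; iteration stops when the bracket is
    narrower than ``tol`` pH units.
    """
    counts, _ = _seq_counts(record.aa_seq)
    return float(_batch_pi(counts[None, :], scale.pka, tol=tol)[0])


def disorder_fraction(record: ProteinRecord) -> float:
    """Fraction of residues annotated disordered (denominator chain length)."""
    disorder = record.require_disorder()
    return disorder.count("D") / len(record)


def rare_codon_split(
    record: ProteinRecord,
    scale: ScaleConfig = DEFAULT_SCALES,
) -> Dict[str, Tuple[float, float]]:
    """Per amino acid in {R, I, L, P}, (rare fraction, common fraction).

    Denominators are chain length, so rare + common equals the amino acid's
    total fraction.  CDS/translation consistency is enforced when the record
    is constructed.
    """
    codons = record.codons
    n = len(record)
    out: Dict[str, Tuple[float, float]] = {}
    for aa, rare_set in scale.rare_codons.items():
        rare = common = 0
        for res, codon in zip(record.aa_seq, codons):
            if res != aa:
                continue
            if codon in rare_set:
                rare += 1
            else:
                common += 1
        out[aa] = (rare / n, common / n)
    return out


def compute_feature_vector(
    record: ProteinRecord,
    scale: ScaleConfig = DEFAULT_SCALES,
) -> Dict[str, float]:
    """All available sequence parameters for one construct.

    Parameters whose annotations are absent (buried/exposed fractions and
    ``esce`` without exposure; ``diso`` without disorder; codon splits
    without a CDS) are omitted from the result rather than silently zeroed.
    """
    out: Dict[str, float] = {}
    fractions = amino_acid_fractions(record)
    for aa, col in zip(STANDARD_AA, AA_COLUMNS):
        out[col] = fractions[aa]
    if record.exposure is not None:
        split = exposure_split_fractions(record)
        for aa, bcol, ecol in zip(STANDARD_AA, BURIED_COLUMNS, EXPOSED_COLUMNS):
            out[bcol], out[ecol] = split[aa]
        out["esce"] = sidechain_entropy(record, scale, exposed_only=True)
    out["gravy"] = gravy(record, scale, on_missing="skip")
    out["sce"] = sidechain_entropy(record, scale)
    out.update(charge_metrics(record))
    if record.disorder is not None:
        out["diso"] = disorder_fraction(record)
    out["length"] = float(len(record))
    out["pi"] = isoelectric_point(record, scale)
    if record.cds is not None:
        split_rc = rare_codon_split(record, scale)
        for aa in "RILP":
            rare, common = split_rc[aa]
            out[f"{aa.lower()}_rare"] = rare
            out[f"{aa.lower()}_common"] = common
    return out


# ---------------------------------------------------------------------------
# batch machinery

_PKA_GROUPS = POSITIVE_GROUPS + NEGATIVE_GROUPS  # K R H | D E C Y
_N_POS = len(POSITIVE_GROUPS)


def _charge_group_counts(counts: np.ndarray) -> np.ndarray:
    """(n, 7) side-chain counts in _PKA_GROUPS order from (n, 20) counts."""
    idx = [_AA_INDEX[aa] for aa in _PKA_GROUPS]
    return counts[:, idx]


def _net_charge(
    group_counts: np.ndarray, ph: np.ndarray, pka: Mapping[str, float]
) -> np.ndarray:
    """Vectorized net charge for each row at its own pH value."""
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for j, aa in enumerate(_PKA_GROUPS):
        frac = (
            1.0 / (1.0 + 10.0 ** (ph - pka[aa]))
            if j < _N_POS
            else -1.0 / (1.0 + 10.0 ** (pka[aa] - ph))
        )
        charge = charge + group_counts[:, j] * frac
    return charge


def _batch_pi(
    counts: np.ndarray, pka: Mapping[str, float], tol: float = 1e-4
) -> np.ndarray:
    """Bisection for the isoelectric point, vectorized over records."""
    group_counts = _charge_group_counts(np.asarray(counts, dtype=float))
    n = group_counts.shape[0]
    lo = np.zeros(n)
    hi = np.full(n, 14.0)
    # ~17 halvings reduce the 14-unit bracket below 1e-4
    n_iter = int(np.ceil(np.log2(14.0 / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        positive = _net_charge(group_counts, mid, pka) > 0.0
        lo = np.where(positive, mid, lo)
        hi = np.where(positive, hi, mid)
    return 0.5 * (lo + hi)


class SequenceFeaturizer(BaseEstimator, TransformerMixin):
    """Transform protein records into the sequence-parameter table.

    The transform is stateless (``fit`` is a no-op kept for pipeline
    compatibility).  Output is a DataFrame indexed by record id with one
    column per parameter; parameters unavailable for a record (missing
    annotation or CDS) are NaN, and columns that are unavailable for every
    record are dropped.

    Parameters
    ----------
    scale : ScaleConfig
        Lookup tables for hydropathy, entropy, pKa, and rare codons.
    """

    def __init__(self, scale: ScaleConfig = DEFAULT_SCALES):
        self.scale = scale

    def fit(self, X: Iterable[ProteinRecord], y=None):  # noqa: D102
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> pd.DataFrame:
        records = list(X)
        if not records:
            raise ValueError("no records to featurize")
        n = len(records)
        lengths = np.array([len(r) for r in records], dtype=float)
        counts = np.zeros((n, 20))
        n_std = np.zeros(n)
        any_nonstd = False
        for i, rec in enumerate(records):
            c, ns = _seq_counts(rec.aa_seq)
            counts[i] = c
            n_std[i] = ns
            if ns < len(rec):
                any_nonstd = True
        if any_nonstd:
            warnings.warn(
                "some records contain nonstandard residues; they count in "
                "chain length but not in fractions or scale means",
                stacklevel=2,
            )

        data: Dict[str, np.ndarray] = {}
        fractions = counts / lengths[:, None]
        for j, col in enumerate(AA_COLUMNS):
            data[col] = fractions[:, j]

        kd_vec = np.array([self.scale.hydropathy[aa] for aa in STANDARD_AA])
        sce_vec = np.array([self.scale.sce[aa] for aa in STANDARD_AA])
        data["gravy"] = counts @ kd_vec / n_std
        data["sce"] = counts @ sce_vec / n_std

        pos = counts[:, [_AA_INDEX[a] for a in _CHARGE_POS]].sum(axis=1)
        neg = counts[:, [_AA_INDEX[a] for a in _CHARGE_NEG]].sum(axis=1)
        data["numcharge"] = pos + neg
        data["netcharge"] = pos - neg
        data["absnetcharge"] = np.abs(pos - neg)
        data["fracnumcharge"] = (pos + neg) / lengths
        data["fracnetcharge"] = (pos - neg) / lengths
        data["fracabsnetcharge"] = np.abs(pos - neg) / lengths
        data["length"] = lengths
        data["pi"] = _batch_pi(counts, self.scale.pka)

        # annotation-dependent blocks
        buried = np.full((n, 20), np.nan)
        exposed = np.full((n, 20), np.nan)
        esce = np.full(n, np.nan)
        diso = np.full(n, np.nan)
        for i, rec in enumerate(records):
            if rec.exposure is not None:
                b = np.zeros(20)
                e = np.zeros(20)
                sce_sum = 0.0
                sce_n = 0
                for aa, lab in zip(rec.aa_seq, rec.exposure):
                    idx = _AA_INDEX.get(aa)
                    if idx is None:
                        continue
                    if lab == "B":
                        b[idx] += 1
                    else:
                        e[idx] += 1
                        sce_sum += sce_vec[idx]
                        sce_n += 1
                buried[i] = b / lengths[i]
                exposed[i] = e / lengths[i]
                esce[i] = sce_sum / sce_n if sce_n else np.nan
            if rec.disorder is not None:
                diso[i] = rec.disorder.count("D") / lengths[i]
        for j, (bcol, ecol) in enumerate(zip(BURIED_COLUMNS, EXPOSED_COLUMNS)):
            data[bcol] = buried[:, j]
            data[ecol] = exposed[:, j]
        data["esce"] = esce
        data["diso"] = diso

        rare = {aa: np.full(n, np.nan) for aa in "RILP"}
        common = {aa: np.full(n, np.nan) for aa in "RILP"}
        for i, rec in enumerate(records):
            if rec.cds is None:
                continue
            split = rare_codon_split(rec, self.scale)
            for aa in "RILP":
                rare[aa][i], common[aa][i] = split[aa]
        for aa in "RILP":
            data[f"{aa.lower()}_rare"] = rare[aa]
            data[f"{aa.lower()}_common"] = common[aa]

        order = CORE_COLUMNS + CODON_SPLIT_COLUMNS
        df = pd.DataFrame(data, index=[r.id for r in records])[order]
        return df.dropna(axis=1, how="all")


def featurize(
    records: Sequence[ProteinRecord],
    scale: ScaleConfig = DEFAULT_SCALES,
) -> pd.DataFrame:
    """Convenience wrapper around :class:`SequenceFeaturizer`."""
    return SequenceFeaturizer(scale=scale).transform(records)
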