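"""Synthetic expression-cohort generator.

The generator emulates the statistical structure of a high-throughput
E. coli expression screen so that every analysis stage can be exercised and
validated without real data:

* random protein sequences with E. coli-like residue frequencies, perturbed
  per construct by a Dirichlet draw (between-protein composition variance),
  lognormal-ish lengths clipped to [50, 600];
* deterministic baseline annotations standing in for external predictors —
  the most hydrophobic ~45% of residues are labeled buried, and residues in
  high-disorder-propensity windows are labeled disordered (these are
  testing stand-ins, not reimplementations of the neural predictors whose
  outputs the real analysis consumed);
* an in-frame CDS per protein with configurable rare-codon usage for Arg,
  Ile, Leu, Pro;
* integer E scores (0-5) drawn from a proportional-odds cumulative-logit
  model whose latent scale is a configured linear combination of the
  construct's *realized* sequence parameters — the same model family the
  analysis fits, which makes parameter recovery well-posed; an optional
  latent-normal mode provides a misspecified variant for robustness checks;
* S scores from a second proportional-odds model whose latent scale adds a
  positive multiple of (E - center), inducing the strong E-S coupling;
  S is unrecorded (NaN) when E = 0;
* replicate clones per construct with a configured fraction of constructs
  showing a one-unit score discrepancy (clone scores are only ever
  perturbed downward, mirroring the expectation that pipeline errors lower
  scores);
* a 4:1 analysis/test split by per-construct Bernoulli draw.

Every quantity is driven by a single integer seed; the same seed yields a
byte-identical cohort.  The generative truth (coefficients, thresholds,
coupling) is stored alongside the cohort for validation but is never read
by the analysis stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import SequenceFeaturizer
from .records import ProteinRecord
from .scales import AA_TO_CODONS, DEFAULT_SCALES, STANDARD_AA, ScaleConfig

#: E. coli-like amino-acid frequencies (normalized at use).
ECOLI_AA_FREQS: Dict[str, float] = {
    "A": 0.089, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012,
    "Q": 0.044, "E": 0.059, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.105, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.015, "Y": 0.029, "V": 0.070,
}

#: TOP-IDP-style disorder propensities (higher = more disorder-prone).
_DISORDER_PROPENSITY: Dict[str, float] = {
    "A": 0.06, "R": 0.18, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.51, "V": -0.121,
}

_DEFAULT_COEFS_E: Dict[str, float] = {
    "fracnumcharge": 15.0, "gravy": -1.0, "r": -20.0,
}
_DEFAULT_THRESHOLDS_E = (1.4, 1.8, 2.2, 2.6, 3.0)
_DEFAULT_COEFS_S: Dict[str, float] = {
    "fracnumcharge": 10.0, "l": -8.0, "r": -8.0,
}
_DEFAULT_THRESHOLDS_S = (0.0, 0.45, 0.85, 1.25, 1.7)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the structure of the real screen: ~25% of constructs
    with discrepant clones, a 4:1 analysis/test split, bimodal E and S
    marginals with most mass at the extreme scores, and a strong positive
    E-S coupling.
    """

    n_constructs: int = 1000
    seed: int = 0
    # sequence model
    length_log_mean: float = float(np.log(200.0))
    length_log_sd: float = 0.45
    length_min: int = 50
    length_max: int = 600
    base_freqs: Dict[str, float] = field(
        default_factory=lambda: dict(ECOLI_AA_FREQS))
    dirichlet_concentration: float = 100.0
    # annotation heuristics
    buried_fraction: float = 0.45
    disorder_window: int = 15
    disorder_threshold: float = 0.16
    # codon model
    with_cds: bool = True
    rare_codon_prob: float = 0.08
    # outcome model
    coefs_e: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFS_E))
    thresholds_e: Tuple[float, ...] = _DEFAULT_THRESHOLDS_E
    coefs_s: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFS_S))
    thresholds_s: Tuple[float, ...] = _DEFAULT_THRESHOLDS_S
    coupling: float = 0.6
    e_center: float = 3.0
    latent: str = "logistic"  # or "normal" (misspecified robustness mode)
    # replication
    clones_per_construct: int = 2
    discrepancy_rate: float = 0.25
    # split
    train_fraction: float = 0.8

    def validate(self) -> None:
        problems = []
        if self.n_constructs < 1:
            problems.append("n_constructs must be >= 1")
        if not 0.0 <= self.discrepancy_rate <= 1.0:
            problems.append("discrepancy_rate must be in [0, 1]")
        if not 0.0 <= self.train_fraction <= 1.0:
            problems.append("train_fraction must be in [0, 1]")
        if not 0.0 <= self.rare_codon_prob <= 1.0:
            problems.append("rare_codon_prob must be in [0, 1]")
        if not 0.0 < self.buried_fraction < 1.0:
            problems.append("buried_fraction must be in (0, 1)")
        if self.clones_per_construct < 1:
            problems.append("clones_per_construct must be >= 1")
        for name, t in (("thresholds_e", self.thresholds_e),
                        ("thresholds_s", self.thresholds_s)):
            if np.any(np.diff(np.asarray(t, dtype=float)) <= 0):
                problems.append(f"{name} must be strictly increasing")
        if self.latent not in ("logistic", "normal"):
            problems.append("latent must be 'logistic' or 'normal'")
        if set(self.base_freqs) != set(STANDARD_AA):
            problems.append("base_freqs must cover exactly the 20 standard "
                            "amino acids")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))


@dataclass
class Cohort:
    """A generated cohort plus its generative truth."""

    records: List[ProteinRecord]
    outcomes: pd.DataFrame  # id, clone_id, E, S (clone level)
    split: pd.Series        # id -> "analysis" | "test"
    features: pd.DataFrame  # realized sequence parameters per construct
    truth: dict

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]


def baseline_annotations(
    seq: str,
    buried_fraction: float = 0.45,
    window: int = 15,
    threshold: float = 0.16,
    scale: ScaleConfig = DEFAULT_SCALES,
    burial_window: int = 5,
) -> Tuple[str, str]:
    """Deterministic stand-in annotations for testing.

    Exposure: residues are ranked by a context-smoothed hydropathy (mean
    over a short window), and the ``buried_fraction`` highest-ranked are
    labeled buried — so any residue type can end up buried when embedded
    in a hydrophobic stretch, as real burial predictions allow.  Disorder:
    residues whose disorder-propensity window mean exceeds ``threshold``
    are labeled disordered.
    """
    n = len(seq)
    hydro = np.array([scale.hydropathy.get(aa, 0.0) for aa in seq])
    wb = min(burial_window, n)
    burial_score = np.convolve(hydro, np.ones(wb) / wb, mode="same")
    n_buried = int(round(buried_fraction * n))
    order = np.argsort(-burial_score, kind="stable")
    exposure = np.full(n, "E", dtype="<U1")
    exposure[order[:n_buried]] = "B"
    prop = np.array([_DISORDER_PROPENSITY.get(aa, 0.0) for aa in seq])
    w = min(window, n)
    kernel = np.ones(w) / w
    smooth = np.convolve(prop, kernel, mode="same")
    disorder = np.where(smooth > threshold, "D", "O")
    return "".join(exposure), "".join(disorder)


def _sample_cds(seq: str, rng: np.random.Generator,
                rare_prob: float, scale: ScaleConfig) -> str:
    codons = []
    for aa in seq:
        rare_set = scale.rare_codons.get(aa)
        if rare_set and rng.random() < rare_prob:
            pool = sorted(rare_set)
        else:
            pool = sorted(AA_TO_CODONS[aa] - (rare_set or frozenset()))
        codons.append(pool[rng.integers(len(pool))])
    return "".join(codons)


def _sample_levels(theta: np.ndarray, thresholds: Sequence[float],
                   rng: np.random.Generator, latent: str) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float)
    if latent == "logistic":
        noise = rng.logistic(size=len(theta))
    else:
        noise = rng.normal(scale=np.pi / np.sqrt(3.0), size=len(theta))
    return (theta[:, None] + noise[:, None] > t[None, :]).sum(axis=1)


def _latent_scores(features: pd.DataFrame, coefs: Dict[str, float]
                   ) -> np.ndarray:
    missing = [k for k in coefs if k not in features.columns]
    if missing:
        raise ValueError(f"truth coefficients name unavailable features: "
                         f"{missing}")
    theta = np.zeros(len(features))
    for name, beta in coefs.items():
        theta += beta * features[name].to_numpy(float)
    return theta


def generate_cohort(
    config: GeneratorConfig,
    scale: ScaleConfig = DEFAULT_SCALES,
) -> Cohort:
    """Generate a full cohort (sequences, annotations, CDS, clone outcomes,
    split, truth record) from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(STANDARD_AA))
    base = np.array([config.base_freqs[a] for a in STANDARD_AA], dtype=float)
    base = base / base.sum()
    n = config.n_constructs
    width = len(str(max(n, 1)))

    lengths = np.exp(rng.normal(config.length_log_mean, config.length_log_sd,
                                size=n))
    lengths = np.clip(np.round(lengths), config.length_min,
                      config.length_max).astype(int)
    comps = rng.dirichlet(config.dirichlet_concentration * base, size=n)

    records: List[ProteinRecord] = []
    for i in range(n):
        seq = "".join(rng.choice(aa, size=lengths[i], p=comps[i]))
        exposure, disorder = baseline_annotations(
            seq, config.buried_fraction, config.disorder_window,
            config.disorder_threshold, scale)
        cds = (_sample_cds(seq, rng, config.rare_codon_prob, scale)
               if config.with_cds else None)
        records.append(ProteinRecord(
            id=f"syn{i:0{width}d}", aa_seq=seq, cds=cds,
            exposure=exposure, disorder=disorder))

    features = SequenceFeaturizer(scale=scale).transform(records)

    theta_e = _latent_scores(features, config.coefs_e)
    E = _sample_levels(theta_e, config.thresholds_e, rng, config.latent)
    theta_s = (_latent_scores(features, config.coefs_s)
               + config.coupling * (E - config.e_center))
    S = _sample_levels(theta_s, config.thresholds_s, rng,
                       config.latent).astype(float)
    S[E == 0] = np.nan

    ids = [r.id for r in records]
    k = config.clones_per_construct
    outcomes = pd.DataFrame({
        "id": np.repeat(ids, k),
        "clone_id": [f"c{j + 1}" for _ in ids for j in range(k)],
        "E": np.repeat(E, k).astype(float),
        "S": np.repeat(S, k),
    })
    outcomes = inject_clone_discrepancy(outcomes, config.discrepancy_rate, rng)

    split = pd.Series(
        np.where(rng.random(n) < config.train_fraction, "analysis", "test"),
        index=pd.Index(ids, name="id"), name="split")

    truth = {
        "config": _config_dict(config),
        "theta_e_mean": float(np.mean(theta_e)),
        "theta_s_mean": float(np.mean(theta_s)),
        "generative_E": [int(v) for v in E],
    }
    return Cohort(records=records, outcomes=outcomes, split=split,
                  features=features, truth=truth)


def inject_clone_discrepancy(
    outcomes: pd.DataFrame,
    rate: float,
    rng,
) -> pd.DataFrame:
    """Make a ``rate`` fraction of constructs show discrepant clone scores.

    A discrepant construct has one clone's E or S lowered by one unit
    (never below 0, never above the construct's generative maximum — i.e.
    scores are only perturbed downward).  Constructs whose scores are all
    at 0 (or whose only perturbable clone count is 1 with nothing to
    lower) cannot be made discrepant and are skipped; the target count is
    drawn from the perturbable constructs so the realized fraction matches
    ``rate`` up to rounding whenever enough constructs qualify.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = outcomes.copy(deep=True)
    ids = out["id"].unique()
    if rate == 0.0 or len(ids) == 0:
        return out
    groups = out.groupby("id", sort=False).indices
    perturbable = []
    for cid in ids:
        rows = groups[cid]
        if len(rows) < 2:
            continue
        e = out["E"].to_numpy()[rows]
        s = out["S"].to_numpy()[rows]
        if np.any(e > 0) or np.any(s[~np.isnan(s)] > 0):
            perturbable.append(cid)
    n_target = int(round(rate * len(ids)))
    n_target = min(n_target, len(perturbable))
    chosen = rng.choice(len(perturbable), size=n_target, replace=False)
    e_col = out.columns.get_loc("E")
    s_col = out.columns.get_loc("S")
    for j in chosen:
        cid = perturbable[j]
        rows = groups[cid]
        row = rows[rng.integers(len(rows))]
        e = out.iat[row, e_col]
        s = out.iat[row, s_col]
        options = []
        if e > 0:
            options.append("E")
        if not pd.isna(s) and s > 0:
            options.append("S")
        choice = options[rng.integers(len(options))]
        if choice == "E":
            new_e = e - 1.0
            out.iat[row, e_col] = new_e
            if new_e == 0:
                out.iat[row, s_col] = np.nan  # S unrecorded without expression
        else:
            out.iat[row, s_col] = s - 1.0
    return out


def _config_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["thresholds_e"] = list(d["thresholds_e"])
    d["thresholds_s"] = list(d["thresholds_s"])
    return d


# ---------------------------------------------------------------------------
# export


def export_cohort(cohort: Cohort, outdir) -> Dict[str, Path]:
    """Write a cohort as plain-text files.

    ``proteins.fasta``, optional ``cds.fasta``, ``annotations.tsv`` (id,
    1-based position, exposure B/E, disorder O/D), ``outcomes.tsv`` (id,
    clone_id, E, S with S blank when unrecorded), ``split.tsv`` and
    ``truth.json`` (the generative record; analysis stages never read it).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    fasta = outdir / "proteins.fasta"
    with fasta.open("w", encoding="utf-8") as fh:
        for rec in cohort.records:
            fh.write(f">{rec.id}\n{rec.aa_seq}\n")
    paths["proteins"] = fasta

    if any(r.cds is not None for r in cohort.records):
        cds_path = outdir / "cds.fasta"
        with cds_path.open("w", encoding="utf-8") as fh:
            for rec in cohort.records:
                if rec.cds is not None:
                    fh.write(f">{rec.id}\n{rec.cds}\n")
        paths["cds"] = cds_path

    ann_path = outdir / "annotations.tsv"
    with ann_path.open("w", encoding="utf-8") as fh:
        fh.write("id\tposition\texposure\tdisorder\n")
        for rec in cohort.records:
            exp = rec.exposure or "E" * len(rec)
            dis = rec.disorder or "O" * len(rec)
            for pos, (e_lab, d_lab) in enumerate(zip(exp, dis), start=1):
                fh.write(f"{rec.id}\t{pos}\t{e_lab}\t{d_lab}\n")
    paths["annotations"] = ann_path

    out_path = outdir / "outcomes.tsv"
    rows = cohort.outcomes.copy()
    rows["E"] = rows["E"].astype(int)
    rows["S"] = rows["S"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    rows.to_csv(out_path, sep="\t", index=False)
    paths["outcomes"] = out_path

    split_path = outdir / "split.tsv"
    cohort.split.rename("split").to_frame().to_csv(split_path, sep="\t")
    paths["split"] = split_path

    truth_path = outdir / "truth.json"
    with truth_path.open("w", encoding="utf-8") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths
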