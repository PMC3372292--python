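"""File formats: FASTA, annotation/outcome TSVs, run provenance.

All tabular files are UTF-8, tab-separated, LF-terminated, with a header
row.  Annotation positions are 1-based.  Outcome tables validate the
recording convention of the screen: integer scores 0-5, with S blank
exactly when E = 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml
from Bio import SeqIO

from .records import ProteinRecord

try:  # package version for provenance blocks
    from importlib.metadata import version as _pkg_version
    __pkg_version__ = _pkg_version("pescore")
except Exception:  # pragma: no cover
    __pkg_version__ = "unknown"


class ParseError(ValueError):
    """A malformed input file."""


@dataclass
class RunConfig:
    """Analysis run configuration, loadable from YAML.

    Unknown keys are rejected rather than ignored, so a typo in a config
    file fails loudly instead of silently running with defaults.
    """

    proteins: Optional[str] = None
    cds: Optional[str] = None
    annotations: Optional[str] = None
    features: Optional[str] = None
    outcomes: Optional[str] = None
    split: Optional[str] = None
    outdir: str = "."
    variant: str = "analysis-max"
    outcome: str = "usability"
    alpha: float = 0.05
    p_add: float = 0.049
    p_remove: float = 0.05
    bin_width: float = 0.1
    cutoffs: List[float] = field(default_factory=lambda: [0.3, 0.4, 0.5])
    seed: int = 0
    rare_codons: Optional[Dict[str, List[str]]] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ParseError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ParseError(f"{path}: unknown config keys {unknown}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Ids must be unique and sequences non-empty; sequences are upper-cased.
    Errors name the offending record and its line number.
    """
    path = Path(path)
    out: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in out:
            raise ParseError(
                f"{path}: duplicate FASTA id {record.id!r} "
                f"(line {_header_line(path, record.id, nth=2)})")
        if not seq:
            raise ParseError(
                f"{path}: empty sequence for {record.id!r} "
                f"(line {_header_line(path, record.id)})")
        out[record.id] = seq
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def _header_line(path: Path, rec_id: str, nth: int = 1) -> int:
    """Best-effort line number of the nth header with the given id."""
    count = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [rec_id]:
                count += 1
                if count == nth:
                    return lineno
    return 0


def read_annotations(path) -> Dict[str, Tuple[str, str]]:
    """Read per-residue annotations: id, position (1-based), exposure, disorder.

    Returns id -> (exposure string of B/E, disorder string of O/D).
    Positions must be contiguous from 1 within each id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "position", "exposure", "disorder"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out: Dict[str, Tuple[str, str]] = {}
    for cid, grp in df.groupby("id", sort=False):
        pos = grp["position"].to_numpy()
        expected = range(1, len(grp) + 1)
        if list(pos) != list(expected):
            raise ParseError(
                f"{path}: positions for {cid!r} are not contiguous from 1")
        exposure = "".join(grp["exposure"].astype(str))
        disorder = "".join(grp["disorder"].astype(str))
        if set(exposure) - set("BE"):
            raise ParseError(f"{path}: exposure labels for {cid!r} must be B/E")
        if set(disorder) - set("OD"):
            raise ParseError(f"{path}: disorder labels for {cid!r} must be O/D")
        out[cid] = (exposure, disorder)
    return out


def read_outcomes(path) -> pd.DataFrame:
    """Read and validate a clone-level outcome table.

    Columns: id, clone_id, E, S.  E and S must be integers in 0-5; S may be
    blank only where E = 0 (S is never recorded without expression, and is
    always recorded with it).  Errors cite the 1-based data row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "clone_id": str})
    required = {"id", "clone_id", "E", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for row_num, row in enumerate(df.itertuples(index=False), start=1):
        e, s = row.E, row.S
        if pd.isna(e) or float(e) != int(e) or not 0 <= int(e) <= 5:
            raise ParseError(
                f"{path}: row {row_num}: E must be an integer in 0-5, "
                f"got {e!r}")
        if pd.isna(s):
            if int(e) != 0:
                raise ParseError(
                    f"{path}: row {row_num}: S is blank but E = {int(e)} > 0")
        else:
            if float(s) != int(s) or not 0 <= int(s) <= 5:
                raise ParseError(
                    f"{path}: row {row_num}: S must be an integer in 0-5, "
                    f"got {s!r}")
            if int(e) == 0:
                raise ParseError(
                    f"{path}: row {row_num}: S recorded but E = 0")
    df["E"] = df["E"].astype(float)
    df["S"] = df["S"].astype(float)
    return df


def read_split(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if not {"id", "split"} <= set(df.columns):
        raise ParseError(f"{path}: split table needs columns id, split")
    bad = set(df["split"].unique()) - {"analysis", "test"}
    if bad:
        raise ParseError(f"{path}: unknown split labels {sorted(bad)}")
    return df.set_index("id")["split"]


def build_records(
    proteins,
    cds=None,
    annotations=None,
) -> List[ProteinRecord]:
    """Assemble ProteinRecords from FASTA paths/mappings and annotations.

    Records are matched by identifier; CDS and annotations are optional
    per-record but, when a file is given, unknown ids in it are errors.
    """
    seqs = read_fasta(proteins) if not isinstance(proteins, dict) else proteins
    cds_map: Dict[str, str] = {}
    if cds is not None:
        cds_map = read_fasta(cds) if not isinstance(cds, dict) else cds
        unknown = set(cds_map) - set(seqs)
        if unknown:
            raise ParseError(f"CDS ids not in protein FASTA: "
                             f"{sorted(unknown)[:5]}")
    ann_map: Dict[str, Tuple[str, str]] = {}
    if annotations is not None:
        ann_map = (read_annotations(annotations)
                   if not isinstance(annotations, dict) else annotations)
        unknown = set(ann_map) - set(seqs)
        if unknown:
            raise ParseError(f"annotation ids not in protein FASTA: "
                             f"{sorted(unknown)[:5]}")
    records = []
    for cid, seq in seqs.items():
        exposure, disorder = ann_map.get(cid, (None, None))
        records.append(ProteinRecord(
            id=cid, aa_seq=seq, cds=cds_map.get(cid),
            exposure=exposure, disorder=disorder))
    return records


def load_cohort_dir(path):
    """Round-trip loader for an exported cohort directory.

    Returns (records, outcomes DataFrame, split Series or None).  The
    truth record, if present, is deliberately not loaded here.
    """
    path = Path(path)
    cds = path / "cds.fasta"
    records = build_records(
        path / "proteins.fasta",
        cds=cds if cds.exists() else None,
        annotations=path / "annotations.tsv",
    )
    outcomes = read_outcomes(path / "outcomes.tsv")
    split_path = path / "split.tsv"
    split = read_split(split_path) if split_path.exists() else None
    return records, outcomes, split


def write_features_tsv(features: pd.DataFrame, path) -> None:
    features.rename_axis("id").to_csv(path, sep="\t",
                                      float_format="%.10g", lineterminator="\n")


def write_screen_tsv(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def write_provenance(path, command: str, params: dict,
                     extra: Optional[dict] = None) -> dict:
    """Write a provenance block for a run: package version, parameters,
    and a stable hash of the configuration."""
    payload = {
        "package": "pescore",
        "version": __pkg_version__,
        "command": command,
        "params": params,
    }
    if extra:
        payload.update(extra)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    payload["config_sha256"] = digest
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return payload
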