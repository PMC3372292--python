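"""Numeric scales used by the sequence-feature calculations.

All scales are plain per-residue lookup tables bundled in a
:class:`ScaleConfig`, so every constant the feature layer uses (hydropathy,
side-chain entropy, pKa values for the isoelectric point, and the rare-codon
sets) can be swapped out without touching the computation code.  The defaults
are the conventional choices for E. coli expression work:

* hydropathy — Kyte-Doolittle (taken from Biopython's published table);
* side-chain entropy — a Monte-Carlo-derived side-chain conformational
  entropy scale (Creamer family), in cal mol^-1 K^-1;
* pKa — Bjellqvist/ExPASy-style constants for the ionizable side chains
  (D, E, C, Y, H, K, R) plus the free N- and C-termini;
* rare codons — the codons conventionally regarded as translation-limiting
  in E. coli: Arg AGA/AGG/CGA/CGG, Ile ATA, Leu CTA, Pro CCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping

from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Monte-Carlo side-chain conformational entropies, cal mol^-1 K^-1.
#: Gly/Ala have no rotatable side chain and Pro is conformationally locked,
#: so all three sit at zero; long charged side chains (Lys, Arg, Gln, Glu,
#: Met) carry the most entropy.
CREAMER_SCE: Dict[str, float] = {
    "A": 0.00, "C": 1.65, "D": 1.59, "E": 3.33, "F": 1.51,
    "G": 0.00, "H": 2.78, "I": 1.85, "K": 4.37, "L": 1.85,
    "M": 3.55, "N": 2.24, "P": 0.00, "Q": 3.49, "R": 4.43,
    "S": 1.75, "T": 1.61, "V": 1.12, "W": 2.21, "Y": 2.27,
}

#: Bjellqvist-style pKa constants as used by the ExPASy pI tool.
#: Keys: the seven ionizable side chains plus "n_term" / "c_term".
BJELLQVIST_PKA: Dict[str, float] = {
    "n_term": 7.50,
    "c_term": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

#: Side chains that gain a positive charge when protonated.
POSITIVE_GROUPS = ("K", "R", "H")
#: Side chains that gain a negative charge when deprotonated.
NEGATIVE_GROUPS = ("D", "E", "C", "Y")

#: Conventional E. coli rare-codon sets for the four amino acids with
#: translation-limiting codons.
ECOLI_RARE_CODONS: Dict[str, FrozenSet[str]] = {
    "R": frozenset({"AGA", "AGG", "CGA", "CGG"}),
    "I": frozenset({"ATA"}),
    "L": frozenset({"CTA"}),
    "P": frozenset({"CCC"}),
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid under the standard genetic code (stops excluded)
CODON_TO_AA: Mapping[str, str] = dict(_STANDARD_TABLE.forward_table)

#: amino acid -> all codons encoding it under the standard code
AA_TO_CODONS: Dict[str, FrozenSet[str]] = {
    aa: frozenset(c for c, a in CODON_TO_AA.items() if a == aa)
    for aa in STANDARD_AA
}


@dataclass(frozen=True)
class ScaleConfig:
    """Bundle of per-residue scales and codon sets.

    Every standard amino acid must be present in ``hydropathy`` and ``sce``,
    and each rare-codon set may contain only codons that encode its amino
    acid under the standard genetic code.
    """

    hydropathy: Mapping[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE))
    sce: Mapping[str, float] = field(default_factory=lambda: dict(CREAMER_SCE))
    pka: Mapping[str, float] = field(
        default_factory=lambda: dict(BJELLQVIST_PKA))
    rare_codons: Mapping[str, FrozenSet[str]] = field(
        default_factory=lambda: {k: frozenset(v)
                                 for k, v in ECOLI_RARE_CODONS.items()})

    def __post_init__(self) -> None:
        for name, scale in (("hydropathy", self.hydropathy), ("sce", self.sce)):
            missing = [aa for aa in STANDARD_AA if aa not in scale]
            if missing:
                raise ValueError(
                    f"{name} scale is missing standard residues: {missing}")
        for key in ("n_term", "c_term"):
            if key not in self.pka:
                raise ValueError(f"pKa table is missing '{key}'")
        for group in POSITIVE_GROUPS + NEGATIVE_GROUPS:
            if group not in self.pka:
                raise ValueError(f"pKa table is missing side chain '{group}'")
        for aa, codons in self.rare_codons.items():
            bad = [c for c in codons if CODON_TO_AA.get(c) != aa]
            if bad:
                raise ValueError(
                    f"rare codons {bad} do not encode amino acid {aa}")

    def common_codons(self, aa: str) -> FrozenSet[str]:
        """Synonymous codons of ``aa`` not in its rare set."""
        return AA_TO_CODONS[aa] - self.rare_codons.get(aa, frozenset())

    def describe(self) -> dict:
        """JSON-serializable record of the scales in use (for provenance)."""
        return {
            "hydropathy": dict(self.hydropathy),
            "sce": dict(self.sce),
            "pka": dict(self.pka),
            "rare_codons": {aa: sorted(c) for aa, c in self.rare_codons.items()},
        }


DEFAULT_SCALES = ScaleConfig()
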