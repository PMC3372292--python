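"""Protein construct records: sequence, optional CDS, per-residue annotations.

A :class:`ProteinRecord` is one expression construct, analyzed on its native
sequence (purification tags are assumed to have been stripped by the caller).
Annotations are compact per-residue strings: exposure uses ``B`` (buried) /
``E`` (exposed), disorder uses ``O`` (ordered) / ``D`` (disordered).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .scales import STANDARD_AA

#: Residue codes accepted beyond the 20 standard amino acids.  They count
#: toward chain length but are excluded from fractions and scale means.
NONSTANDARD_AA = "XUBZO*"

_VALID_AA = set(STANDARD_AA) | set(NONSTANDARD_AA)


class AnnotationRequiredError(ValueError):
    """A computation needed a per-residue annotation that is absent."""


class CdsMismatchError(ValueError):
    """The CDS does not translate to the stated amino-acid sequence."""


@dataclass(frozen=True)
class ProteinRecord:
    """One construct: id, amino-acid sequence, optional CDS and annotations.

    Invariants enforced at construction:

    * non-empty amino-acid sequence over the accepted alphabet;
    * if a CDS is present, its length is ``3 * len(aa_seq)`` (no stop codon)
      and its in-frame translation under the standard code matches
      ``aa_seq`` at every standard-residue position;
    * annotation strings, when present, match the sequence length.
    """

    id: str
    aa_seq: str
    cds: Optional[str] = None
    exposure: Optional[str] = None  # 'B'/'E' per residue
    disorder: Optional[str] = None  # 'O'/'D' per residue

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.aa_seq.upper()
        object.__setattr__(self, "aa_seq", seq)
        if not seq:
            raise ValueError(f"{self.id}: empty amino-acid sequence")
        bad = sorted(set(seq) - _VALID_AA)
        if bad:
            raise ValueError(f"{self.id}: invalid residue codes {bad}")
        if self.cds is not None:
            cds = self.cds.upper()
            object.__setattr__(self, "cds", cds)
            if len(cds) != 3 * len(seq):
                raise CdsMismatchError(
                    f"{self.id}: CDS length {len(cds)} != 3*{len(seq)}")
            if set(cds) - set("ACGT"):
                raise CdsMismatchError(
                    f"{self.id}: CDS contains non-ACGT characters")
            translated = str(Seq(cds).translate())
            for pos, (aa, taa) in enumerate(zip(seq, translated)):
                if aa in STANDARD_AA and aa != taa:
                    raise CdsMismatchError(
                        f"{self.id}: codon {pos + 1} ({cds[3*pos:3*pos+3]}) "
                        f"translates to {taa!r}, sequence has {aa!r}")
        if self.exposure is not None:
            exp = self.exposure.upper()
            object.__setattr__(self, "exposure", exp)
            if len(exp) != len(seq):
                raise ValueError(
                    f"{self.id}: exposure annotation length {len(exp)} "
                    f"!= sequence length {len(seq)}")
            if set(exp) - set("BE"):
                raise ValueError(f"{self.id}: exposure labels must be B/E")
        if self.disorder is not None:
            dis = self.disorder.upper()
            object.__setattr__(self, "disorder", dis)
            if len(dis) != len(seq):
                raise ValueError(
                    f"{self.id}: disorder annotation length {len(dis)} "
                    f"!= sequence length {len(seq)}")
            if set(dis) - set("OD"):
                raise ValueError(f"{self.id}: disorder labels must be O/D")

    def __len__(self) -> int:
        return len(self.aa_seq)

    @property
    def codons(self) -> list[str]:
        """The CDS split into in-frame codons."""
        if self.cds is None:
            raise AnnotationRequiredError(f"{self.id}: no CDS available")
        return [self.cds[i:i + 3] for i in range(0, len(self.cds), 3)]

    def require_exposure(self) -> str:
        if self.exposure is None:
            raise AnnotationRequiredError(
                f"{self.id}: exposure annotation required but absent")
        return self.exposure

    def require_disorder(self) -> str:
        if self.disorder is None:
            raise AnnotationRequiredError(
                f"{self.id}: disorder annotation required but absent")
        return self.disorder
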