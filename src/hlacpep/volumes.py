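"""Amino-acid residue volumes (Zamyatnin, 1972), in cubic angstroms.

Used to test whether enrichment at the penultimate peptide position
tracks side-chain size: C2-groove geometry admits bulkier residues at
pΩ-1 than the C1 groove does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabet import AMINO_ACIDS

#: Residue volumes in A^3 (Zamyatnin, Prog Biophys Mol Biol 1972).
ZAMYATNIN_1972: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


@dataclass(frozen=True)
class VolumeTable:
    """Residue volume scale covering all 20 standard amino acids."""

    volumes: dict[str, float] = field(default_factory=lambda: dict(ZAMYATNIN_1972))
    citation: str = "Zamyatnin AA (1972) Prog Biophys Mol Biol 24:107-123"

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.volumes)
        if missing:
            raise ValueError(f"volume table missing amino acids: {sorted(missing)}")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("all residue volumes must be positive")
        if not (self.volumes["G"] < self.volumes["A"] < self.volumes["W"]):
            raise ValueError("volume scale fails sanity ordering Gly < Ala < Trp")

    def __getitem__(self, aa: str) -> float:
        return self.volumes[aa.upper()]

    def vector(self) -> list[float]:
        """Volumes in the fixed alphabet order ACDEFGHIKLMNPQRSTVWY."""
        return [self.volumes[aa] for aa in AMINO_ACIDS]
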