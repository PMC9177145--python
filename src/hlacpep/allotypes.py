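"""HLA-C allotype records and C1/C2 group assignment.

HLA-C allotypes fall into two serologically and functionally distinct
groups defined by a dimorphism at heavy-chain positions 77 and 80:
C1 allotypes carry Ser77/Asn80 and C2 allotypes carry Asn77/Lys80.
The two groups are ligands for different inhibitory KIR receptors and,
as this package quantifies, select different peptide repertoires at the
C-terminal (pΩ) and penultimate (pΩ-1) peptide positions.

Engineered point mutants (e.g. C*05:01-N77S) mix the two signatures and
are classified as ``HYBRID``.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path

from .alphabet import AMINO_ACIDS


class Group(str, enum.Enum):
    """C1/C2 dimorphism group of an HLA-C allotype."""

    C1 = "C1"
    C2 = "C2"
    HYBRID = "HYBRID"


def assign_c1c2(residue77: str, residue80: str) -> Group:
    """Classify an allotype by its residues at positions 77 and 80.

    Ser77/Asn80 -> C1; Asn77/Lys80 -> C2; every other combination of
    valid one-letter codes -> HYBRID.

    Raises
    ------
    ValueError
        If either input is not a standard one-letter amino-acid code.
    """
    r77 = str(residue77).upper()
    r80 = str(residue80).upper()
    for r, label in ((r77, "residue77"), (r80, "residue80")):
        if r not in AMINO_ACIDS:
            raise ValueError(f"{label}={r!r} is not a standard one-letter amino-acid code")
    if r77 == "S" and r80 == "N":
        return Group.C1
    if r77 == "N" and r80 == "K":
        return Group.C2
    return Group.HYBRID


@dataclass(frozen=True)
class AllotypeRecord:
    """One HLA-C allotype with its dimorphic residues.

    The group label is derived from residues 77/80 and must be
    consistent with them; use :meth:`from_residues` to construct.
    """

    name: str
    residue77: str
    residue80: str
    group: Group

    def __post_init__(self) -> None:
        expected = assign_c1c2(self.residue77, self.residue80)
        if self.group != expected:
            raise ValueError(
                f"group {self.group} inconsistent with residues "
                f"77={self.residue77}/80={self.residue80} (expected {expected})"
            )

    @classmethod
    def from_residues(cls, name: str, residue77: str, residue80: str) -> "AllotypeRecord":
        r77, r80 = residue77.upper(), residue80.upper()
        return cls(name=name, residue77=r77, residue80=r80, group=assign_c1c2(r77, r80))


# The 21-allotype immunopeptidome panel: 14 C1 and 7 C2.
_C1_PANEL = (
    "C*01:02", "C*03:02", "C*03:03", "C*03:04", "C*07:01", "C*07:02",
    "C*07:04", "C*08:01", "C*08:02", "C*12:02", "C*12:03", "C*14:02",
    "C*14:03", "C*16:01",
)
_C2_PANEL = ("C*02:02", "C*04:01", "C*04:03", "C*05:01", "C*06:02", "C*15:02", "C*17:01")


def study_panel() -> list[AllotypeRecord]:
    """The bundled 21-allotype HLA-C panel (14 C1 + 7 C2)."""
    recs = [AllotypeRecord.from_residues(n, "S", "N") for n in _C1_PANEL]
    recs += [AllotypeRecord.from_residues(n, "N", "K") for n in _C2_PANEL]
    return recs


_BUNDLED = {r.name: r for r in study_panel()}


def lookup_allotype(name: str) -> AllotypeRecord:
    """Look up an allotype in the bundled panel by name (e.g. ``C*08:02``)."""
    try:
        return _BUNDLED[name]
    except KeyError:
        raise KeyError(
            f"allotype {name!r} not in the bundled panel; supply residues 77/80 explicitly"
        ) from None


def read_allotype_table(path: str | Path) -> list[AllotypeRecord]:
    """Read allotype metadata from a CSV with columns name,res77,res80."""
    records: list[AllotypeRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "res77", "res80"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected CSV columns name,res77,res80")
        for row in reader:
            name = row["name"].strip()
            if name in seen:
                raise ValueError(f"{path}: duplicate allotype name {name!r}")
            seen.add(name)
            records.append(AllotypeRecord.from_residues(name, row["res77"].strip(), row["res80"].strip()))
    return records
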