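"""Position frequency matrices over equal-length peptide sets.

A PFM records, for each position 1..L of an L-mer set, the count and
relative frequency of each of the 20 amino acids.  Positions are
1-based in the public API, matching the p1..pΩ convention (pΩ is the
C-terminal anchor, pΩ-1 the penultimate position).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA
from .peptides import PeptideSet


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position amino-acid counts and relative frequencies.

    ``counts`` has shape (L, 20) in the fixed alphabet order
    ``ACDEFGHIKLMNPQRSTVWY``; each row sums to ``n`` and each row of
    ``freqs`` sums to 1 when ``n > 0``.
    """

    length: int
    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.counts.shape != (self.length, N_AA):
            raise ValueError(f"counts must have shape ({self.length}, {N_AA})")
        if self.n > 0 and not np.all(self.counts.sum(axis=1) == self.n):
            raise ValueError("counts at each position must sum to n")

    @property
    def freqs(self) -> np.ndarray:
        if self.n == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / float(self.n)

    def frequency(self, position: int, aa: str) -> float:
        """Relative frequency of ``aa`` at 1-based ``position``."""
        self._check_position(position)
        return float(self.freqs[position - 1, AA_INDEX[aa.upper()]])

    def row(self, position: int) -> np.ndarray:
        """The 20-vector of frequencies at 1-based ``position``."""
        self._check_position(position)
        return self.freqs[position - 1].copy()

    def count_row(self, position: int) -> np.ndarray:
        self._check_position(position)
        return self.counts[position - 1].copy()

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} out of range 1..{self.length}")

    def to_frame(self):
        """PFM frequencies as a pandas DataFrame (positions x amino acids)."""
        import pandas as pd

        return pd.DataFrame(
            self.freqs, index=range(1, self.length + 1), columns=list(AMINO_ACIDS)
        )


def _count_matrix(seqs: Iterable[str], length: int) -> tuple[np.ndarray, int]:
    counts = np.zeros((length, N_AA), dtype=np.int64)
    n = 0
    for seq in seqs:
        if len(seq) != length:
            raise ValueError(f"peptide {seq!r} is not a {length}mer")
        for pos, aa in enumerate(seq):
            counts[pos, AA_INDEX[aa]] += 1
        n += 1
    return counts, n


def position_frequency_matrix(
    peptides: PeptideSet | Iterable[str], length: int
) -> PositionFrequencyMatrix:
    """Count amino acids per position over an L-mer stratum.

    Accepts a :class:`PeptideSet` (stratified internally) or any
    iterable of equal-length sequences.  An empty stratum is an error:
    a frequency over nothing is undefined.
    """
    if isinstance(peptides, PeptideSet):
        seqs: Iterable[str] = (p for p in peptides.peptides if len(p) == length)
    else:
        seqs = peptides
    counts, n = _count_matrix(seqs, length)
    if n == 0:
        raise ValueError(f"no {length}mers available to build a PFM")
    return PositionFrequencyMatrix(length=length, counts=counts, n=n)


def residue_frequency(
    peptides: PeptideSet | Iterable[str], length: int, position: int, aa: str
) -> tuple[int, int, float]:
    """Count and percent of ``aa`` at ``position`` among L-mers.

    Returns ``(count, total, percent)`` with ``percent = 100*count/total``.
    This is the quantity behind statements like "pΩ-Ala was found in
    1.5% (30 out of 1986) of 9mers".
    """
    if not 1 <= position <= length:
        raise ValueError(f"position {position} out of range 1..{length}")
    aa = aa.upper()
    if aa not in AA_INDEX:
        raise ValueError(f"{aa!r} is not a standard amino acid")
    if isinstance(peptides, PeptideSet):
        seqs: Iterable[str] = (p for p in peptides.peptides if len(p) == length)
    else:
        seqs = peptides
    count = 0
    total = 0
    for seq in seqs:
        if len(seq) != length:
            raise ValueError(f"peptide {seq!r} is not a {length}mer")
        total += 1
        if seq[position - 1] == aa:
            count += 1
    return count, total, count_to_percent(count, total)


def count_to_percent(count: int, total: int) -> float:
    """Convert a count/total pair to a percentage (0 when total == 0)."""
    if count < 0 or total < 0 or count > total:
        raise ValueError(f"inconsistent counts: {count}/{total}")
    return 100.0 * count / total if total else 0.0


def stratified_pomega1_profile(
    peptides: PeptideSet | Iterable[str], length: int, pomega_aa: str
) -> np.ndarray:
    """pΩ-1 frequency vector over peptides whose pΩ equals ``pomega_aa``.

    Conditioning the penultimate-position profile on the C-terminal
    anchor tests whether the size preference at pΩ-1 tightens for
    short pΩ anchors (e.g. Ala) relative to canonical ones (e.g. Leu).
    """
    pomega_aa = pomega_aa.upper()
    if pomega_aa not in AA_INDEX:
        raise ValueError(f"{pomega_aa!r} is not a standard amino acid")
    if isinstance(peptides, PeptideSet):
        seqs: Iterable[str] = (p for p in peptides.peptides if len(p) == length)
    else:
        seqs = peptides
    stratum = [s for s in seqs if len(s) == length and s[-1] == pomega_aa]
    if not stratum:
        raise ValueError(f"no {length}mers ending in {pomega_aa}")
    pfm = position_frequency_matrix(stratum, length)
    return pfm.row(length - 1)
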