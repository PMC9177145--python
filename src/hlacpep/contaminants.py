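"""Removal of background peptides matching contaminant allotype motifs.

Elution experiments in partially HLA-deficient cell lines carry a
residual background of peptides presented by the host line's own
allotypes (e.g. B*35:03 and C*04:01 in C1R cells).  Peptides aligning
with those motifs are removed before motif analysis.  Alignment is
scored as the mean per-position log2 likelihood of the peptide under
the contaminant's position frequency matrix; a peptide is removed when
its score under any supplied motif reaches that motif's threshold.
With no motifs supplied the filter is a no-op.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .alphabet import AA_INDEX
from .peptides import PeptideSet
from .pfm import PositionFrequencyMatrix

log = logging.getLogger(__name__)

#: Floor frequency when scoring, so zero cells stay finite.
MIN_FREQ = 1e-4


@dataclass(frozen=True)
class ContaminantMotif:
    """A contaminant allotype's motif: per-length PFMs plus a score cutoff.

    ``threshold`` is on the mean log2-likelihood-per-position scale;
    peptides scoring >= threshold under this motif are treated as
    contaminants.  A random peptide under a flat background scores
    log2(1/20) ~ -4.32 per position.
    """

    allotype_name: str
    pfms: dict[int, PositionFrequencyMatrix] = field(default_factory=dict)
    threshold: float = math.inf

    def __post_init__(self) -> None:
        if math.isnan(self.threshold):
            raise ValueError("threshold must not be NaN")
        for length, pfm in self.pfms.items():
            if pfm.length != length:
                raise ValueError(f"PFM keyed {length} has length {pfm.length}")

    def score(self, peptide: str) -> float:
        """Mean per-position log2 likelihood of ``peptide`` under the motif."""
        pfm = self.pfms.get(len(peptide))
        if pfm is None:
            raise ValueError(
                f"motif {self.allotype_name} has no PFM for length {len(peptide)}"
            )
        total = 0.0
        for pos, aa in enumerate(peptide):
            f = max(float(pfm.freqs[pos, AA_INDEX[aa]]), MIN_FREQ)
            total += math.log2(f)
        return total / len(peptide)


def filter_contaminant_motifs(
    peptide_set: PeptideSet, motifs: list[ContaminantMotif]
) -> tuple[PeptideSet, list[tuple[str, str, float]]]:
    """Remove peptides scoring at or above any contaminant motif threshold.

    Returns the filtered set and a removal log of
    ``(peptide, motif allotype, score)`` naming the motif responsible.
    Raising a threshold never removes more peptides (monotone filter).
    """
    removed: list[tuple[str, str, float]] = []
    kept: set[str] = set()
    for pep in peptide_set.peptides:
        hit = None
        for motif in motifs:
            s = motif.score(pep)
            if s >= motif.threshold:
                hit = (pep, motif.allotype_name, s)
                break
        if hit is None:
            kept.add(pep)
        else:
            removed.append(hit)
    if removed:
        log.info(
            "contaminant filter removed %d/%d peptides from %s",
            len(removed), len(peptide_set), peptide_set.allotype.name,
        )
    filtered = PeptideSet(
        allotype=peptide_set.allotype,
        peptides=frozenset(kept),
        sources={p: peptide_set.sources.get(p, ()) for p in kept},
    )
    return filtered, removed
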