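"""Group-level amino-acid enrichment between C1 and C2 allotype panels.

Frequencies are computed per allotype first and then averaged
unweighted within each group, so that a single deeply sampled allotype
cannot dominate the group mean (per-allotype peptide counts differ by
more than tenfold in real elution data).  Fold differences are formed
on pseudocounted frequencies (Haldane-Anscombe, +0.5 counts per cell)
so zero cells stay finite; raw means are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, N_AA
from .allotypes import AllotypeRecord, Group
from .pfm import PositionFrequencyMatrix
from .stats import benjamini_hochberg, pearson_r, student_t_pvalue, welch_t_pvalue
from .volumes import VolumeTable

log = logging.getLogger(__name__)

FOLD_THRESHOLD = 2.0
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-amino-acid C1-vs-C2 comparison at one peptide position.

    ``table`` columns: aa, mean_c1, mean_c2 (raw group means of the
    per-allotype frequencies), sd_c1, sd_c2, mean_c1_pc / mean_c2_pc
    (pseudocounted means used for ratios), fold_c2_c1, log2_fold,
    p_student, p_welch, q_bh, significant.  The significance flag is
    fold >= 2 or <= 0.5 together with p < 0.05 on the default test.
    """

    position: int
    table: pd.DataFrame
    n_c1: int
    n_c2: int
    test: str = "student"

    def row(self, aa: str) -> pd.Series:
        return self.table.set_index("aa").loc[aa.upper()]

    def flagged(self) -> list[str]:
        """Amino acids meeting the twofold + p<0.05 volcano thresholds."""
        return list(self.table.loc[self.table["significant"], "aa"])


def group_enrichment(
    panel: list[tuple[AllotypeRecord, PositionFrequencyMatrix]],
    position: int,
    pseudocount: float = 0.5,
    test: str = "student",
) -> EnrichmentTable:
    """Compare per-allotype amino-acid frequencies at one position across groups.

    Parameters
    ----------
    panel
        (allotype, PFM) pairs; HYBRID allotypes are excluded with a
        logged warning, and each group must retain at least two.
    position
        1-based peptide position (e.g. L for pΩ, L-1 for pΩ-1).
    pseudocount
        Counts added per cell before forming the frequencies used in
        the C2/C1 fold ratio.
    test
        "student" (equal variance; the volcano default) or "welch".
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {test!r}")
    freq_rows = {Group.C1: [], Group.C2: []}
    pc_rows = {Group.C1: [], Group.C2: []}
    for rec, pfm in panel:
        if rec.group is Group.HYBRID:
            log.warning("excluding HYBRID allotype %s from group enrichment", rec.name)
            continue
        counts = pfm.count_row(position)
        freq_rows[rec.group].append(counts / pfm.n)
        pc_rows[rec.group].append((counts + pseudocount) / (pfm.n + pseudocount * N_AA))
    for g in (Group.C1, Group.C2):
        if len(freq_rows[g]) < 2:
            raise ValueError(f"need at least 2 {g.value} allotypes, got {len(freq_rows[g])}")
    f1 = np.vstack(freq_rows[Group.C1])  # (n_c1, 20)
    f2 = np.vstack(freq_rows[Group.C2])
    pc1 = np.vstack(pc_rows[Group.C1]).mean(axis=0)
    pc2 = np.vstack(pc_rows[Group.C2]).mean(axis=0)

    mean1, mean2 = f1.mean(axis=0), f2.mean(axis=0)
    sd1 = f1.std(axis=0, ddof=1)
    sd2 = f2.std(axis=0, ddof=1)
    fold = pc2 / pc1
    p_student = np.array([student_t_pvalue(f1[:, j], f2[:, j]) for j in range(N_AA)])
    p_welch = np.array([welch_t_pvalue(f1[:, j], f2[:, j]) for j in range(N_AA)])
    p_flag = p_student if test == "student" else p_welch
    significant = ((fold >= FOLD_THRESHOLD) | (fold <= 1.0 / FOLD_THRESHOLD)) & (
        p_flag < P_THRESHOLD
    )
    table = pd.DataFrame(
        {
            "aa": list(AMINO_ACIDS),
            "mean_c1": mean1,
            "mean_c2": mean2,
            "sd_c1": sd1,
            "sd_c2": sd2,
            "mean_c1_pc": pc1,
            "mean_c2_pc": pc2,
            "fold_c2_c1": fold,
            "log2_fold": np.log2(fold),
            "p_student": p_student,
            "p_welch": p_welch,
            "q_bh": benjamini_hochberg(p_flag),
            "significant": significant,
        }
    )
    return EnrichmentTable(
        position=position, table=table, n_c1=f1.shape[0], n_c2=f2.shape[0], test=test
    )


def positionwise_correlation(
    pfm_a: PositionFrequencyMatrix, pfm_b: PositionFrequencyMatrix, position: int
) -> float:
    """Pearson r between two allotypes' 20-vector frequency profiles at a position."""
    if pfm_a.length != pfm_b.length:
        raise ValueError("PFMs must describe the same peptide length")
    return pearson_r(pfm_a.row(position), pfm_b.row(position))


def volume_correlation(
    enrichment: EnrichmentTable, volumes: VolumeTable | None = None
) -> tuple[float, pd.DataFrame]:
    """Correlate log2(C2/C1) enrichment with residue volume.

    Returns the Pearson r over the 20 amino acids and a scatter table
    (aa, volume, log2_fold) for plotting.  A positive r means the C2
    groove enriches for bulkier residues at the examined position.
    """
    if volumes is None:
        volumes = VolumeTable()
    vols = np.array(volumes.vector())
    log2_fold = enrichment.table["log2_fold"].to_numpy()
    if not np.all(np.isfinite(log2_fold)):
        raise ValueError("non-finite fold values; use a pseudocount > 0")
    r = pearson_r(vols, log2_fold)
    scatter = pd.DataFrame(
        {"aa": list(AMINO_ACIDS), "volume": vols, "log2_fold": log2_fold}
    )
    return r, scatter
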