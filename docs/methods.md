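# Methods

## Background and model

HLA-C allotypes split into two groups by a dimorphism at heavy-chain
positions 77 and 80: C1 (Ser77/Asn80) and C2 (Asn77/Lys80). Position
77 points into the peptide-binding groove and hydrogen-bonds the amide
of the terminal peptide bond; because Asn is larger than Ser, the
peptide's penultimate residue (pΩ-1) sits higher in the C2 groove than
in the C1 groove. The package quantifies the two observable
consequences: (i) sequence-level selection — C1 repertoires tolerate a
short C-terminal anchor (pΩ-Ala) and favor small residues at pΩ-1,
C2 repertoires favor bulky ones; (ii) structure-level displacement —
a ~1 Å difference in the Cβ(77)–Cα(pΩ-1) distance, loss of the
pΩ-1/Val76 van der Waals contact in C2, and a reoriented terminal
peptide-bond torsion.

Group assignment is exact: Ser77+Asn80 → C1, Asn77+Lys80 → C2, any
other combination (e.g. engineered point mutants such as N77S) →
HYBRID, which group-level statistics exclude with a warning.

## Sequence statistics

*Peptide sets.* Eluted-ligand lists are uppercased, validated against
the 20-letter alphabet (non-standard codes are an error naming the
input line), restricted to lengths 8–15 (out-of-range sequences are
dropped with a logged count), and deduplicated by exact string
equality within an allotype. Merging across studies is set union with
sorted provenance labels, hence idempotent and order-independent.
Analyses run on a fixed-length stratum; 9mers are the primary set.
Peptide abundance is deliberately ignored — every unique sequence
counts once.

*Contaminant filtering.* Lists produced in cell lines with residual
endogenous HLA carry background peptides. A contaminant motif is a
per-length PFM plus a threshold on the mean per-position log2
likelihood (frequencies floored at 1e-4); peptides scoring at or above
any motif's threshold are removed and logged with the motif
responsible. The scorer and threshold are deliberately exposed rather
than fixed: no published algorithm pins this step down, so the filter
defaults to off (no motifs supplied) and the threshold is a user
choice. A per-position log2 likelihood of −4.32 corresponds to a flat
background; thresholds around −3.5 are selective for motif-matching
peptides.

*Position frequency matrices.* Counts per (position, amino acid) over
an L-mer set, with relative frequencies; rows sum to 1. Conditional
(stratified) pΩ-1 profiles are computed over the subset of peptides
with a given pΩ residue; weighting the strata by size reconstructs
the unconditional profile exactly.

*Fisher's exact test.* Two-sided, probability-mass convention: with
margins fixed, the count in one group is hypergeometric, and the
p-value sums the probabilities of all tables at most as probable as
the observed one. The sum is accumulated in exact rational arithmetic
(`fractions.Fraction`), so tie handling needs no floating-point slack;
the result is symmetric under swapping the groups. scipy's
implementation serves as an independent cross-check in the tests.

*Group enrichment (volcano).* Frequencies are computed per allotype
first and averaged unweighted within each group — allotype set sizes
differ by more than tenfold, and pooling would let deep sets dominate.
The C2/C1 fold difference uses Haldane–Anscombe pseudocounts (+0.5
counts per cell, i.e. (k+0.5)/(n+10)) so zero cells stay finite; raw
means and SDs are reported alongside. Significance uses a two-sided
t-test across allotype-level frequencies — equal-variance Student by
default for the volcano, with the Welch p-value always reported in a
second column (group comparisons of single descriptors default to
Welch). The flag is fold ≥ 2 or ≤ 0.5 together with p < 0.05 on the
default test; Benjamini–Hochberg q-values are emitted for transparency
but do not drive the flags, matching the raw-p + fold-threshold
convention of the source analysis. Swapping the group labels inverts
every fold and leaves every p-value unchanged.

*Volume correlation.* Pearson r between log2(C2/C1) enrichment and
residue volume over the 20 amino acids. The volume scale is Zamyatnin
(1972) residue volumes (Å³), shipped in `volumes.py` with its
citation; the original analysis does not name its scale, so the
choice is documented rather than inferred.

## Structure descriptors

Structures are read with gemmi (PDB or mmCIF), first model only;
among alternate conformers the highest-occupancy atom wins, ties
broken toward altloc "A". When chain ids are not given, the peptide
chain is auto-detected as the shortest amino-acid chain of 8–11
residues (an exact tie is an error demanding explicit ids) and the
heavy chain as a chain of ≥ 180 residues containing author-numbered
residues 76, 77 and 171; an integer offset handles files whose heavy
chain does not start at 1.

- `d77_pomega1`: Euclidean distance from Cβ of heavy residue 77 to Cα
  of the peptide's penultimate residue. "Penultimate" generalizes p8:
  for a 10mer-bound structure it is p9.
- `d_tyr171_nterm`: distance from Tyr171's side-chain hydroxyl oxygen
  (standard atom name OH — the η-hydroxyl; descriptions of this
  contact sometimes write "Oγ") to the peptide p1 backbone N. Residue
  171 must be Tyr.
- `d_val76_side`: minimum over all pairs of side-chain heavy atoms
  (Cβ and beyond; N/Cα/C/O/OXT and hydrogens excluded) between pΩ-1
  and heavy residue 76. Glycine at either position leaves the
  descriptor undefined (NaN in panel output, with a log entry) rather
  than failing the structure.
- `omega_term` and `psi_pomega1`: signed dihedrals in (−180°, 180°],
  IUPAC sign convention (validated against gemmi's dihedral routine).
  ω = Cα(pΩ-1)–C(pΩ-1)–N(pΩ)–Cα(pΩ) ≈ 180° trans / 0° cis. Which of
  ω or ψ a given report of "the terminal peptide-bond torsion" means
  is ambiguous in prose; both are computed and ω is the default.

Panel statistics are unweighted per-group means and sample SDs with a
two-sided Welch t-test per descriptor; structures with an undefined
descriptor are excluded from that descriptor only. Two groups with
zero variance and unequal means make the t-test undefined and raise
rather than returning a fabricated p.

All distances are rigid-body invariant (tested to 1e-9 under random
rotations/translations); dihedral magnitudes are mirror-invariant with
sign flip.

## Synthetic data

*Peptide panels.* Each group has an effective per-position model built
from a baseline (background amino-acid frequencies with a p2 anchor
favoring Ala/Pro and a hydrophobic pΩ anchor dominated by Leu) by
(1) pinning the pΩ-Ala rate — defaults 1.45% (C1) and 0.27% (C2), the
group-level rates the sequence arm is meant to recover; (2) tilting
pΩ-1 by a size coefficient: log-frequency shift = ±coef × volume
z-score (C2 positive, C1 negative), default 0.25, which yields ~2–3
fold enrichment of the bulkiest residues — the scale of the real
effect; (3) optionally multiplying chosen (position, amino acid)
frequencies in C2 by a planted fold (an unrealizable product ≥ 1 is an
error). Per-allotype models are Dirichlet perturbations of the group
model with concentration 500 × frequency, giving between-allotype
scatter of the same order as real panels; peptides are independent
per-position draws, deduplicated to exactly the requested number of
unique sequences. An optional pΩ-conditional pΩ-1 shift emulates the
sharpened size preference of short-anchor peptides. Defaults follow
the study conditions: 14 C1 + 7 C2 allotypes, 1200 unique 9mers each.

What the generator does *not* emulate: positional couplings beyond the
single optional conditional, proteome-derived sequence composition,
abundance structure, and study-specific FDR artifacts. Passing tests
therefore demonstrate correctness of the estimators and statistics
under the stated model, not robustness to every property of real
immunopeptidomes; the unique/shared correlation of ~0.46 at p7
reported for real data, for instance, reflects couplings the generator
has no mechanism to produce.

*Toy structures.* Coordinate fixtures are built by direct geometric
construction: the four descriptor-defining atom groups are placed so
each descriptor equals its target exactly at zero noise (the terminal
backbone via internal-coordinate placement with the target ω), and the
rest of the heavy chain is a glycine-backbone lattice placed far from
the peptide. The heavy chain is a geometric stub, not a folded MHC
model — descriptor tests need geometry, not physics. Files are written
as mmCIF by default: the fixed-width PDB format truncates coordinates
to 3 decimals, which alone perturbs dihedrals by ~0.01–0.02°, while
mmCIF keeps ~8 significant digits; torsion-critical atoms are placed
near the origin, bounding the worst file round-trip error below 1e-6
in the tested target range. Gaussian placement noise (Å) can be added
for realistic panels. Identical spec + seed reproduces files byte for
byte.

## Pipeline

`run_peptidome_analysis` validates the whole configuration before
computing, then emits per-allotype PFM CSVs, the pΩ frequency table,
the pair Fisher comparison, volcano tables at pΩ and pΩ-1, the
unique/shared partition with position-wise correlations (falling back
to full-stratum correlation with a warning when the unique fractions
are empty, e.g. identical inputs), the volume correlation, and a
machine-readable run log in which every input row is accounted for:
rows read = kept + duplicates removed + length-dropped + contaminant-
removed, per allotype. Reports are schema-validated CSVs plus one
JSON; output bytes are identical across reruns of the same config and
seed (the run log's timestamp is the only exception, isolated to one
key). `run_geometry_analysis` isolates per-row failures: a bad
manifest row is recorded and the run continues, erroring only if all
rows fail; group statistics are skipped with a warning when a group
has fewer than two structures. CLI exit codes: 0 success, 1 validation
error, 2 partial failure.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on generated data.
Recovery and detection checks use 6+6 allotypes × 1000 peptides over
20 seeded replicates (the planted effect is 2.5-fold — strictly beyond
the twofold flag threshold, since an effect exactly at the threshold
is detected only half the time by construction); the study-condition
panel is 21 allotypes × 1200 peptides, and group-level rate recovery
averages 10 replicate panels because the per-allotype rates are
strongly skewed (as in real panels, where group SDs rival the means).
Per-cell PFM recovery is asserted as ≥ 99% of cells within 3
multinomial standard errors plus mean absolute error < 0.01 — with 180
cells, demanding every cell inside 3σ would fail by chance in a large
fraction of honest runs. Exhaustive Fisher validation covers all 2×2
tables with total ≤ 40 against an independent enumeration oracle at
1e-12.

## Known limitations

- The contaminant filter is a stand-in for an unspecified published
  procedure; results depending on aggressive background removal (full
  reconstruction of archived study repertoires) are integration goals,
  not covered by the hermetic suite.
- Chain auto-detection assumes a classical MHC-I heavy chain with
  author numbering near canonical positions; single-chain constructs
  or renumbered files need explicit chain ids and/or the numbering
  offset.
- The enrichment t-tests treat allotypes as independent replicates;
  phylogenetic relatedness between allotypes of the same serological
  family is not modelled.
- Volume correlation uses one residue-volume scale; rank-level
  conclusions are insensitive to the common alternatives, exact r
  values are not.
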