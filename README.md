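# hlacpep

Analysis of how the HLA-C **C1/C2 dimorphism** — Ser77/Asn80 (C1) vs
Asn77/Lys80 (C2) at the peptide-binding groove — shapes the peptides
HLA-C presents, at the sequence level and at the structural level.

The package is written for immunopeptidomics and structural-immunology
work: people comparing eluted-ligand repertoires between HLA-C
allotypes, or measuring peptide–MHC groove geometry across crystal
structures.

## What it computes

**Sequence arm.** From per-allotype eluted-peptide lists (merged and
deduplicated across studies) it builds per-position amino-acid
frequency matrices (PFMs) and compares allotype groups:

- frequency of an amino acid *a* at position *p* among *n* L-mers,
  `f = k/n`, with a two-sided Fisher's exact test (probability-mass
  convention, exact rational arithmetic) for comparing counts between
  two allotypes;
- a C1-vs-C2 enrichment "volcano" at the C-terminal anchor pΩ and the
  penultimate position pΩ-1: unweighted group means of per-allotype
  frequencies, C2/C1 fold difference on Haldane–Anscombe pseudocounted
  frequencies, and two-sided Student (or Welch) t-tests across
  allotypes; an amino acid is flagged when fold ≥ 2 (or ≤ 0.5) and
  p < 0.05;
- position-wise Pearson correlation of the repertoires unique to two
  allotypes, and the Pearson correlation of log2(C2/C1) enrichment
  with residue volume (Zamyatnin scale), which quantifies the side-chain
  size constraint C1 grooves impose at pΩ-1.

**Structure arm.** From peptide–MHC coordinate files (PDB/mmCIF, via
gemmi) it measures four groove descriptors per structure and compares
C1 vs C2 panels with Welch t-tests:

- `d77_pomega1` — Cβ(77) to Cα(pΩ-1) distance;
- `d_tyr171_nterm` — Tyr171 hydroxyl O to peptide p1 N (conserved
  A-pocket contact, an internal control);
- `d_val76_side` — minimum side-chain heavy-atom distance between
  pΩ-1 and residue 76;
- `omega_term` — the ω torsion of the terminal peptide bond
  (Cα(pΩ-1)–C(pΩ-1)–N(pΩ)–Cα(pΩ)), with ψ(pΩ-1) reported alongside.

A seeded **synthetic-data generator** produces peptide panels from
position-frequency models with known group effects, and toy coordinate
files whose descriptors equal chosen targets exactly, so the whole
pipeline is testable offline with ground truth.

## Worked example

```bash
python examples/pomega_ala_counts.py
```

```
C*08:02 9mers: pΩ-Ala in 30/1986 = 1.51%
C*05:01 9mers: pΩ-Ala in 1/732 = 0.14%
C*08:02 10mers: pΩ-Ala in 5/349 = 1.43%
C*05:01 10mers: pΩ-Ala in 0/152 = 0.00%

Fisher's exact test, 9mer pΩ-Ala C*08:02 vs C*05:01: p = 0.0016
```

The two allotypes are identical except for the C1/C2 residues, yet the
C1 allotype presents C-terminal-alanine peptides an order of magnitude
more often — the short Ala anchor is tolerated only by the C1 groove.

The other examples each run one capability end to end and print what
the numbers mean: `examples/synthetic_volcano.py` (group enrichment at
pΩ-1 plus the volume correlation, r ≈ 0.99 on the synthetic panel),
`examples/groove_geometry.py` (a 12-structure toy panel giving
C1 4.69 ± 0.10 Å vs C2 5.66 ± 0.11 Å for `d77_pomega1`, Welch
p ≈ 3e-08), and `examples/unique_shared_correlation.py` (position-wise
r ≈ 0.8 everywhere except pΩ-1, which decorrelates).

There is also a thin CLI:

```bash
hlacpep synth-panel --out panel.csv --seed 1
hlacpep peptidome --peptides panel.csv --allotypes allotypes.csv --out results/
hlacpep geometry --manifest structures.csv --out results/
```

Real deposited structures can be analyzed by listing accessions/paths
in the manifest; `--fetch` (off by default) downloads missing entries
from RCSB.

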