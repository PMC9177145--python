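"""C1-vs-C2 enrichment volcano on a synthetic immunopeptidome panel.

Samples a 21-allotype panel (14 C1, 7 C2) under the package's default
study conditions, builds per-allotype position frequency matrices, and
runs the group enrichment at pΩ-1 (p8 of a 9mer), where the C1/C2
groove difference imposes a side-chain size constraint.
"""

from hlacpep import GeneratorSpec, group_enrichment, sample_peptide_panel, volume_correlation

sample = sample_peptide_panel(GeneratorSpec(seed=0))
panel = sample.panel_pfms()
print(f"sampled {len(panel)} allotypes x {panel[0][1].n} unique 9mers each")

table = group_enrichment(panel, position=8)
flagged = table.table[table.table["significant"]]
print("\namino acids with >=2-fold C1/C2 difference and p < 0.05 at pΩ-1:")
print(
    flagged[["aa", "mean_c1", "mean_c2", "fold_c2_c1", "p_student"]]
    .to_string(index=False, float_format=lambda v: f"{v:.4g}")
)

r, _ = volume_correlation(table)
print(f"\nPearson r between residue volume and log2(C2/C1) enrichment: {r:.2f}")
print(
    "A strong positive r means bulky residues are enriched at pΩ-1 in C2\n"
    "allotypes and depleted in C1 — the size selection the groove imposes."
)
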