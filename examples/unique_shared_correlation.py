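"""Position-wise correlation of two allotypes' unique peptide repertoires.

Partitions two synthetic allotypes' 9mer sets into unique and shared
fractions and correlates their amino-acid frequency profiles position
by position — high r at most positions, low r where the groove
difference reshapes usage (pΩ-1).
"""

from hlacpep import (
    GeneratorSpec,
    partition_unique_shared,
    position_frequency_matrix,
    positionwise_correlation,
    sample_peptide_panel,
)

sample = sample_peptide_panel(
    GeneratorSpec(n_c1=1, n_c2=1, peptides_per_allotype=3000, size_coef=0.6, seed=4)
)
(rec_a, set_a), (rec_b, set_b) = sample.records
unique_a, unique_b, shared = partition_unique_shared(set_a, set_b, 9)
print(
    f"{rec_a.name} vs {rec_b.name}: {len(unique_a)} unique / "
    f"{len(unique_b)} unique / {len(shared)} shared 9mers"
)

pfm_a = position_frequency_matrix(unique_a, 9)
pfm_b = position_frequency_matrix(unique_b, 9)
print("\nposition-wise Pearson r between the unique fractions:")
for pos in range(1, 10):
    r = positionwise_correlation(pfm_a, pfm_b, pos)
    print(f"  p{pos}: r = {r:+.2f}")
print(
    "\nPositions with shared selection correlate strongly; the penultimate\n"
    "position (p8), where the C1/C2 size preference acts in opposite\n"
    "directions, decorrelates."
)
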