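"""The 20-letter amino-acid alphabet used throughout the package.

Sequences are restricted to the 20 standard residues; ambiguity and
non-standard codes (B, J, O, U, X, Z) are rejected at ingestion so that
position-frequency matrices are always 20 columns wide.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = len(AMINO_ACIDS)

#: Sequence lengths retained for analysis (eluted-ligand length range).
MIN_LENGTH: int = 8
MAX_LENGTH: int = 15


def is_valid_peptide(seq: str) -> bool:
    """True if ``seq`` is non-empty and uses only the 20 standard letters."""
    return bool(seq) and all(c in AA_INDEX for c in seq)
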