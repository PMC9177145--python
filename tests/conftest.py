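import pytest

from hlacpep.allotypes import AllotypeRecord
from hlacpep.peptides import peptide_set
from hlacpep.synth import GeneratorSpec, ToyStructureSpec, build_toy_structure, sample_peptide_panel


@pytest.fixture(scope="session")
def c1_record() -> AllotypeRecord:
    return AllotypeRecord.from_residues("C*08:02", "S", "N")


@pytest.fixture(scope="session")
def c2_record() -> AllotypeRecord:
    return AllotypeRecord.from_residues("C*05:01", "N", "K")


@pytest.fixture
def make_set(c1_record):
    def _make(seqs, allotype=None, source="test"):
        return peptide_set(allotype or c1_record, seqs, source)

    return _make


@pytest.fixture
def toy_structure(tmp_path):
    """Factory: build a toy structure file and return its path."""

    def _build(**kwargs):
        spec = ToyStructureSpec(**kwargs)
        return build_toy_structure(spec, tmp_path / f"toy_{abs(hash(tuple(sorted(kwargs.items()))))}.cif")

    return _build


@pytest.fixture(scope="session")
def small_panel():
    """A small seeded synthetic panel shared across read-only tests."""
    spec = GeneratorSpec(n_c1=4, n_c2=4, peptides_per_allotype=500, seed=11)
    return sample_peptide_panel(spec)
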