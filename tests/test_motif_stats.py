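"""Position frequencies, exact count tests and group enrichment statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlacpep.alphabet import AA_INDEX, AMINO_ACIDS
from hlacpep.allotypes import AllotypeRecord
from hlacpep.enrichment import (
    EnrichmentTable,
    group_enrichment,
    positionwise_correlation,
    volume_correlation,
)
from hlacpep.pfm import (
    PositionFrequencyMatrix,
    count_to_percent,
    position_frequency_matrix,
    residue_frequency,
    stratified_pomega1_profile,
)
from hlacpep.stats import fisher_count_test, pearson_r
from hlacpep.synth import GeneratorSpec, sample_peptide_panel
from hlacpep.volumes import ZAMYATNIN_1972, VolumeTable


def fisher_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Independent enumeration oracle for the two-sided exact test.

    Enumerates every 2x2 table with the observed margins, computing each
    table's conditional probability as the number of ways to place the
    successes and failures into group 1 over all placements.
    """
    n, m = n1 + n2, k1 + k2
    denom = comb(n, n1)
    tables = {}
    for a in range(max(0, m - n2), min(n1, m) + 1):
        tables[a] = Fraction(comb(m, a) * comb(n - m, n1 - a), denom)
    p_obs = tables[k1]
    return float(sum(p for p in tables.values() if p <= p_obs))


class TestPFM:
    def test_degenerate_polyalanine(self, make_set):
        ps = make_set(["AAAAAAAAA"])
        pfm = position_frequency_matrix(ps, 9)
        assert pfm.n == 1
        for pos in range(1, 10):
            assert pfm.frequency(pos, "A") == 1.0

    def test_single_neoantigen_sequence(self):
        pfm = position_frequency_matrix(["GADGVGKSA"], 9)
        assert pfm.frequency(1, "G") == 1.0
        assert pfm.frequency(3, "D") == 1.0
        assert pfm.frequency(9, "A") == 1.0

    def test_rows_sum_to_one_and_counts_to_n(self, small_panel):
        _, ps = small_panel.records[0]
        pfm = position_frequency_matrix(ps, 9)
        assert np.allclose(pfm.freqs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pfm.counts.sum(axis=1) == pfm.n)

    def test_recovery_within_multinomial_error(self):
        # 2000 draws from a known per-position model; every cell within
        # 3 standard multinomial errors and MAE < 0.01
        rng = np.random.default_rng(42)
        true = rng.dirichlet(np.full(20, 5.0), size=9)
        n = 2000
        seqs = [
            "".join(AMINO_ACIDS[j] for j in (rng.choice(20, p=true[pos]) for pos in range(9)))
            for _ in range(n)
        ]
        pfm = position_frequency_matrix(seqs, 9)
        se = np.sqrt(true * (1 - true) / n)
        z = np.abs(pfm.freqs - true) / se
        # per-cell 3-sigma coverage: ~99.7% expected over the 180 cells
        assert np.mean(z <= 3.0) >= 0.99
        assert z.max() < 4.5
        assert np.mean(np.abs(pfm.freqs - true)) < 0.01

    def test_empty_stratum_is_error(self, make_set):
        with pytest.raises(ValueError):
            position_frequency_matrix(make_set(["AAAAAAAAAL"]), 9)


class TestResidueFrequency:
    def test_percent_conversion_of_study_counts(self):
        assert count_to_percent(30, 1986) == pytest.approx(1.5106, abs=1e-4)
        assert round(count_to_percent(30, 1986), 1) == 1.5
        assert count_to_percent(5, 349) == pytest.approx(1.4327, abs=1e-4)
        assert round(count_to_percent(5, 349), 1) == 1.4
        assert count_to_percent(1, 732) == pytest.approx(0.1366, abs=1e-4)

    def test_on_constructed_set(self, make_set):
        seqs = [f"AAAAAAAA{aa}" for aa in "CDEF"] + ["AAAAAAAAA"]
        k, n, pct = residue_frequency(make_set(seqs), 9, 9, "A")
        assert (k, n) == (1, 5)
        assert pct == 20.0

    def test_absent_residue(self, make_set):
        k, n, pct = residue_frequency(make_set(["AAAAAAAAC"]), 9, 9, "W")
        assert (k, n, pct) == (0, 1, 0.0)

    def test_position_out_of_range(self, make_set):
        with pytest.raises(ValueError):
            residue_frequency(make_set(["AAAAAAAAC"]), 9, 10, "A")


class TestFisher:
    def test_reproduces_pomega_ala_comparison(self):
        # 30/1986 vs 1/732 pΩ-Ala 9mers
        p = fisher_count_test(30, 1986, 1, 732)
        assert float(f"{p:.2g}") == 0.0016

    def test_equal_proportions_give_one(self):
        assert fisher_count_test(5, 10, 5, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(5, 10, 0, 10), (3, 8, 7, 9), (0, 4, 4, 4)])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_count_test(*table) == pytest.approx(fisher_oracle(*table), abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(7)
        for _ in range(40):
            n1, n2 = rng.integers(1, 60, 2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            ours = fisher_count_test(k1, n1, k2, n2)
            ref = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_symmetric_under_group_swap(self, data):
        n1 = data.draw(st.integers(0, 25))
        n2 = data.draw(st.integers(0, 25))
        if n1 + n2 == 0:
            return
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        assert fisher_count_test(k1, n1, k2, n2) == fisher_count_test(k2, n2, k1, n1)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_count_test(5, 3, 0, 10)


def _pfm_from_seqs(seqs):
    return position_frequency_matrix(seqs, len(seqs[0]))


def _swap_groups(panel):
    swapped = []
    for rec, pfm in panel:
        residues = ("N", "K") if rec.group.value == "C1" else ("S", "N")
        swapped.append((AllotypeRecord.from_residues(rec.name + "_sw", *residues), pfm))
    return swapped


class TestGroupEnrichment:
    def test_identical_groups_are_null(self):
        seqs = ["AAAWAAAAK", "CCDEFGHIK", "AAAWAAAAL", "DDDWAAAAK"]
        pfm = _pfm_from_seqs(seqs)
        panel = [
            (AllotypeRecord.from_residues(f"C1-{i}", "S", "N"), pfm) for i in range(2)
        ] + [(AllotypeRecord.from_residues(f"C2-{i}", "N", "K"), pfm) for i in range(2)]
        table = group_enrichment(panel, 9)
        assert np.allclose(table.table["fold_c2_c1"], 1.0)
        assert np.allclose(table.table["p_student"], 1.0)
        assert not table.flagged()

    def test_planted_excess_recovered_and_flagged(self):
        # 2.5x C2 excess of Lys at p8, 6+6 allotypes, 1000 peptides each
        spec = GeneratorSpec(
            n_c1=6, n_c2=6, peptides_per_allotype=1000, size_coef=0.0,
            planted_c2={(8, "K"): 2.5}, seed=5,
        )
        panel = sample_peptide_panel(spec).panel_pfms()
        table = group_enrichment(panel, 8)
        row = table.row("K")
        assert row["significant"]
        assert row["fold_c2_c1"] == pytest.approx(2.5, rel=0.2)

    def test_fold_inverts_and_p_invariant_under_label_swap(self, small_panel):
        panel = small_panel.panel_pfms()
        t1 = group_enrichment(panel, 8)
        t2 = group_enrichment(_swap_groups(panel), 8)
        assert np.allclose(t1.table["fold_c2_c1"], 1.0 / t2.table["fold_c2_c1"])
        assert np.allclose(t1.table["p_student"], t2.table["p_student"])
        assert np.allclose(t1.table["p_welch"], t2.table["p_welch"])

    def test_hybrid_excluded_and_small_groups_rejected(self, small_panel, caplog):
        panel = small_panel.panel_pfms()
        hybrid = (AllotypeRecord.from_residues("MUT", "S", "K"), panel[0][1])
        with caplog.at_level("WARNING"):
            table = group_enrichment(panel + [hybrid], 9)
        assert "MUT" in caplog.text
        assert table.n_c1 + table.n_c2 == len(panel)
        with pytest.raises(ValueError, match="at least 2"):
            group_enrichment(panel[:3], 9)  # only one C2 left


class TestPositionwiseCorrelation:
    def test_identity_is_one(self):
        pfm = _pfm_from_seqs(["AAAWAAAAK", "CCDEFGHIK"])
        assert positionwise_correlation(pfm, pfm, 5) == pytest.approx(1.0)

    def test_hand_computed_disjoint_vectors(self):
        # p1 profiles (.5,.5,0,...) vs (0,0,.5,.5,0,...): r = -1/9
        a = _pfm_from_seqs(["AAAAAAAAA"] * 5 + ["CAAAAAAAA"] * 5)
        b = _pfm_from_seqs(["DAAAAAAAA"] * 5 + ["EAAAAAAAA"] * 5)
        assert positionwise_correlation(a, b, 1) == pytest.approx(-1 / 9, abs=1e-12)

    def test_zero_variance_is_error(self):
        # uniform p1 usage: all 20 frequencies equal, r undefined
        flat = _pfm_from_seqs([aa + "AAAAAAAA" for aa in AMINO_ACIDS])
        other = _pfm_from_seqs(["AAAWAAAAK", "CCDEFGHIK"])
        with pytest.raises(ValueError, match="zero variance"):
            positionwise_correlation(flat, other, 1)

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = pearson_r(x, y)
        assert pearson_r(3.0 * x + 7.0, y) == pytest.approx(r, abs=1e-12)
        assert pearson_r(x, 0.01 * y - 5.0) == pytest.approx(r, abs=1e-12)
        assert pearson_r(-2.0 * x, y) == pytest.approx(-r, abs=1e-12)


def _table_from_log2fold(log2_fold):
    df = pd.DataFrame({"aa": list(AMINO_ACIDS), "log2_fold": log2_fold})
    return EnrichmentTable(position=8, table=df, n_c1=2, n_c2=2)


class TestVolumeCorrelation:
    def test_perfect_linear_dependence(self):
        vols = np.array(VolumeTable().vector())
        r, scatter = volume_correlation(_table_from_log2fold(0.01 * vols - 1.0))
        assert r == pytest.approx(1.0)
        assert list(scatter.columns) == ["aa", "volume", "log2_fold"]

    def test_permuted_enrichment_mostly_uncorrelated(self):
        rng = np.random.default_rng(9)
        vols = np.array(VolumeTable().vector())
        base = 0.02 * (vols - vols.mean())
        hits = sum(
            abs(volume_correlation(_table_from_log2fold(rng.permutation(base)))[0]) < 0.5
            for _ in range(100)
        )
        assert hits >= 95

    def test_size_linked_planting_gives_positive_r(self):
        # double every large residue (>100 A^3) in C2 at p8
        large = [aa for aa in AMINO_ACIDS if ZAMYATNIN_1972[aa] > 100.0]
        spec = GeneratorSpec(
            n_c1=4, n_c2=4, peptides_per_allotype=800, size_coef=0.0,
            planted_c2={(8, aa): 1.6 for aa in large}, seed=13,
        )
        panel = sample_peptide_panel(spec).panel_pfms()
        r, _ = volume_correlation(group_enrichment(panel, 8))
        assert r > 0.1

    def test_nonfinite_fold_rejected(self):
        bad = np.zeros(20)
        bad[0] = np.inf
        with pytest.raises(ValueError):
            volume_correlation(_table_from_log2fold(bad))


class TestStratifiedProfile:
    def test_constructed_stratum(self, make_set):
        ps = make_set(["AAAAAAASA", "CCDEFGHSA", "AAAAAAALL"])
        profile = stratified_pomega1_profile(ps, 9, "A")
        assert profile[AA_INDEX["S"]] == 1.0

    def test_single_neoantigen(self):
        profile = stratified_pomega1_profile(["GADGVGKSA"], 9, "A")
        assert profile[AA_INDEX["S"]] == 1.0

    def test_convex_reconstruction_of_unstratified_profile(self, small_panel):
        _, ps = small_panel.records[0]
        pfm = position_frequency_matrix(ps, 9)
        total = np.zeros(20)
        for aa in AMINO_ACIDS:
            k = int(pfm.count_row(9)[AA_INDEX[aa]])
            if k == 0:
                continue
            total += k * stratified_pomega1_profile(ps, 9, aa)
        assert np.allclose(total / pfm.n, pfm.row(8), atol=1e-12)

    def test_empty_stratum_is_error(self, make_set):
        with pytest.raises(ValueError):
            stratified_pomega1_profile(make_set(["AAAAAAAAL"]), 9, "W")
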