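import numpy as np
import pytest

from conftest import make_table
from oracles import grid_search_haplotype_ml, random_mating_table
from slco1b1.haplotypes import (
    HAPLOTYPE_NAMES,
    HaplotypeFrequencies,
    TwoLocusCounts,
    assign_diplotype,
    em_haplotype_frequencies,
    haplotype_frequency_se,
    haplotype_frequency_table,
    star_allele,
    two_locus_counts,
)


class TestStarAllele:
    @pytest.mark.parametrize(
        "a388,a521,name,cls",
        [
            ("A", "T", "*1a", "functional"),
            ("G", "T", "*1b", "functional"),
            ("A", "C", "*5", "reduced"),
            ("G", "C", "*15", "reduced"),
        ],
    )
    def test_four_combinations(self, a388, a521, name, cls):
        s = star_allele(a388, a521)
        assert s.name == name and s.functional_class == cls

    def test_reduced_iff_521c(self):
        for a388 in "AG":
            assert star_allele(a388, "C").functional_class == "reduced"
            assert star_allele(a388, "T").functional_class == "functional"

    def test_invalid_nucleotides(self):
        with pytest.raises(ValueError):
            star_allele("T", "T")
        with pytest.raises(ValueError):
            star_allele("A", "G")


class TestTwoLocusCounts:
    def test_diagonal_example(self):
        t = make_table([(0, 0), (1, 1), (2, 2)])
        c = two_locus_counts(t)
        assert c.n[0, 0] == c.n[1, 1] == c.n[2, 2] == 1 and c.n.sum() == 3

    def test_empty_group(self):
        t = make_table([(0, 0, "g1")], groups=["g1", "g2"])
        assert two_locus_counts(t, "g2").n.sum() == 0

    def test_missing_excluded_and_tallied(self, sim_cohort):
        table = sim_cohort["table"]
        c = two_locus_counts(table, "Total")
        both_observed = sum(
            1 for s in table.samples if s.dosage_388 is not None and s.dosage_521 is not None
        )
        assert c.n_samples == both_observed
        assert c.n_samples + c.n_missing == len(table.samples)


class TestEm:
    def test_no_double_het_is_direct_gamete_count(self):
        # all phases forced: EM must land on direct counting immediately
        n = np.zeros((3, 3), dtype=int)
        n[0, 0], n[1, 0], n[2, 1], n[1, 2] = 4, 2, 3, 1
        hf = em_haplotype_frequencies(TwoLocusCounts(n))
        total = 2 * n.sum()
        expected = np.array([4 * 2 + 2, 2 + 3, 1, 3 + 1]) / total
        assert hf.as_array() == pytest.approx(expected, abs=1e-12)
        assert hf.converged

    def test_homozygote_only_table(self):
        n = np.zeros((3, 3), dtype=int)
        n[0, 0], n[2, 2] = 30, 10
        hf = em_haplotype_frequencies(TwoLocusCounts(n))
        assert hf.as_array() == pytest.approx([0.75, 0, 0, 0.25], abs=1e-12)

    def test_marginal_allele_frequency_conservation_each_iterate(self):
        rng = np.random.default_rng(5)
        f = np.array([0.3, 0.3, 0.1, 0.3])
        n = random_mating_table(rng, f, 150)
        tlc = TwoLocusCounts(n)
        p_g = (n[1, :].sum() + 2 * n[2, :].sum()) / (2 * n.sum())
        p_c = (n[:, 1].sum() + 2 * n[:, 2].sum()) / (2 * n.sum())
        for k in (1, 2, 3, 5, 10, 40):
            hf = em_haplotype_frequencies(tlc, tol=0.0, max_iter=k)
            assert hf.f_1b + hf.f_15 == pytest.approx(p_g, abs=1e-12)
            assert hf.f_5 + hf.f_15 == pytest.approx(p_c, abs=1e-12)

    def test_monotone_loglik(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = random_mating_table(rng, rng.dirichlet([1, 1, 1, 1]), 120)
            if n.sum() == 0:
                continue
            tlc = TwoLocusCounts(n)
            lls = [
                em_haplotype_frequencies(tlc, tol=0.0, max_iter=k).loglik for k in range(1, 25)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = random_mating_table(rng, rng.dirichlet([1, 1, 1, 1]), int(rng.integers(20, 201)))
            hf = em_haplotype_frequencies(TwoLocusCounts(n))
            gf, gll = grid_search_haplotype_ml(n)
            assert np.max(np.abs(hf.as_array() - gf)) < 1e-3
            assert abs(hf.loglik - gll) < 1e-6

    def test_non_identifiable_double_het_only(self):
        n = np.zeros((3, 3), dtype=int)
        n[1, 1] = 12
        hf = em_haplotype_frequencies(TwoLocusCounts(n))
        assert hf.converged
        assert any("non-identifiable" in w for w in hf.warnings)
        assert hf.as_array() == pytest.approx([0.25] * 4, abs=1e-12)

    def test_zero_phase_denominator_splits_half(self):
        n = np.zeros((3, 3), dtype=int)
        n[1, 1], n[0, 0] = 2, 2
        hf = em_haplotype_frequencies(TwoLocusCounts(n), init=(0.5, 0.5, 0.0, 0.0))
        assert any("50/50" in w for w in hf.warnings)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            em_haplotype_frequencies(TwoLocusCounts(np.zeros((3, 3), dtype=int)))

    def test_se_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        f = np.array([0.25, 0.35, 0.1, 0.3])
        ses = []
        for n_samples in (200, 5000):
            tlc = TwoLocusCounts(random_mating_table(rng, f, n_samples))
            hf = em_haplotype_frequencies(tlc)
            ses.append(haplotype_frequency_se(tlc, hf))
        assert (ses[1] < ses[0]).all()


class TestAssignDiplotype:
    def test_forced_phases(self):
        f = HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25)
        assert assign_diplotype(0, 0, f).name == "*1a/*1a"
        assert assign_diplotype(2, 1, f).name == "*1b/*15"
        assert assign_diplotype(0, 0, f).phase_posterior == 1.0
        assert not assign_diplotype(2, 1, f).ambiguous

    def test_double_het_posterior_published_frequencies(self):
        f = HaplotypeFrequencies(0.2324, 0.3495, 0.0381, 0.38)
        d = assign_diplotype(1, 1, f)
        assert d.name == "*1a/*15" and d.ambiguous
        expected = (0.2324 * 0.38) / (0.2324 * 0.38 + 0.3495 * 0.0381)
        assert d.phase_posterior == pytest.approx(expected)
        assert round(d.phase_posterior, 3) == 0.869

    def test_double_het_trans_phase_wins(self):
        f = HaplotypeFrequencies(0.05, 0.45, 0.45, 0.05)
        d = assign_diplotype(1, 1, f)
        assert d.name == "*1b/*5"

    def test_tie_and_degenerate_go_to_1a_15(self):
        f = HaplotypeFrequencies(0.3, 0.3, 0.2, 0.2)  # 0.06 == 0.06
        assert assign_diplotype(1, 1, f).name == "*1a/*15"
        f0 = HaplotypeFrequencies(0.5, 0.0, 0.0, 0.5)
        d = assign_diplotype(1, 1, HaplotypeFrequencies(0.0, 0.5, 0.5, 0.0))
        assert d.name == "*1b/*5"
        assert assign_diplotype(1, 1, f0).name == "*1a/*15"

    def test_double_het_always_one_reduced_allele(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = rng.dirichlet([1, 1, 1, 1])
            f = HaplotypeFrequencies(*a)
            assert assign_diplotype(1, 1, f).n_reduced() == 1

    def test_missing_dosage_rejected(self):
        f = HaplotypeFrequencies(0.25, 0.25, 0.25, 0.25)
        with pytest.raises(ValueError):
            assign_diplotype(None, 1, f)


class TestFrequencyTable:
    def test_published_star5_percentage(self):
        f = HaplotypeFrequencies(1 - 80 / 2100, 0.0, 80 / 2100, 0.0)
        rows = haplotype_frequency_table({"Total": f}, {"Total": 2100})
        row5 = next(r for r in rows if r["row"] == "*5")
        assert round(row5["Total"], 2) == 3.81
        assert row5["Total_expected_count"] == pytest.approx(80.0)

    def test_degenerate_single_haplotype(self):
        f = HaplotypeFrequencies(1.0, 0.0, 0.0, 0.0)
        rows = haplotype_frequency_table({"g": f}, {"g": 100})
        assert [r["g"] for r in rows] == [100.0, 0.0, 0.0, 0.0]

    def test_percentages_sum_to_100(self):
        f = HaplotypeFrequencies(0.2324, 0.3495, 0.0381, 0.38)
        rows = haplotype_frequency_table({"g": f}, {"g": 2100})
        assert sum(r["g"] for r in rows) == pytest.approx(100.0, abs=1e-9)
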