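"""Diversity, equilibrium and differentiation estimators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

import pangotrace as pt
from pangotrace.core import AlleleFrequencyTable


def _table(genos, loci=None):
    genos = np.asarray(genos)
    if genos.ndim == 2:
        genos = genos[:, None, :]
    ids = [f"s{i}" for i in range(len(genos))]
    loci = loci or [f"L{j}" for j in range(genos.shape[1])]
    return pt.GenotypeTable(ids, loci, genos)


def _one_pop(table):
    return pt.PopulationMap({"p": list(table.individuals)})


class TestDiversity:
    def test_ho_he_on_balanced_two_allele_locus(self):
        # allele frequencies 0.5/0.5, half the genotypes heterozygous
        t = _table([[100, 102], [100, 100], [100, 102], [102, 102]])
        s = pt.diversity(t, _one_pop(t)).per_population
        assert s.loc["p", "Ho"] == pytest.approx(0.5)
        assert s.loc["p", "He"] == pytest.approx(0.5)

    def test_unbiased_correction_at_n_two(self):
        # two opposite homozygotes: He = 0.5, uHe = (2n/(2n-1)) He = 2/3
        t = _table([[100, 100], [102, 102]])
        s = pt.diversity(t, _one_pop(t)).per_population
        assert s.loc["p", "He"] == pytest.approx(0.5)
        assert s.loc["p", "uHe"] == pytest.approx(4 / 3 * 0.5)

    def test_monomorphic_locus(self):
        t = _table([[100, 100], [100, 100]])
        s = pt.diversity(t, _one_pop(t)).per_population
        assert s.loc["p", "Ho"] == 0 and s.loc["p", "He"] == 0
        assert s.loc["p", "Na"] == 1

    def test_uhe_at_least_he(self, small_table):
        part = pt.PopulationMap.from_metadata(small_table)
        s = pt.diversity(small_table, part).per_population
        assert (s["uHe"] >= s["He"] - 1e-12).all()


class TestAllelicRichness:
    def _aft(self, counts):
        aft = AlleleFrequencyTable(["p"], ["L"])
        aft._counts[("p", "L")] = counts
        return aft

    def test_two_by_two_enumeration_value(self):
        ar = pt.allelic_richness(self._aft({1: 2, 2: 2}), 2)
        assert ar[("p", "L")] == pytest.approx(5 / 3)

    def test_full_sample_equals_observed_allele_count(self):
        ar = pt.allelic_richness(self._aft({1: 3, 2: 2, 3: 1}), 6)
        assert ar[("p", "L")] == pytest.approx(3.0)

    def test_single_allele_gives_one(self):
        ar = pt.allelic_richness(self._aft({1: 8}), 4)
        assert ar[("p", "L")] == pytest.approx(1.0)

    def test_g_below_two_rejected(self):
        with pytest.raises(ValueError, match="g"):
            pt.allelic_richness(self._aft({1: 4}), 1)


class TestFis:
    def test_all_heterozygotes_give_minus_one(self):
        t = _table([[100, 102]] * 10)
        f = pt.fis(t, _one_pop(t)).loc["p", "fis"]
        assert f == pytest.approx(-1.0)

    def test_monomorphic_flagged_undefined(self):
        t = _table([[100, 100]] * 10)
        assert math.isnan(pt.fis(t, _one_pop(t)).loc["p", "fis"])

    def test_randomization_p_significant_under_strong_deficit(self):
        rng = np.random.default_rng(0)
        alleles = rng.choice([100, 102, 104, 106], size=(60, 3))
        genos = np.stack([alleles, alleles], axis=2)  # all homozygous
        t = pt.GenotypeTable([f"s{i}" for i in range(60)],
                             ["L0", "L1", "L2"], genos)
        res = pt.fis(t, _one_pop(t), n_randomizations=99, seed=1)
        assert res.loc["p", "p"] == pytest.approx(1 / 100)


class TestHwe:
    def test_perfect_hwe_counts_give_p_one(self):
        genos = [[100, 100]] * 25 + [[100, 102]] * 50 + [[102, 102]] * 25
        t = _table(genos)
        p = pt.hwe_test(t, _one_pop(t), "p", "L0", method="chi2")
        assert p == pytest.approx(1.0)

    def test_total_homozygote_excess_chi_square(self):
        genos = [[100, 100]] * 50 + [[102, 102]] * 50
        t = _table(genos)
        from pangotrace.popgen import _hwe_chi2_stat, _locus_calls
        stat, df = _hwe_chi2_stat(_locus_calls(t, list(range(100)), 0))
        assert stat == pytest.approx(100.0)
        assert df == 1
        p = pt.hwe_test(t, _one_pop(t), "p", "L0")
        assert p < 1e-20

    def test_exact_mc_agrees_with_chi2_on_balanced_sample(self):
        rng = np.random.default_rng(3)
        a = rng.choice([100, 102], size=(200, 2))
        t = _table(np.sort(a, axis=1))
        p_chi = pt.hwe_test(t, _one_pop(t), "p", "L0", method="chi2")
        p_mc = pt.hwe_test(t, _one_pop(t), "p", "L0", method="exact_mc",
                           n_mc=999, seed=4)
        assert p_mc == pytest.approx(p_chi, abs=0.12)

    def test_monomorphic_returns_one(self):
        t = _table([[100, 100]] * 10)
        assert pt.hwe_test(t, _one_pop(t), "p", "L0") == 1.0


class TestLd:
    def test_duplicated_locus_maximally_significant(self):
        rng = np.random.default_rng(6)
        a = np.sort(rng.choice([100, 102, 104], size=(40, 2)), axis=1)
        genos = np.stack([a, a], axis=1)
        t = pt.GenotypeTable([f"s{i}" for i in range(40)], ["L0", "L1"],
                             genos)
        p = pt.ld_test(t, _one_pop(t), "p", ("L0", "L1"),
                       n_randomizations=199, seed=7)
        assert p <= 1 / 200

    def test_independent_loci_not_significant_on_average(self):
        rng = np.random.default_rng(8)
        ps = []
        for k in range(20):
            genos = np.sort(rng.choice([100, 102], size=(50, 2, 2)), axis=2)
            t = pt.GenotypeTable([f"s{i}" for i in range(50)],
                                 ["L0", "L1"], genos)
            ps.append(pt.ld_test(t, _one_pop(t), "p", ("L0", "L1"),
                                 n_randomizations=99, seed=k))
        assert 0.25 <= np.mean(ps) <= 0.75   # roughly uniform p-values

    def test_zero_randomizations_rejected(self, small_table):
        with pytest.raises(ValueError, match="randomizations"):
            pt.ld_test(small_table, pt.PopulationMap.from_metadata(
                small_table), "P01", ("L01", "L02"), n_randomizations=0)


class TestNullAlleles:
    def test_hand_formula_values(self):
        # He 0.5, Ho 0.4: Chakraborty 0.1111..., Brookfield-1 0.0667...
        genos = ([[100, 102]] * 40 + [[100, 100]] * 35 + [[102, 102]] * 25)
        t = _table(genos)
        est = pt.null_alleles(t, _one_pop(t), "p", "L0", seed=0)
        ho, he = 0.4, 0.5
        assert est["chakraborty"] == pytest.approx((he - ho) / (he + ho),
                                                   abs=1e-2)
        assert est["brookfield1"] == pytest.approx((he - ho) / (1 + he),
                                                   abs=1e-2)

    def test_zero_when_ho_equals_he(self):
        genos = [[100, 102]] * 50 + [[100, 100]] * 25 + [[102, 102]] * 25
        t = _table(genos)
        est = pt.null_alleles(t, _one_pop(t), "p", "L0", seed=1)
        assert est["chakraborty"] == pytest.approx(0.0, abs=1e-9)
        assert est["brookfield1"] == pytest.approx(0.0, abs=1e-9)


class TestPairwiseFst:
    def test_fixed_populations_give_theta_one(self):
        genos = [[100, 100]] * 10 + [[102, 102]] * 10
        t = _table(genos)
        pm = pt.PopulationMap({"a": t.individuals[:10],
                               "b": t.individuals[10:]})
        res = pt.pairwise_fst(t, pm)
        assert res.theta.loc["a", "b"] == pytest.approx(1.0)

    def test_relabeling_alleles_leaves_theta_unchanged(self, small_table):
        part = pt.PopulationMap.from_metadata(small_table)
        t1 = pt.theta(small_table, part)
        relabeled = pt.GenotypeTable(
            list(small_table.individuals), list(small_table.loci),
            np.where(small_table.calls > 0, small_table.calls + 500, 0),
            small_table.metadata)
        assert pt.theta(relabeled, part) == pytest.approx(t1)

    def test_split_panmictic_population_theta_near_zero(self):
        m = pt.simulate_model(1, 10, f=0.0, seed=41)
        t = pt.simulate_genotypes(m, {"P01": 200}, seed=42)
        pm = pt.PopulationMap({"a": t.individuals[:100],
                               "b": t.individuals[100:]})
        assert abs(pt.theta(t, pm)) < 0.02

    def test_permutation_p_small_for_divergent_pair(self):
        m = pt.simulate_model(2, 8, concentration=3, seed=43)
        t = pt.simulate_genotypes(m, {p: 30 for p in m.populations},
                                  seed=44)
        part = pt.PopulationMap.from_metadata(t)
        res = pt.pairwise_fst(t, part, n_permutations=99, seed=45)
        assert res.p.loc["P01", "P02"] == pytest.approx(1 / 100)


class TestMantel:
    def test_identical_matrices_give_r_one(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        res = pt.mantel_ibd(a, a.copy(), n_permutations=99, seed=2)
        assert res.r == pytest.approx(1.0)

    def test_hand_pearson_on_three_by_three(self):
        g = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        e = np.array([[0, 1, 2], [1, 0, 3.5], [2, 3.5, 0]])
        res = pt.mantel_ibd(g, e, n_permutations=9, seed=3)
        expected = np.corrcoef([1, 2, 3], [1, 2, 3.5])[0, 1]
        assert res.r == pytest.approx(expected)

    def test_agrees_with_skbio_mantel_r(self):
        rng = np.random.default_rng(4)
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + 0.1 * rng.standard_normal((8, 8))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        ours = pt.mantel_ibd(a, b, n_permutations=99, seed=5)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                   permutations=0)
        assert ours.r == pytest.approx(r_ref, abs=1e-12)

    def test_constant_matrix_rejected(self):
        c = np.zeros((4, 4))
        with pytest.raises(ValueError, match="constant"):
            pt.mantel_ibd(c, c)

    def test_p_values_use_add_one_rule(self):
        rng = np.random.default_rng(6)
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        res = pt.mantel_ibd(a, a.copy(), n_permutations=99, seed=7)
        assert 0 < res.p <= 1
        assert res.p >= 1 / 100


class TestEdwardsDistance:
    def test_identical_individuals_distance_zero(self):
        t = _table([[100, 102], [100, 102]])
        d = pt.edwards_distance(t)
        assert d[0, 1] == pytest.approx(0.0)

    def test_symmetric_zero_diagonal(self, small_table):
        d = pt.edwards_distance(small_table)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        calls = np.sort(rng.choice([100, 102, 104],
                                   size=(5, 3, 2)), axis=2)
        t = pt.GenotypeTable([f"s{i}" for i in range(5)],
                             ["L0", "L1", "L2"], calls)
        d = pt.edwards_distance(t)
        assert ((d >= 0) & (d <= 1)).all()
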