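"""Private-allele rarefaction, panel construction and source assignment."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

import pangotrace as pt
from pangotrace.core import AlleleFrequencyTable


def _aft(pop_counts, loci=None):
    """pop_counts: {pop: {locus: {allele: count}}}"""
    pops = list(pop_counts)
    loci = loci or sorted({l for d in pop_counts.values() for l in d})
    aft = AlleleFrequencyTable(pops, loci)
    for p, by_locus in pop_counts.items():
        for l, counts in by_locus.items():
            aft._counts[(p, l)] = dict(counts)
    return aft


def brute_force_rarefaction(counts_by_pop, g):
    """Exact expectations by enumerating every subset of g gene copies.

    Returns {pop: (E[distinct], E[private])} as Fractions; the private
    expectation multiplies, per allele, the enumerated presence probability
    in the focal population with the enumerated absence probabilities in
    every other population (subsamples are independent across populations).
    """
    pops = list(counts_by_pop)
    alleles = sorted({a for c in counts_by_pop.values() for a in c})

    def presence_prob(counts, allele):
        copies = [a for a, k in counts.items() for _ in range(k)]
        subsets = list(itertools.combinations(range(len(copies)), g))
        hit = sum(1 for s in subsets if any(copies[i] == allele for i in s))
        return Fraction(hit, len(subsets))

    out = {}
    for pop in pops:
        e_distinct = Fraction(0)
        e_private = Fraction(0)
        for a in alleles:
            pres = presence_prob(counts_by_pop[pop], a)
            e_distinct += pres
            absent_elsewhere = Fraction(1)
            for other in pops:
                if other != pop:
                    absent_elsewhere *= 1 - presence_prob(
                        counts_by_pop[other], a)
            e_private += pres * absent_elsewhere
        out[pop] = (e_distinct, e_private)
    return out


class TestRarefaction:
    def test_two_population_hand_case(self):
        aft = _aft({"p1": {"L": {1: 2, 2: 2}}, "p2": {"L": {1: 4}}})
        c = pt.rarefy_private_alleles(aft, g_max=2, unit="genes",
                                      exact=True)
        assert c.private[("L", "p1")][2] == Fraction(5, 6)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        counts = {p: {"L": {a: int(k) for a, k in zip(
            range(1, 5), rng.multinomial(8, [0.4, 0.3, 0.2, 0.1])) if k}}
            for p in ("p1", "p2", "p3")}
        aft = _aft(counts)
        for g in (2, 3, 4):
            curves = pt.rarefy_private_alleles(aft, g_max=g, g_min=g,
                                               unit="genes", exact=True)
            brute = brute_force_rarefaction(
                {p: counts[p]["L"] for p in counts}, g)
            for p in counts:
                assert curves.distinct[("L", p)][g] == brute[p][0]
                assert curves.private[("L", p)][g] == brute[p][1]

    def test_shared_allele_contributes_nothing_private(self):
        aft = _aft({"p1": {"L": {1: 4}}, "p2": {"L": {1: 4}}})
        c = pt.rarefy_private_alleles(aft, g_max=4, unit="genes")
        assert c.private[("L", "p1")][4] == pytest.approx(0.0)

    def test_full_sample_equals_observed_private_count(self):
        aft = _aft({"p1": {"L": {1: 2, 2: 2}}, "p2": {"L": {1: 3, 3: 1}}})
        c = pt.rarefy_private_alleles(aft, g_max=4, unit="genes")
        # allele 2 private to p1, allele 3 private to p2
        assert c.private[("L", "p1")][4] == pytest.approx(1.0)
        assert c.private[("L", "p2")][4] == pytest.approx(1.0)

    def test_g_exceeding_population_rejected_with_name(self):
        aft = _aft({"p1": {"L": {1: 4}}, "p2": {"L": {1: 2}}})
        with pytest.raises(ValueError, match="p2"):
            pt.rarefy_private_alleles(aft, g_max=4, unit="genes")

    def test_paf_non_increasing_as_populations_added(self):
        rng = np.random.default_rng(23)
        counts = {p: {"L": {a: int(k) + 1 for a, k in enumerate(
            rng.multinomial(16, np.ones(4) / 4))}}
            for p in ("p1", "p2", "p3")}
        aft = _aft(counts)
        two = pt.rarefy_private_alleles(aft, 4, pops=["p1", "p2"],
                                        unit="genes")
        three = pt.rarefy_private_alleles(aft, 4, unit="genes")
        for g in (2, 3, 4):
            assert three.private[("L", "p1")][g] \
                <= two.private[("L", "p1")][g] + 1e-12

    def test_expected_alleles_non_decreasing_in_g(self):
        aft = _aft({"p1": {"L": {1: 5, 2: 3, 3: 2}},
                    "p2": {"L": {1: 10}}})
        c = pt.rarefy_private_alleles(aft, g_max=5, unit="genes")
        vals = [c.distinct[("L", "p1")][g] for g in range(2, 6)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_individual_unit_doubles_gene_copies(self):
        aft = _aft({"p1": {"L": {1: 6, 2: 6}}, "p2": {"L": {1: 12}}})
        ind = pt.rarefy_private_alleles(aft, g_max=3, unit="individuals")
        gen = pt.rarefy_private_alleles(aft, g_max=6, unit="genes")
        assert ind.private[("L", "p1")][3] \
            == pytest.approx(gen.private[("L", "p1")][6])


class TestSelection:
    def _curves(self, values):
        return pt.RarefactionCurve(
            distinct={("L", "p"): {g: 9 for g in values}},
            private={("L", "p"): values})

    def test_increasing_above_threshold_kept(self):
        kept = pt.select_tracing_loci(
            self._curves({4: 0.45, 5: 0.5}), 0.4, 5, 0.01)
        assert kept == {("L", "p")}

    def test_below_threshold_excluded(self):
        assert pt.select_tracing_loci(
            self._curves({4: 0.38, 5: 0.39}), 0.4, 5, 0.01) == set()

    def test_declining_curve_excluded(self):
        assert pt.select_tracing_loci(
            self._curves({4: 0.6, 5: 0.5}), 0.4, 5, 0.02) == set()

    def test_missing_g_star_rejected(self):
        with pytest.raises(ValueError, match="g"):
            pt.select_tracing_loci(self._curves({4: 0.5, 5: 0.5}),
                                   g_star=7)


class TestObservedPrivate:
    def test_injected_private_allele_recovered(self, small_model,
                                               small_table):
        part = pt.PopulationMap.from_metadata(small_table)
        aft = pt.allele_counts(small_table, part)
        priv = pt.observed_private_alleles(aft)
        assert ("L01", 301, "P01") in priv

    def test_shared_allele_excluded(self):
        aft = _aft({"p1": {"L": {1: 2, 7: 2}}, "p2": {"L": {1: 2, 7: 2}}})
        assert pt.observed_private_alleles(aft) == set()

    def test_degenerate_single_population_warns(self):
        aft = _aft({"p1": {"L": {1: 2}}, "p2": {"L": {}}})
        with pytest.warns(UserWarning, match="trivially private"):
            pt.observed_private_alleles(aft)


class TestPanelAndAssign:
    def test_panel_is_candidate_observed_intersection(self):
        cands = {("L1", "P")}
        observed = {("L1", 301, "P"), ("L2", 305, "P"), ("L1", 309, "Q")}
        panel = pt.build_panel(cands, observed)
        assert panel.entries == [("L1", 301, "P")]

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning, match="empty tracing panel"):
            panel = pt.build_panel(set(), {("L1", 301, "P")})
        assert panel.entries == []

    def test_assignment_by_single_panel_allele(self):
        panel = pt.TracingPanel([("L1", 301, "P")])
        calls = np.array([[[301, 100]], [[100, 102]]])
        t = pt.GenotypeTable(["m1", "m2"], ["L1"], calls)
        t.metadata["population"] = "market"
        t.metadata["cls"] = "market"
        res = pt.assign(t, panel)
        assigned = res.assigned()
        assert list(assigned["individual"]) == ["m1"]
        assert assigned.iloc[0]["sources"] == {"P"}

    def test_multi_source_carrier_flagged_conflicted(self):
        panel = pt.TracingPanel([("L1", 301, "P"), ("L2", 401, "Q")])
        calls = np.array([[[301, 100], [401, 120]]])
        t = pt.GenotypeTable(["m1"], ["L1", "L2"], calls)
        res = pt.assign(t, panel)
        assert bool(res.assignments.iloc[0]["conflict"])
        assert len(res.assigned()) == 0
        assert len(res.assigned(include_conflicted=True)) == 1

    def test_summary_conserves_counts(self):
        panel = pt.TracingPanel([("L1", 301, "P"), ("L1", 303, "Q")])
        calls = np.array([[[301, 100]], [[303, 100]], [[100, 100]],
                          [[301, 301]]])
        t = pt.GenotypeTable(["a", "b", "c", "d"], ["L1"], calls)
        t.metadata["population"] = ["M1", "M1", "M2", "M2"]
        res = pt.assign(t, panel)
        summ = pt.trace_summary(res)
        assert summ.to_numpy().sum() == len(res.assigned())
        assert summ.loc["P", "M1"] == 1 and summ.loc["P", "M2"] == 1
        assert summ.loc["Q", "M1"] == 1


class TestEndToEndRecovery:
    def test_assignments_match_true_sources(self):
        model, table = pt.survey_scenario(seed=3)
        part = pt.PopulationMap.from_metadata(table)
        aft = pt.allele_counts(table, part)
        usable = pt.feasible_loci(aft, 5)
        curves = pt.rarefy_private_alleles(aft, g_max=5, loci=usable)
        cands = pt.select_tracing_loci(curves)
        panel = pt.build_panel(cands, pt.observed_private_alleles(aft))
        assert panel.entries, "scenario should yield a non-empty panel"
        # every injected private allele at a retained locus is in the panel
        injected = {(l, a, p) for p, l, a, _ in model.private}
        assert {e for e in injected if (e[0], e[2]) in cands} \
            <= set(panel.entries)
        # with truly private markers, assignment has perfect precision
        panel_true = pt.TracingPanel(
            [e for e in panel.entries if e in injected])
        market_ids = [i for i in table.individuals
                      if table.metadata.loc[i, "cls"] != "reference"]
        res = pt.assign(table.subset(market_ids), panel_true)
        assigned = res.assigned()
        assert len(assigned) > 0
        for rec in assigned.itertuples(index=False):
            truth = table.metadata.loc[rec.individual, "true_source"]
            assert rec.sources == {truth}
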