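"""Diversity, equilibrium and differentiation statistics for microsatellites.

Estimators follow the conventions of the classic desktop programs for
co-dominant data: Nei heterozygosities with the small-sample (unbiased)
correction, hypergeometric rarefaction for allelic richness, Weir &
Cockerham (1984) variance-component estimators for F_IS and pairwise F_ST,
randomization/permutation significance with the add-one rule
p = (b + 1) / (m + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, AlleleFrequencyTable, GenotypeTable, PopulationMap

# ---------------------------------------------------------------------------
# per-locus helpers


def _locus_calls(table: GenotypeTable, rows, j) -> np.ndarray:
    """Typed (k, 2) calls for individuals ``rows`` at locus index ``j``."""
    g = table.calls[rows, j, :]
    return g[(g != MISSING).all(axis=1)]


def _rows(table: GenotypeTable, ids) -> list:
    index = {ind: i for i, ind in enumerate(table.individuals)}
    return [index[i] for i in ids]


def _het_stats(genos: np.ndarray):
    """(Ho, He, uHe, n, allele freq dict) for one locus' typed calls."""
    n = len(genos)
    if n == 0:
        return math.nan, math.nan, math.nan, 0, {}
    ho = float((genos[:, 0] != genos[:, 1]).mean())
    vals, cnt = np.unique(genos.ravel(), return_counts=True)
    p = cnt / cnt.sum()
    he = float(1 - (p ** 2).sum())
    uhe = he * (2 * n) / (2 * n - 1) if n > 0 else math.nan
    return ho, he, uhe, n, dict(zip(vals.tolist(), p.tolist()))


# ---------------------------------------------------------------------------
# diversity summary


@dataclass
class DiversitySummary:
    """Population-level genetic diversity (Table-style output)."""

    per_population: pd.DataFrame
    per_locus: pd.DataFrame
    g_richness: int | None = None

    def to_tsv(self, path):
        self.per_population.to_csv(path, sep="\t")


def diversity(table: GenotypeTable, partition: PopulationMap,
              richness_g: int | None = None,
              fis_randomizations: int = 0, seed=None) -> DiversitySummary:
    """Per-population Na, Ho, He, uHe, F_IS, A_R and private-allele columns.

    ``He = 1 - sum(p_i^2)`` from sample allele frequencies,
    ``uHe = 2n/(2n-1) * He`` with n typed genotypes, ``Ho`` the fraction of
    heterozygous typed genotypes; all are locus means.  A_R is rarefied to
    ``richness_g`` gene copies (default: twice the smallest per-locus typed
    sample across populations, the FSTAT convention).  Private-allele
    count/frequency consider alleles observed in exactly one population;
    the frequency column is the mean sample frequency of those alleles in
    their home population.
    """
    from .trace import observed_private_alleles  # local import, no cycle

    partition.validate(table)
    pops = partition.populations
    recs_locus = []
    typed_min = {}
    for pop in pops:
        rows = _rows(table, partition.groups[pop])
        for j, locus in enumerate(table.loci):
            genos = _locus_calls(table, rows, j)
            ho, he, uhe, n, freqs = _het_stats(genos)
            recs_locus.append({
                "population": pop, "locus": locus, "n": n,
                "Na": len(freqs) if n else math.nan,
                "Ho": ho, "He": he, "uHe": uhe,
            })
            typed_min[locus] = min(typed_min.get(locus, np.inf), n)
    per_locus = pd.DataFrame(recs_locus)

    aft = _allele_counts(table, partition)
    if richness_g is None:
        finite = [2 * int(v) for v in typed_min.values() if v > 0]
        richness_g = max(2, min(finite)) if finite else 2
    ar = allelic_richness(aft, richness_g)

    priv = observed_private_alleles(aft, warn_degenerate=False)
    priv_by_pop: dict = {p: [] for p in pops}
    for locus, allele, pop in priv:
        priv_by_pop[pop].append(aft.freqs(pop, locus)[allele])

    fis_res = fis(table, partition, n_randomizations=fis_randomizations,
                  seed=seed)
    recs = []
    for pop in pops:
        sub = per_locus[per_locus["population"] == pop]
        typed = sub[sub["n"] > 0]
        pf = priv_by_pop[pop]
        recs.append({
            "population": pop,
            "N": len(partition.groups[pop]),
            "Na": typed["Na"].mean(),
            "Ho": typed["Ho"].mean(),
            "He": typed["He"].mean(),
            "uHe": typed["uHe"].mean(),
            "F_IS": fis_res.loc[pop, "fis"],
            "F_IS_p": fis_res.loc[pop, "p"],
            "A_R": np.nanmean([ar.get((pop, l), math.nan)
                               for l in table.loci]),
            "n_private": len(pf),
            "private_freq": float(np.mean(pf)) if pf else 0.0,
        })
    return DiversitySummary(pd.DataFrame(recs).set_index("population"),
                            per_locus, richness_g)


def _allele_counts(table, partition):
    from .core import allele_counts
    return allele_counts(table, partition)


# ---------------------------------------------------------------------------
# allelic richness (hypergeometric rarefaction)


def allelic_richness(freqs: AlleleFrequencyTable, g: int) -> dict:
    """Expected number of distinct alleles in g gene copies, per (pop, locus).

    ``A_R = sum_i [1 - C(N - N_i, g) / C(N, g)]`` where N is the gene-copy
    total and N_i the count of allele i.  Entries with N < g are left out
    (rarefaction undefined there).
    """
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    out = {}
    for pop in freqs.populations:
        for locus in freqs.loci:
            counts = freqs.counts(pop, locus)
            N = sum(counts.values())
            if N < g:
                continue
            denom = math.comb(N, g)
            out[(pop, locus)] = float(sum(
                1 - math.comb(N - ni, g) / denom for ni in counts.values()))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components


def _wc_single_pop(genos: np.ndarray):
    """Within-population components (b, c) summed over alleles, one locus."""
    n = len(genos)
    if n < 2:
        return 0.0, 0.0
    alleles = np.unique(genos)
    if len(alleles) < 2:
        return 0.0, 0.0
    b_sum = c_sum = 0.0
    het = genos[:, 0] != genos[:, 1]
    for a in alleles:
        carries = genos == a
        p = carries.mean()
        h = float((het & carries.any(axis=1)).mean())
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        b_sum += b
        c_sum += h / 2
    return b_sum, c_sum


def fis(table: GenotypeTable, partition: PopulationMap,
        n_randomizations: int = 0, seed=None) -> pd.DataFrame:
    """Multilocus Weir-Cockerham f per population with randomization p.

    f = 1 - sum(c) / sum(b + c) over loci and alleles.  Significance of a
    heterozygote deficit (one-tailed, f > 0) is assessed by shuffling gene
    copies among individuals within the population at each locus; p uses the
    add-one rule.  Populations where every locus is monomorphic get NaN.
    """
    rng = np.random.default_rng(seed)
    recs = {}
    for pop, ids in partition.groups.items():
        rows = _rows(table, ids)
        genos_by_locus = [
            _locus_calls(table, rows, j) for j in range(table.n_loci)]
        f_obs = _fis_value(genos_by_locus)
        p = math.nan
        if n_randomizations > 0 and not math.isnan(f_obs):
            hits = 0
            for _ in range(n_randomizations):
                rand = [_shuffle_gene_copies(g, rng) for g in genos_by_locus]
                f_r = _fis_value(rand)
                if not math.isnan(f_r) and f_r >= f_obs:
                    hits += 1
            p = (hits + 1) / (n_randomizations + 1)
        recs[pop] = {"fis": f_obs, "p": p}
    return pd.DataFrame(recs).T


def _fis_value(genos_by_locus) -> float:
    b_tot = c_tot = 0.0
    for genos in genos_by_locus:
        b, c = _wc_single_pop(genos)
        b_tot += b
        c_tot += c
    if b_tot + c_tot == 0:
        return math.nan
    return 1 - c_tot / (b_tot + c_tot)


def _shuffle_gene_copies(genos: np.ndarray, rng) -> np.ndarray:
    if len(genos) == 0:
        return genos
    pool = genos.ravel().copy()
    rng.shuffle(pool)
    return np.sort(pool.reshape(-1, 2), axis=1)


def _wc_theta_components(pop_genos):
    """WC84 (a, b, c) totals over alleles for one locus, r populations."""
    pop_genos = [g for g in pop_genos if len(g) >= 1]
    r = len(pop_genos)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([len(g) for g in pop_genos], dtype=float)
    n_bar = n_i.mean()
    if n_bar <= 1:
        return 0.0, 0.0, 0.0
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in pop_genos]))
    if len(alleles) < 2:
        return 0.0, 0.0, 0.0
    a_tot = b_tot = c_tot = 0.0
    for al in alleles:
        p_i = np.array([(g == al).mean() for g in pop_genos])
        h_i = np.array([((g[:, 0] != g[:, 1]) & (g == al).any(axis=1)).mean()
                        for g in pop_genos])
        p_bar = (n_i * p_i).sum() / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum() / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
            / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_tot += a
        b_tot += b
        c_tot += c
    return a_tot, b_tot, c_tot


def theta(table: GenotypeTable, partition: PopulationMap,
          pops=None) -> float:
    """Multilocus Weir-Cockerham theta over the given populations."""
    pops = pops if pops is not None else partition.populations
    rows = {p: _rows(table, partition.groups[p]) for p in pops}
    a_tot = d_tot = 0.0
    for j in range(table.n_loci):
        genos = [_locus_calls(table, rows[p], j) for p in pops]
        a, b, c = _wc_theta_components(genos)
        a_tot += a
        d_tot += a + b + c
    return a_tot / d_tot if d_tot else math.nan


@dataclass
class PairwiseFst:
    """Symmetric matrix of pairwise theta with permutation p-values."""

    theta: pd.DataFrame
    p: pd.DataFrame


def pairwise_fst(table: GenotypeTable, partition: PopulationMap,
                 n_permutations: int = 0, seed=None) -> PairwiseFst:
    """Pairwise WC theta; p from shuffling individuals between the pair."""
    rng = np.random.default_rng(seed)
    pops = partition.populations
    th = pd.DataFrame(0.0, index=pops, columns=pops)
    pv = pd.DataFrame(math.nan, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            ids1 = partition.groups[p1]
            ids2 = partition.groups[p2]
            obs = theta(table, PopulationMap({p1: ids1, p2: ids2}))
            pval = math.nan
            if n_permutations > 0 and not math.isnan(obs):
                combined = list(ids1) + list(ids2)
                n1 = len(ids1)
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(combined)
                    pm = PopulationMap({p1: perm[:n1].tolist(),
                                        p2: perm[n1:].tolist()})
                    t = theta(table, pm)
                    if not math.isnan(t) and t >= obs:
                        hits += 1
                pval = (hits + 1) / (n_permutations + 1)
            th.loc[p1, p2] = th.loc[p2, p1] = obs
            pv.loc[p1, p2] = pv.loc[p2, p1] = pval
    return PairwiseFst(th, pv)


# ---------------------------------------------------------------------------
# Hardy-Weinberg and linkage tests


def _genotype_counts(genos: np.ndarray) -> dict:
    out: dict = {}
    for a, b in genos:
        out[(int(a), int(b))] = out.get((int(a), int(b)), 0) + 1
    return out


def _hwe_chi2_stat(genos: np.ndarray):
    n = len(genos)
    vals, cnt = np.unique(genos.ravel(), return_counts=True)
    p = cnt / cnt.sum()
    obs = _genotype_counts(genos)
    stat = 0.0
    for i, a in enumerate(vals):
        for k in range(i, len(vals)):
            b = vals[k]
            e = n * (p[i] ** 2 if i == k else 2 * p[i] * p[k])
            o = obs.get((min(a, b), max(a, b)), 0)
            if e > 0:
                stat += (o - e) ** 2 / e
    k_alleles = len(vals)
    df = k_alleles * (k_alleles - 1) // 2
    return stat, df


def hwe_test(table: GenotypeTable, partition: PopulationMap, population,
             locus, method: str = "chi2", n_mc: int = 1000,
             seed=None) -> float:
    """Hardy-Weinberg deviation p-value for one population and locus.

    ``chi2``: goodness of fit of genotype counts against HWE expectations
    with df = k(k-1)/2.  ``exact_mc``: Monte-Carlo test shuffling gene
    copies among individuals, same chi-square statistic, add-one p.
    Monomorphic loci return p = 1.
    """
    j = table.loci.index(locus)
    rows = _rows(table, partition.groups[population])
    genos = _locus_calls(table, rows, j)
    if len(genos) == 0 or len(np.unique(genos)) < 2:
        return 1.0
    stat, df = _hwe_chi2_stat(genos)
    if method == "chi2":
        return float(stats.chi2.sf(stat, df))
    if method == "exact_mc":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_mc):
            s, _ = _hwe_chi2_stat(_shuffle_gene_copies(genos, rng))
            if s >= stat - 1e-12:
                hits += 1
        return (hits + 1) / (n_mc + 1)
    raise ValueError(f"unknown method {method!r}")


def ld_test(table: GenotypeTable, partition: PopulationMap, population,
            locus_pair, n_randomizations: int = 1000, seed=None) -> float:
    """Genotypic linkage disequilibrium between two loci in one population.

    G-test statistic on the two-locus genotype contingency table; the null
    distribution comes from permuting one locus' genotypes among
    individuals.  Returns the add-one permutation p-value.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    j1 = table.loci.index(locus_pair[0])
    j2 = table.loci.index(locus_pair[1])
    rows = _rows(table, partition.groups[population])
    g = table.calls[rows][:, [j1, j2], :]
    typed = (g != MISSING).all(axis=(1, 2))
    g = g[typed]
    if len(g) < 5:
        raise ValueError("need both loci typed in >= 5 individuals")
    code1 = np.unique(g[:, 0, :], axis=0, return_inverse=True)[1]
    code2 = np.unique(g[:, 1, :], axis=0, return_inverse=True)[1]
    if code1.max() == 0 or code2.max() == 0:
        return 1.0

    def gstat(c1, c2):
        tab = np.zeros((code1.max() + 1, code2.max() + 1))
        np.add.at(tab, (c1, c2), 1)
        n = tab.sum()
        e = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
        mask = tab > 0
        return 2 * (tab[mask] * np.log(tab[mask] / e[mask])).sum()

    obs = gstat(code1, code2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_randomizations):
        if gstat(code1, rng.permutation(code2)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_randomizations + 1)


def bonferroni(pvalues, alpha: float = 0.05):
    """(adjusted p-values, rejected mask) under Bonferroni correction."""
    p = np.asarray(list(pvalues), dtype=float)
    adj = np.clip(p * len(p), 0, 1)
    return adj, adj <= alpha


# ---------------------------------------------------------------------------
# null alleles


def null_alleles(table: GenotypeTable, partition: PopulationMap, population,
                 locus, n_mc: int = 1000, seed=None) -> dict:
    """Null-allele frequency estimates plus a homozygote-excess MC p-value.

    Chakraborty r = (He - Ho) / (He + Ho); Brookfield-1 r = (He - Ho) /
    (1 + He).  The Monte-Carlo p compares the observed homozygote count to
    its distribution under HWE given the sample allele frequencies (a
    simplified size-class-free analogue of the Micro-Checker test).
    """
    j = table.loci.index(locus)
    rows = _rows(table, partition.groups[population])
    genos = _locus_calls(table, rows, j)
    ho, he, _, n, freqs = _het_stats(genos)
    if n == 0 or len(freqs) < 2:
        raise ValueError(f"locus {locus} monomorphic or untyped in {population}")
    est = {
        "chakraborty": (he - ho) / (he + ho) if he + ho > 0 else math.nan,
        "brookfield1": (he - ho) / (1 + he),
    }
    rng = np.random.default_rng(seed)
    alleles = np.array(sorted(freqs))
    p = np.array([freqs[a] for a in alleles])
    obs_hom = int((genos[:, 0] == genos[:, 1]).sum())
    draws = rng.choice(len(alleles), size=(n_mc, n, 2), p=p)
    sim_hom = (draws[:, :, 0] == draws[:, :, 1]).sum(axis=1)
    est["p_homozygote_excess"] = float(
        ((sim_hom >= obs_hom).sum() + 1) / (n_mc + 1))
    return est


# ---------------------------------------------------------------------------
# isolation by distance


@dataclass
class IbdResult:
    r: float
    p: float
    level: str = "individual"
    n_permutations: int = 0


def edwards_distance(table: GenotypeTable) -> np.ndarray:
    """Individual-level Cavalli-Sforza & Edwards chord distance matrix.

    Each individual's per-locus allele-dosage profile (dosage / 2) is
    treated as a frequency vector; the per-locus chord distance
    ``sqrt(1 - sum_i sqrt(x_i * y_i))`` is averaged over loci typed in both
    individuals.
    """
    n = table.n_individuals
    total = np.zeros((n, n))
    shared = np.zeros((n, n))
    for j in range(table.n_loci):
        genos = table.calls[:, j, :]
        typed = (genos != MISSING).all(axis=1)
        alleles = np.unique(genos[typed])
        if len(alleles) == 0:
            continue
        dosage = np.zeros((n, len(alleles)))
        for k, a in enumerate(alleles):
            dosage[:, k] = (genos == a).sum(axis=1) / 2.0
        s = np.sqrt(dosage) @ np.sqrt(dosage).T
        d = np.sqrt(np.clip(1 - s, 0, None))
        pair_typed = np.outer(typed, typed)
        total += np.where(pair_typed, d, 0.0)
        shared += pair_typed
    with np.errstate(invalid="ignore"):
        out = total / shared
    np.fill_diagonal(out, 0.0)
    return out


def mantel_ibd(genetic: np.ndarray, geographic: np.ndarray,
               n_permutations: int = 10000, seed=None,
               level: str = "individual") -> IbdResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal entries; p is the
    upper-tail probability from permuting one matrix's row/column order,
    with the add-one rule.
    """
    g = np.asarray(genetic, dtype=float)
    e = np.asarray(geographic, dtype=float)
    if g.shape != e.shape or g.shape[0] != g.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if not (np.allclose(g, g.T, equal_nan=True)
            and np.allclose(e, e.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric")
    n = g.shape[0]
    iu = np.triu_indices(n, k=1)
    x = g[iu]
    if x.std() == 0 or e[iu].std() == 0:
        raise ValueError("constant distance matrix: r undefined")

    def corr(perm):
        y = e[np.ix_(perm, perm)][iu]
        return np.corrcoef(x, y)[0, 1]

    obs = corr(np.arange(n))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if corr(rng.permutation(n)) >= obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return IbdResult(float(obs), float(p), level, n_permutations)
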