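"""Heterozygosity-excess bottleneck test under SMM and TPM.

A recent reduction in effective population size erodes allele number
faster than gene diversity, so a bottlenecked sample shows He above the
mutation-drift-equilibrium expectation given its observed allele count.
The expectation is obtained by simulating coalescent genealogies of the
sampled gene copies under a stepwise mutation model (SMM) or two-phase
model (TPM: single steps with probability p_smm, otherwise a geometric
multi-step jump of chosen variance), with the scaled mutation rate theta
tuned so that the mean simulated allele number matches the observed one,
and replicates retained conditional on exact allele-number agreement.
Across polymorphic loci the signs of He_obs - mean(Heq) feed a Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeTable

#: geometric success probability giving multi-step jump variance 12
_GEOM_Q_VAR12 = 0.25


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class MutationModel:
    """Microsatellite ladder mutation model.

    ``p_smm = 1`` is the strict stepwise model; smaller values mix in
    multi-step jumps of geometric magnitude whose variance is set through
    ``geometric_q`` (var = (1 - q) / q^2; the default q = 0.25 gives 12).
    """

    p_smm: float = 1.0
    geometric_q: float = _GEOM_Q_VAR12

    @property
    def name(self) -> str:
        return "SMM" if self.p_smm >= 1 else f"TPM({self.p_smm:g})"


SMM = MutationModel(1.0)
TPM = MutationModel(0.95)


def _steps(rng, k: int, model: MutationModel) -> np.ndarray:
    """k signed mutation step sizes."""
    size = np.ones(k, dtype=np.int64)
    if model.p_smm < 1:
        multi = rng.random(k) >= model.p_smm
        n_multi = int(multi.sum())
        if n_multi:
            size[multi] = rng.geometric(model.geometric_q, size=n_multi)
    sign = rng.integers(0, 2, size=k) * 2 - 1
    return sign * size


def _simulate_alleles(rng, n_genes: int, theta: float,
                      model: MutationModel) -> np.ndarray:
    """Allele states for one equilibrium coalescent genealogy.

    Kingman coalescent in units of 2N generations (pairwise coalescence
    rate 1); each lineage mutates at rate theta / 2, so the expected
    pairwise difference count equals theta.
    """
    states = np.zeros(n_genes, dtype=np.int64)
    lineages = [[i] for i in range(n_genes)]
    j = n_genes
    while j > 1:
        t = rng.exponential(1.0 / (j * (j - 1) / 2))
        n_mut = rng.poisson(theta / 2 * t * j)
        if n_mut:
            which = rng.integers(0, j, size=n_mut)
            steps = _steps(rng, n_mut, model)
            for w, s in zip(which, steps):
                for tip in lineages[w]:
                    states[tip] += s
        a, b = rng.choice(j, size=2, replace=False)
        a, b = (a, b) if a < b else (b, a)
        lineages[a] = lineages[a] + lineages[b]
        del lineages[b]
        j -= 1
    return states


def _k_and_he(states: np.ndarray):
    n = len(states)
    _, cnt = np.unique(states, return_counts=True)
    p = cnt / n
    he = n / (n - 1) * (1 - (p ** 2).sum())
    return len(cnt), float(he)


def _tune_theta(rng, n_genes: int, k_target: int, model: MutationModel,
                pilot: int = 200, tol: float = 0.15) -> float:
    """Bisect log-theta so mean simulated allele number hits k_target."""
    lo, hi = 1e-3, 5e3

    def mean_k(theta):
        return float(np.mean([
            _k_and_he(_simulate_alleles(rng, n_genes, theta, model))[0]
            for _ in range(pilot)]))

    for _ in range(24):
        mid = math.sqrt(lo * hi)
        mk = mean_k(mid)
        if abs(mk - k_target) <= tol:
            return mid
        if mk < k_target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_heq(n_genes: int, k_observed: int, model: MutationModel = SMM,
                 n_reps: int = 1000, seed=None, max_attempts=None,
                 theta: float | None = None) -> np.ndarray:
    """Equilibrium He sample conditional on the observed allele number.

    theta is tuned by bisection on the mean simulated allele count, then
    replicates are accepted only when they carry exactly ``k_observed``
    alleles.  Returns the retained He values (may be shorter than
    ``n_reps`` if ``max_attempts`` is hit).
    """
    if not 2 <= k_observed <= n_genes:
        raise ValueError("need 2 <= k_observed <= n_genes")
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = _tune_theta(rng, n_genes, k_observed, model)
    if max_attempts is None:
        max_attempts = 200 * n_reps
    out = []
    attempts = 0
    while len(out) < n_reps and attempts < max_attempts:
        attempts += 1
        k, he = _k_and_he(_simulate_alleles(rng, n_genes, theta, model))
        if k == k_observed:
            out.append(he)
    return np.asarray(out)


class HeqBank:
    """Cache of conditional Heq samples keyed by (n_genes, k, model)."""

    def __init__(self, n_reps: int = 500, seed=None):
        self.n_reps = n_reps
        self._ss = _as_seedseq(seed)
        self._store: dict = {}

    def get(self, n_genes: int, k: int, model: MutationModel) -> np.ndarray:
        key = (n_genes, k, model.p_smm, model.geometric_q)
        if key not in self._store:
            child = self._ss.spawn(1)[0]
            self._store[key] = simulate_heq(
                n_genes, k, model, n_reps=self.n_reps, seed=child)
        return self._store[key]


@dataclass
class BottleneckResult:
    """Per-locus He vs equilibrium expectation and Wilcoxon p-values."""

    per_locus: pd.DataFrame
    p_excess: float
    p_deficit: float
    p_two_sided: float
    model_name: str
    n_reps: int
    excluded_loci: list = field(default_factory=list)

    def to_tsv(self, path):
        self.per_locus.to_csv(path, sep="\t", index=False)


def bottleneck_test(table: GenotypeTable, individuals=None,
                    model: MutationModel = SMM, n_reps: int = 10000,
                    seed=None, heq_bank: HeqBank | None = None
                    ) -> BottleneckResult:
    """Wilcoxon heterozygosity-excess test for one population sample.

    Per polymorphic locus the observed unbiased gene diversity is compared
    with the conditional equilibrium distribution from
    :func:`simulate_heq`; the standardized differences
    ``(He - mean(Heq)) / sd(Heq)`` enter a Wilcoxon signed-rank test
    (exact distribution for small locus numbers).  The conditional mean
    and SD must be estimated accurately for the test to hold its size --
    keep ``n_reps`` (or the bank size) in the thousands; a few hundred
    equilibrium replicates visibly distort the null.  All three tails are
    returned; the bottleneck signal is ``p_excess``.
    """
    if individuals is None:
        individuals = table.individuals
    idx = [table.individuals.index(i) for i in individuals]
    ss = _as_seedseq(seed)
    recs, excluded = [], []
    children = iter(ss.spawn(table.n_loci))
    for j, locus in enumerate(table.loci):
        child = next(children)
        g = table.calls[idx, j, :]
        g = g[(g != MISSING).all(axis=1)]
        if len(g) < 2:
            excluded.append(locus)
            continue
        genes = g.ravel()
        k, he = _k_and_he(genes)
        if k < 2:
            excluded.append(locus)
            continue
        n_genes = len(genes)
        if heq_bank is not None:
            heq = heq_bank.get(n_genes, k, model)
        else:
            heq = simulate_heq(n_genes, k, model, n_reps=n_reps, seed=child)
        mu, sd = float(heq.mean()), float(heq.std(ddof=1))
        recs.append({
            "locus": locus, "n_genes": n_genes, "k": k, "He": he,
            "Heq_mean": mu, "Heq_sd": sd,
            "Heq_median": float(np.median(heq)),
            "std_diff": (he - mu) / sd if sd > 0 else math.nan,
        })
    per_locus = pd.DataFrame(recs)
    if len(per_locus) < 4:
        raise ValueError("need >= 4 polymorphic loci for the Wilcoxon test")
    d = per_locus["std_diff"].to_numpy()
    p_exc = float(stats.wilcoxon(d, alternative="greater").pvalue)
    p_def = float(stats.wilcoxon(d, alternative="less").pvalue)
    p_two = float(stats.wilcoxon(d, alternative="two-sided").pvalue)
    return BottleneckResult(per_locus, p_exc, p_def, p_two,
                            model.name, n_reps, excluded)
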