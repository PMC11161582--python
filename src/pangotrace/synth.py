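"""Synthetic microsatellite cohorts with controlled population structure.

The generator emulates the sampling design of a regional bushmeat-trade
survey: a handful of small reference populations with high heterozygosity,
a Wahlund-like heterozygote deficit (positive F_IS), weak differentiation
within a lineage, population-private alleles at chosen frequencies, large
"market" samples mixing several sources, exact-duplicate individuals and
missing genotypes.

Population allele frequencies are drawn hierarchically: a shared ancestral
frequency vector per locus, then one Dirichlet(concentration * ancestral)
draw per population.  Under this model the expected differentiation between
two populations is approximately 1 / (1 + concentration), which is how the
default concentration is chosen.  Spatial autocorrelation (isolation by
distance) is induced through a Gaussian copula on the Gamma variates behind
the Dirichlet draws, so marginals stay exactly Dirichlet while nearby
populations receive correlated perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable, PopulationMap


@dataclass
class PopulationModel:
    """Allele-frequency model for a set of reference populations.

    ``freqs[pop][locus]`` maps allele code -> frequency (sums to 1);
    ``coords[pop]`` is an (lon, lat) pair; ``f[pop]`` is the inbreeding /
    Wahlund coefficient used when drawing genotypes; ``private`` lists
    (pop, locus, allele, frequency) entries injected as strictly private.
    """

    freqs: dict
    coords: dict
    f: dict
    private: list = field(default_factory=list)
    loci: list = field(default_factory=list)

    @property
    def populations(self) -> list:
        return list(self.freqs)

    def population_map(self, table: GenotypeTable) -> PopulationMap:
        pm = PopulationMap.from_metadata(table, classes=("reference",))
        pm.coords.update(self.coords)
        return pm


@dataclass
class MarketSpec:
    """A market (or seizure) sample as a mixture over source populations."""

    name: str
    weights: dict
    size: int
    cls: str = "market"

    def __post_init__(self):
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1")


def _ladder(n_alleles: int, start: int = 100, step: int = 2) -> np.ndarray:
    """Dinucleotide-style allele codes (fragment sizes in bp)."""
    return start + step * np.arange(n_alleles)


def simulate_model(n_pops: int, n_loci: int, alleles_per_locus: int = 6,
                   concentration: float = 40.0, ibd_strength: float = 0.0,
                   private_spec=None, f=0.16, seed=None,
                   ancestral_alpha: float = 2.0) -> PopulationModel:
    """Draw a :class:`PopulationModel`.

    Parameters
    ----------
    concentration
        Dirichlet concentration multiplying the ancestral vector; expected
        pairwise differentiation ~ 1 / (1 + concentration).
    ibd_strength
        In [0, 1]; scales the spatial correlation of the per-population
        Dirichlet perturbations (0 = independent populations).
    private_spec
        Iterable of ``(pop_index_or_name, locus_index_or_name, allele,
        frequency)`` entries; each allele is set to the stated frequency in
        its population and removed everywhere else.
    f
        Scalar or per-population inbreeding coefficient(s).
    """
    if n_pops < 1 or alleles_per_locus < 2:
        raise ValueError("need n_pops >= 1 and alleles_per_locus >= 2")
    rng = np.random.default_rng(seed)
    pops = [f"P{i + 1:02d}" for i in range(n_pops)]
    loci = [f"L{j + 1:02d}" for j in range(n_loci)]

    # populations along a geographic transect with jitter
    lons = np.linspace(9.0, 15.0, n_pops) + rng.normal(0, 0.3, n_pops)
    lats = np.linspace(2.0, 6.0, n_pops) + rng.normal(0, 0.3, n_pops)
    coords = {p: (float(x), float(y)) for p, x, y in zip(pops, lons, lats)}

    # spatial correlation of the Dirichlet perturbations (Gaussian copula)
    d = np.sqrt((lons[:, None] - lons[None, :]) ** 2
                + (lats[:, None] - lats[None, :]) ** 2)
    scale = max(d.max() / 2, 1e-9)
    corr = ibd_strength * np.exp(-d / scale)
    np.fill_diagonal(corr, 1.0)
    # nearest-PSD guard for strong ibd settings
    w_eig, v_eig = np.linalg.eigh(corr)
    corr = (v_eig * np.clip(w_eig, 1e-9, None)) @ v_eig.T
    chol = np.linalg.cholesky(corr)

    freqs = {p: {} for p in pops}
    codes = _ladder(alleles_per_locus)
    for locus in loci:
        anc = rng.dirichlet(np.full(alleles_per_locus, ancestral_alpha))
        shape = concentration * anc                      # per-allele Gamma shape
        z = chol @ rng.standard_normal((n_pops, alleles_per_locus))
        u = stats.norm.cdf(z)
        g = stats.gamma.ppf(np.clip(u, 1e-12, 1 - 1e-12), shape[None, :])
        g = np.clip(g, 1e-300, None)
        p = g / g.sum(axis=1, keepdims=True)
        for i, pop in enumerate(pops):
            freqs[pop][locus] = {int(c): float(v)
                                 for c, v in zip(codes, p[i]) if v > 0}

    private = []
    for entry in (private_spec or []):
        pop, locus, allele, q = entry
        pop = pops[pop] if isinstance(pop, int) else pop
        locus = loci[locus] if isinstance(locus, int) else locus
        if not 0 < q < 1:
            raise ValueError(f"private allele frequency {q} not in (0, 1)")
        for other in pops:
            freqs[other][locus].pop(int(allele), None)
        vec = freqs[pop][locus]
        tot = sum(vec.values())
        for a in list(vec):
            vec[a] *= (1 - q) / tot
        vec[int(allele)] = q
        private.append((pop, locus, int(allele), q))

    if np.isscalar(f):
        fmap = {p: float(f) for p in pops}
    else:
        fmap = {p: float(v) for p, v in zip(pops, f)}
    return PopulationModel(freqs=freqs, coords=coords, f=fmap,
                           private=private, loci=loci)


def _draw_genotypes(rng, freq: dict, n: int, f: float) -> np.ndarray:
    """n diploid calls from one locus' frequency map with inbreeding f."""
    alleles = np.array(sorted(freq), dtype=np.int64)
    p = np.array([freq[a] for a in alleles])
    p = p / p.sum()
    out = np.empty((n, 2), dtype=np.int64)
    ibd = rng.random(n) < f
    k_ibd = int(ibd.sum())
    if k_ibd:
        a = alleles[rng.choice(len(alleles), size=k_ibd, p=p)]
        out[ibd] = np.stack([a, a], axis=1)
    k_hwe = n - k_ibd
    if k_hwe:
        out[~ibd] = alleles[rng.choice(len(alleles), size=(k_hwe, 2), p=p)]
    return np.sort(out, axis=1)


def simulate_genotypes(model: PopulationModel, sizes: dict,
                       seed=None) -> GenotypeTable:
    """Reference individuals drawn per population under inbreeding f.

    With probability ``f[pop]`` a genotype is an identical-by-descent
    homozygote (one allele drawn, duplicated); otherwise two independent
    gene copies are drawn (Hardy-Weinberg).
    """
    rng = np.random.default_rng(seed)
    individuals, pop_labels = [], []
    blocks = []
    for pop in model.populations:
        n = int(sizes.get(pop, 0))
        if n == 0:
            continue
        ids = [f"{pop}_{i + 1:03d}" for i in range(n)]
        individuals += ids
        pop_labels += [pop] * n
        cols = [
            _draw_genotypes(rng, model.freqs[pop][locus], n, model.f[pop])
            for locus in model.loci]
        blocks.append(np.stack(cols, axis=1))
    calls = (np.concatenate(blocks, axis=0) if blocks
             else np.zeros((0, len(model.loci), 2), dtype=np.int64))
    meta = pd.DataFrame({
        "population": pop_labels,
        "cls": "reference",
        "lon": [model.coords[p][0] for p in pop_labels],
        "lat": [model.coords[p][1] for p in pop_labels],
    }, index=individuals)
    return GenotypeTable(individuals, model.loci, calls, meta)


def simulate_market(model: PopulationModel, spec: MarketSpec,
                    seed=None) -> GenotypeTable:
    """A market/seizure cohort; each individual's true source is recorded."""
    rng = np.random.default_rng(seed)
    sources = list(spec.weights)
    missing_src = set(sources) - set(model.populations)
    if missing_src:
        raise ValueError(f"unknown source populations {sorted(missing_src)}")
    w = np.array([spec.weights[s] for s in sources])
    picks = rng.choice(len(sources), size=spec.size, p=w / w.sum())
    individuals = [f"{spec.name}_{i + 1:03d}" for i in range(spec.size)]
    calls = np.zeros((spec.size, len(model.loci), 2), dtype=np.int64)
    for si, src in enumerate(sources):
        rows = np.where(picks == si)[0]
        if rows.size == 0:
            continue
        for j, locus in enumerate(model.loci):
            calls[rows, j] = _draw_genotypes(
                rng, model.freqs[src][locus], rows.size, model.f[src])
    meta = pd.DataFrame({
        "population": spec.name,
        "cls": spec.cls,
        "lon": np.nan,
        "lat": np.nan,
        "true_source": [sources[k] for k in picks],
    }, index=individuals)
    return GenotypeTable(individuals, model.loci, calls, meta)


def concat_tables(tables) -> GenotypeTable:
    """Stack tables sharing the same locus panel."""
    tables = list(tables)
    loci = tables[0].loci
    for t in tables[1:]:
        if t.loci != loci:
            raise ValueError("tables have different locus panels")
    individuals = sum((t.individuals for t in tables), [])
    calls = np.concatenate([t.calls for t in tables], axis=0)
    meta = pd.concat([t.metadata for t in tables], axis=0)
    return GenotypeTable(individuals, loci, calls, meta)


def corrupt(table: GenotypeTable, missing_rate: float = 0.0,
            duplicate_rate: float = 0.0, null_allele_spec=None,
            seed=None) -> GenotypeTable:
    """Apply field-realistic degradations.

    Duplicates: ``round(duplicate_rate * n)`` individuals are copied verbatim
    under new IDs (``duplicate_of`` records the original).  Null alleles: at
    each ``(locus, r)`` in ``null_allele_spec`` every gene copy is silently
    null with probability ``r``; a half-null genotype shows as a homozygote
    for the visible allele, a double null as a missing genotype.  Missing
    calls are then injected i.i.d. at ``missing_rate``.
    """
    for rate in (missing_rate, duplicate_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    individuals = list(table.individuals)
    calls = table.calls.copy()
    meta = table.metadata.copy()
    if "duplicate_of" not in meta.columns:
        meta["duplicate_of"] = None

    n_dup = int(round(duplicate_rate * len(individuals)))
    if n_dup:
        src_rows = rng.choice(len(individuals), size=n_dup, replace=False)
        dup_ids = [f"DUP_{individuals[r]}" for r in src_rows]
        calls = np.concatenate([calls, calls[src_rows].copy()], axis=0)
        dup_meta = meta.iloc[src_rows].copy()
        dup_meta.index = dup_ids
        dup_meta["duplicate_of"] = [individuals[r] for r in src_rows]
        meta = pd.concat([meta, dup_meta])
        individuals = individuals + dup_ids

    lidx = {l: j for j, l in enumerate(table.loci)}
    for locus, r in (null_allele_spec or {}).items():
        j = lidx[locus]
        typed = (calls[:, j] != 0).all(axis=1)
        nulled = rng.random((len(individuals), 2)) < r
        both = typed & nulled.all(axis=1)
        one = typed & (nulled.sum(axis=1) == 1)
        calls[both, j] = 0
        rows = np.where(one)[0]
        visible = np.where(nulled[rows, 0], calls[rows, j, 1],
                           calls[rows, j, 0])
        calls[rows, j, 0] = visible
        calls[rows, j, 1] = visible

    if missing_rate > 0:
        drop = rng.random((len(individuals), len(table.loci))) < missing_rate
        calls[drop] = 0
    return GenotypeTable(individuals, list(table.loci), calls, meta)


# ---------------------------------------------------------------------------
# study-shaped preset

#: reference population sizes of the emulated survey design
PRESET_SIZES = (13, 5, 23, 36, 12, 19, 6, 11, 45, 9)
#: per-population Wahlund-like inbreeding coefficients (range 0.11-0.22)
PRESET_F = (0.21, 0.12, 0.22, 0.16, 0.11, 0.12, 0.13, 0.15, 0.17, 0.14)


def survey_scenario(seed=None, private_freq=0.25, missing_rate=0.05,
                         duplicate_rate=0.04, ibd_strength=0.5):
    """The default end-to-end scenario: model, references, markets, seizure.

    Ten reference populations of 5-45 individuals at 20 loci, private
    alleles injected for seven populations at seven loci, two urban-market
    mixtures (84 and 248 individuals) drawing from all sources, and one
    10-individual seizure.  Returns ``(model, table)`` where ``table``
    stacks references, markets and the seizure after corruption.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    s_model, s_ref, s_m1, s_m2, s_sz, s_cor = ss.spawn(6)
    n_pops, n_loci = len(PRESET_SIZES), 20
    # 18 private alleles spread over 7 loci and 7 source populations,
    # mirroring the footprint of a real tracing panel
    private = []
    slots = [(0, 0), (1, 2), (2, 4), (3, 6), (4, 8), (5, 10), (6, 12),
             (0, 2), (1, 4), (2, 6), (3, 8), (4, 10), (5, 12), (6, 0),
             (0, 4), (1, 6), (2, 8), (3, 10)]
    for k, (pop, locus) in enumerate(slots):
        private.append((pop, locus, 301 + 2 * k, private_freq))
    model = simulate_model(
        n_pops=n_pops, n_loci=n_loci, alleles_per_locus=6,
        concentration=40.0, ibd_strength=ibd_strength,
        private_spec=private, f=PRESET_F, seed=s_model,
        ancestral_alpha=0.8)   # skewed ancestral spectrum -> He ~ 0.6-0.7
    sizes = {p: n for p, n in zip(model.populations, PRESET_SIZES)}
    refs = simulate_genotypes(model, sizes, seed=s_ref)
    even = {p: 1 / n_pops for p in model.populations}
    markets = [
        simulate_market(model, MarketSpec("Douala", even, 84), seed=s_m1),
        simulate_market(model, MarketSpec("Yaounde", even, 248), seed=s_m2),
        simulate_market(model, MarketSpec(
            "Seizure", even, 10, cls="seizure"), seed=s_sz),
    ]
    table = concat_tables([refs] + markets)
    table = corrupt(table, missing_rate=missing_rate,
                    duplicate_rate=duplicate_rate, seed=s_cor)
    return model, table
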