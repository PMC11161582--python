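"""Geographic tracing of trade samples through private-allele rarefaction.

The protocol: (1) compute, per locus and reference population, the rarefied
expected number of distinct and private alleles at standardized sample
size g (generalized hypergeometric rarefaction, as in allele-diversity
rarefaction software); (2) keep (locus, population) combinations whose
expected private-allele count at g* clears a threshold and is not
declining; (3) cross-filter against the alleles actually observed in
exactly one reference population; (4) screen market/seizure genotypes for
the retained private alleles and assign carriers to the allele's home
population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFrequencyTable, GenotypeTable


def _absent_prob(N: int, Ni: int, g: int, exact: bool = False):
    """P(allele with Ni of N gene copies absent from a subsample of g)."""
    if Ni > N:
        raise ValueError("allele count exceeds gene-copy total")
    if N - Ni < g:
        return Fraction(0) if exact else 0.0
    num = math.comb(N - Ni, g)
    den = math.comb(N, g)
    return Fraction(num, den) if exact else num / den


@dataclass
class RarefactionCurve:
    """Expected distinct / private allele counts per (locus, pop, g).

    ``g`` is expressed in the curve's declared unit (individuals by
    default; one individual = two gene copies).
    """

    distinct: dict      # (locus, pop) -> {g: value}
    private: dict       # (locus, pop) -> {g: value}
    unit: str = "individuals"
    populations: list = field(default_factory=list)
    loci: list = field(default_factory=list)

    def paf(self, locus, pop, g):
        return self.private[(locus, pop)][g]


def feasible_loci(freqs: AlleleFrequencyTable, g: int, pops=None,
                  unit: str = "individuals") -> list:
    """Loci where every population has >= g (individuals or gene copies).

    Rarefaction to g is undefined for a population with fewer typed gene
    copies; pipelines drop those loci rather than lowering g.
    """
    mult = 2 if unit == "individuals" else 1
    pops = list(pops) if pops is not None else list(freqs.populations)
    return [l for l in freqs.loci
            if min(freqs.n_genes(p, l) for p in pops) >= mult * g]


def rarefy_private_alleles(freqs: AlleleFrequencyTable, g_max: int,
                           pops=None, unit: str = "individuals",
                           g_min: int = 2, exact: bool = False,
                           loci=None) -> RarefactionCurve:
    """Generalized private-allele rarefaction over a population set.

    For allele i with ``N_ji`` of population j's ``N_j`` gene copies, the
    expected number of distinct alleles in a subsample of g gene copies is
    ``sum_i [1 - C(N_j - N_ji, g) / C(N_j, g)]`` and the expected number of
    alleles private to j within the set S is
    ``sum_i [1 - C(N_j - N_ji, g)/C(N_j, g)] * prod_{k != j} C(N_k - N_ki, g)/C(N_k, g)``.

    ``unit='individuals'`` (default) interprets g as diploid individuals
    and rarefies 2g gene copies; ``unit='genes'`` uses g gene copies
    directly.  With ``exact=True`` all values are ``fractions.Fraction``.
    """
    pops = list(pops) if pops is not None else list(freqs.populations)
    if len(pops) < 1:
        raise ValueError("need at least one population")
    mult = 2 if unit == "individuals" else 1
    if unit not in ("individuals", "genes"):
        raise ValueError(f"unknown rarefaction unit {unit!r}")
    distinct: dict = {}
    private: dict = {}
    grid = range(g_min, g_max + 1)
    loci = list(loci) if loci is not None else list(freqs.loci)
    for locus in loci:
        for g_u in grid:
            g = mult * g_u
            for pop in pops:
                if freqs.n_genes(pop, locus) < g:
                    raise ValueError(
                        f"g = {g} gene copies exceeds population "
                        f"{pop!r} at locus {locus!r} "
                        f"(n_genes = {freqs.n_genes(pop, locus)})")
        alleles = freqs.alleles(locus)
        counts = {p: freqs.counts(p, locus) for p in pops}
        totals = {p: freqs.n_genes(p, locus) for p in pops}
        for pop in pops:
            dd = distinct.setdefault((locus, pop), {})
            pp = private.setdefault((locus, pop), {})
            for g_u in grid:
                g = mult * g_u
                zero = Fraction(0) if exact else 0.0
                one = Fraction(1) if exact else 1.0
                d_sum = zero
                p_sum = zero
                for a in alleles:
                    q_home = _absent_prob(
                        totals[pop], counts[pop].get(a, 0), g, exact)
                    present = one - q_home
                    d_sum += present
                    absent_elsewhere = one
                    for other in pops:
                        if other == pop:
                            continue
                        absent_elsewhere *= _absent_prob(
                            totals[other], counts[other].get(a, 0), g, exact)
                    p_sum += present * absent_elsewhere
                dd[g_u] = d_sum
                pp[g_u] = p_sum
    return RarefactionCurve(distinct, private, unit, pops, loci)


def select_tracing_loci(curves: RarefactionCurve, paf_threshold: float = 0.4,
                        g_star: int = 5, slope_tolerance: float = 0.01
                        ) -> set:
    """(locus, population) combinations worth tracing with.

    Keeps entries whose rarefied private-allele expectation at ``g_star``
    exceeds ``paf_threshold`` and whose last step
    ``paf(g*) - paf(g* - 1)`` is not declining beyond ``slope_tolerance``
    (the plateau-or-increasing rule).
    """
    kept = set()
    for (locus, pop), curve in curves.private.items():
        if g_star not in curve or (g_star - 1) not in curve:
            raise ValueError(
                f"curves do not cover g* = {g_star} (and g* - 1)")
        paf_star = float(curve[g_star])
        slope = paf_star - float(curve[g_star - 1])
        if paf_star > paf_threshold and slope >= -slope_tolerance:
            kept.add((locus, pop))
    return kept


def observed_private_alleles(freqs: AlleleFrequencyTable, pops=None,
                             warn_degenerate: bool = True) -> set:
    """Alleles with positive count in exactly one reference population."""
    pops = list(pops) if pops is not None else list(freqs.populations)
    out = set()
    nonempty = [p for p in pops
                if any(freqs.n_genes(p, l) for l in freqs.loci)]
    if warn_degenerate and len(nonempty) < 2:
        warnings.warn("fewer than two non-empty populations: every allele "
                      "is trivially private", stacklevel=2)
    for locus in freqs.loci:
        for allele in freqs.alleles(locus):
            holders = [p for p in pops
                       if freqs.counts(p, locus).get(allele, 0) > 0]
            if len(holders) == 1:
                out.add((locus, allele, holders[0]))
    return out


@dataclass
class TracingPanel:
    """Retained (locus, allele) -> source population diagnostic markers."""

    entries: list   # of (locus, allele, population)

    def __post_init__(self):
        seen = {}
        for locus, allele, pop in self.entries:
            key = (locus, allele)
            if key in seen and seen[key] != pop:
                raise ValueError(
                    f"allele {allele} at {locus} mapped to two sources")
            seen[key] = pop

    @property
    def loci(self) -> set:
        return {locus for locus, _, _ in self.entries}

    def lookup(self, locus, allele):
        for l, a, p in self.entries:
            if l == locus and a == allele:
                return p
        return None

    def to_tsv(self, path):
        pd.DataFrame(self.entries,
                     columns=["locus", "allele", "source"]) \
            .to_csv(path, sep="\t", index=False)


def build_panel(candidates: set, observed: set) -> TracingPanel:
    """Intersect rarefaction-supported loci with observed private alleles."""
    entries = [(locus, allele, pop) for (locus, allele, pop) in sorted(observed)
               if (locus, pop) in candidates]
    if not entries:
        warnings.warn("empty tracing panel: no locus is both "
                      "rarefaction-supported and observed-private",
                      stacklevel=2)
    return TracingPanel(entries)


@dataclass
class TraceAssignment:
    """Market/seizure individual -> private-allele evidence and source(s)."""

    assignments: pd.DataFrame   # individual, market, sources, evidence, conflict

    def assigned(self, include_conflicted: bool = False) -> pd.DataFrame:
        df = self.assignments[self.assignments["sources"].map(len) > 0]
        if not include_conflicted:
            df = df[~df["conflict"]]
        return df

    def to_tsv(self, path):
        df = self.assignments.copy()
        df["sources"] = df["sources"].map(lambda s: ",".join(sorted(s)))
        df["evidence"] = df["evidence"].map(
            lambda ev: ";".join(f"{l}:{a}->{p}" for l, a, p in ev))
        df.to_csv(path, sep="\t", index=False)


def assign(market_table: GenotypeTable, panel: TracingPanel
           ) -> TraceAssignment:
    """Screen market/seizure genotypes for panel alleles.

    An individual carrying >= 1 panel allele of population P is assigned to
    P; carriers of panel alleles from several populations are flagged as
    conflicted (reported, not dropped).
    """
    unknown = panel.loci - set(market_table.loci)
    if unknown:
        raise ValueError(f"panel loci {sorted(unknown)} absent from table")
    lidx = {l: j for j, l in enumerate(market_table.loci)}
    recs = []
    for i, ind in enumerate(market_table.individuals):
        evidence = []
        for locus, allele, pop in panel.entries:
            call = market_table.calls[i, lidx[locus]]
            if MISSING in call:
                continue
            if allele in call:
                evidence.append((locus, int(allele), pop))
        sources = {pop for _, _, pop in evidence}
        recs.append({
            "individual": ind,
            "market": market_table.metadata.loc[ind, "population"],
            "sources": sources,
            "evidence": evidence,
            "conflict": len(sources) > 1,
        })
    return TraceAssignment(pd.DataFrame(recs))


def trace_summary(assignment: TraceAssignment,
                  include_conflicted: bool = False) -> pd.DataFrame:
    """Source x market count matrix (chord-diagram-ready).

    By default only non-conflicted assignments are counted; conflicted
    individuals contribute one count per candidate source when included.
    """
    df = assignment.assigned(include_conflicted)
    counts: dict = {}
    for rec in df.itertuples(index=False):
        for src in rec.sources:
            counts[(src, rec.market)] = counts.get((src, rec.market), 0) + 1
    if not counts:
        return pd.DataFrame()
    sources = sorted({s for s, _ in counts})
    markets = sorted({m for _, m in counts})
    out = pd.DataFrame(0, index=sources, columns=markets)
    for (s, m), k in counts.items():
        out.loc[s, m] = k
    return out
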