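"""Individual identification from multilocus genotypes.

De-duplication of trade samples rests on three pillars: exhaustive pairwise
genotype matching (missing data never count as mismatches), the probability
of drawing a given multilocus genotype from a reference gene pool (pgen)
and of meeting it more than once in a cohort (psex), and the population-level
discriminability indices PI, unbiased PI and PI among siblings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, AlleleFrequencyTable, GenotypeTable

NOT_REACHABLE = -1


@dataclass
class MatchPair:
    id1: str
    id2: str
    shared_loci: int
    mismatches: int


def find_matches(table: GenotypeTable, max_mismatch_loci: int = 0,
                 min_shared_loci: int = 1) -> list:
    """All pairs identical at their mutually typed loci.

    A pair is reported when it shares >= ``min_shared_loci`` typed loci and
    differs at <= ``max_mismatch_loci`` of them.  Missing genotypes are
    ignored, never counted as mismatches.
    """
    if min_shared_loci > table.n_loci:
        raise ValueError("min_shared_loci exceeds the number of loci")
    typed = table.typed_mask()
    calls = table.calls
    same = (calls[:, None, :, :] == calls[None, :, :, :]).all(axis=3)
    both = typed[:, None, :] & typed[None, :, :]
    shared = both.sum(axis=2)
    mismatch = (both & ~same).sum(axis=2)
    out = []
    n = table.n_individuals
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] >= min_shared_loci \
                    and mismatch[i, j] <= max_mismatch_loci:
                out.append(MatchPair(table.individuals[i],
                                     table.individuals[j],
                                     int(shared[i, j]),
                                     int(mismatch[i, j])))
    return out


# ---------------------------------------------------------------------------
# genotype probability


def pgen(genotype, freqs: AlleleFrequencyTable, pop="pooled",
         f: float = 0.0, floor: float | None = None) -> float:
    """Probability of a multilocus genotype given reference frequencies.

    Per locus: ``p_i^2 + f p_i (1 - p_i)`` for a homozygote and
    ``2 p_i p_j (1 - f)`` for a heterozygote; the product runs over typed
    loci.  Alleles absent from the reference table get the floor frequency
    ``1 / (2N + 1)`` (N = reference gene copies at that locus) so that
    market genotypes never receive probability zero.
    """
    prob = 1.0
    for locus, (a, b) in genotype.items():
        if a == MISSING or b == MISSING:
            continue
        fr = freqs.freqs(pop, locus)
        n_genes = freqs.n_genes(pop, locus)
        lo = floor if floor is not None else 1 / (2 * n_genes + 1) \
            if n_genes else 1e-6
        pa = fr.get(a, lo)
        pb = fr.get(b, lo)
        if a == b:
            prob *= pa ** 2 + f * pa * (1 - pa)
        else:
            prob *= 2 * pa * pb * (1 - f)
    return prob


def psex(p: float, n_population: int) -> float:
    """P(genotype with draw probability p occurs again among n - 1 others)."""
    if n_population < 2:
        return 0.0
    # -expm1((n-1) log1p(-p)) keeps precision for forensic-scale tiny p
    return float(-math.expm1((n_population - 1) * math.log1p(-p)))


def genotype_of(table: GenotypeTable, individual) -> dict:
    i = table.individuals.index(individual)
    return {locus: (int(table.calls[i, j, 0]), int(table.calls[i, j, 1]))
            for j, locus in enumerate(table.loci)}


# ---------------------------------------------------------------------------
# probability of identity


def _pi_from_moments(a2: float, a4: float) -> float:
    # PI = sum p^4 + sum_{i<j} (2 p_i p_j)^2 = 2 a2^2 - a4
    return 2 * a2 ** 2 - a4


def pi_point(p) -> float:
    """PI for one locus: probability two random HWE genotypes match."""
    p = np.asarray(p, dtype=float)
    return float(_pi_from_moments((p ** 2).sum(), (p ** 4).sum()))


def upi_point(p, n_genes: int) -> float:
    """Small-sample unbiased PI estimator.

    ``n_genes`` is the number of sampled gene copies (2 x genotypes) behind
    the frequency estimates; with a_k the k-th frequency moments,

        uPI = [n^3 (2 a2^2 - a4) - 2 n^2 (a3 + 2 a2) + n (9 a2 + 2) - 6]
              / [(n - 1)(n - 2)(n - 3)]

    whose expectation over sampling equals the true PI and which tends to
    ``2 a2^2 - a4 = PI`` as n grows.
    """
    n = n_genes
    if n < 4:
        raise ValueError("uPI undefined for n < 4 gene copies")
    p = np.asarray(p, dtype=float)
    a2 = (p ** 2).sum()
    a3 = (p ** 3).sum()
    a4 = (p ** 4).sum()
    num = (n ** 3 * (2 * a2 ** 2 - a4) - 2 * n ** 2 * (a3 + 2 * a2)
           + n * (9 * a2 + 2) - 6)
    den = (n - 1) * (n - 2) * (n - 3)
    return float(num / den)


def pisibs_point(p) -> float:
    """PI among full siblings: 0.25 + 0.5 a2 + 0.5 a2^2 - 0.25 a4."""
    p = np.asarray(p, dtype=float)
    a2 = (p ** 2).sum()
    a4 = (p ** 4).sum()
    return float(0.25 + 0.5 * a2 + 0.5 * a2 ** 2 - 0.25 * a4)


@dataclass
class IdentityResult:
    """Per-locus and cumulative PI indices (cumulative = running product)."""

    per_locus: pd.DataFrame
    cumulative: dict = field(default_factory=dict)

    def to_tsv(self, path):
        self.per_locus.to_csv(path, sep="\t", index=False)


def probability_of_identity(freqs: AlleleFrequencyTable,
                            pop="pooled") -> IdentityResult:
    """PI, uPI and PIsibs per locus plus cumulative products.

    Loci are kept in table order for the cumulative columns; n for uPI is
    the number of typed genotypes behind the frequency table
    (gene copies / 2).  Loci with n < 4 get NaN uPI.
    """
    recs = []
    for locus in freqs.loci:
        fr = freqs.freqs(pop, locus)
        if not fr:
            continue
        p = np.array(list(fr.values()))
        n_genes = freqs.n_genes(pop, locus)
        recs.append({
            "locus": locus, "n": n_genes // 2,
            "PI": pi_point(p),
            "uPI": upi_point(p, n_genes) if n_genes >= 4 else math.nan,
            "PIsibs": pisibs_point(p),
        })
    df = pd.DataFrame(recs)
    for col in ("PI", "uPI", "PIsibs"):
        df[f"cum_{col}"] = df[col].cumprod()
    cum = {col: float(df[f"cum_{col}"].iloc[-1]) for col in
           ("PI", "uPI", "PIsibs")} if len(df) else {}
    return IdentityResult(df, cum)


def min_loci_for_pi(per_locus_pi, threshold: float) -> int:
    """Smallest panel size whose cumulative PI drops below ``threshold``.

    Loci are greedily ordered by ascending per-locus PI (most informative
    first).  Returns ``NOT_REACHABLE`` when even the full panel stays at or
    above the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    prod = 1.0
    for k, pi in enumerate(sorted(per_locus_pi), start=1):
        prod *= pi
        if prod < threshold:
            return k
    return NOT_REACHABLE
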