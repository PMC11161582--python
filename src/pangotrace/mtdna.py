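"""Cytochrome-b workflow: haplotypes, K2P/NJ lineages, mismatch analysis.

Sequences enter as an aligned FASTA; the pipeline collapses identical
sequences into haplotypes, computes the standard diversity quartet
(segregating sites S, haplotype number h, haplotype diversity Hd,
nucleotide diversity pi), assigns queries to reference mitochondrial
lineages by neighbour-joining on Kimura two-parameter distances, and tests
for sudden demographic expansion with the mismatch distribution (least-
squares fit of the closed-form expansion curve, SSD and Harpending's
raggedness assessed by parametric coalescent bootstrap).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import optimize, special, stats  # noqa: F401  (stats used by callers)
from skbio import DistanceMatrix
from skbio.tree import nj

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = (0, 2)


@dataclass
class Alignment:
    """Equal-length DNA sequences with IDs (uint8-coded; 255 = ambiguous)."""

    ids: list
    matrix: np.ndarray          # (n, L) uint8

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("ragged alignment: sequences differ in length")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def subset(self, ids) -> "Alignment":
        idx = [self.ids.index(i) for i in ids]
        return Alignment(list(ids), self.matrix[idx])

    @classmethod
    def from_strings(cls, records) -> "Alignment":
        """records: iterable of (id, sequence string)."""
        ids, rows = [], []
        length = None
        for name, seq in records:
            seq = seq.upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"sequence {name!r} has length {len(seq)} != {length}")
            ids.append(name)
            rows.append([_CODE.get(c, 255) for c in seq])
        return cls(ids, np.asarray(rows, dtype=np.uint8))


def read_fasta(path) -> Alignment:
    """Load an aligned FASTA (Bio.SeqIO underneath)."""
    recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise ValueError(f"no sequences in {path}")
    return Alignment.from_strings(recs)


_DECODE = np.array(list("ACGT"), dtype="U1")


def write_fasta(alignment: Alignment, path):
    with open(path, "w") as fh:
        for i, name in enumerate(alignment.ids):
            row = alignment.matrix[i]
            chars = np.where(row == 255, "N", _DECODE[np.minimum(row, 3)])
            fh.write(f">{name}\n{''.join(chars)}\n")


# ---------------------------------------------------------------------------
# haplotypes and diversity


@dataclass
class HaplotypeSet:
    """Collapsed haplotypes with membership and optional lineage labels."""

    alignment: Alignment                  # retained sequences only
    members: dict                         # hap name -> list of sequence IDs
    hap_index: dict                       # hap name -> row in alignment of rep
    lineage: dict = field(default_factory=dict)   # sequence ID -> label
    dropped: list = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.members)

    def haplotype_of(self, seq_id) -> str:
        for hap, ids in self.members.items():
            if seq_id in ids:
                return hap
        raise KeyError(seq_id)

    def to_tsv(self, path):
        recs = [{"haplotype": h, "member": m,
                 "lineage": self.lineage.get(m, "")}
                for h, ids in self.members.items() for m in ids]
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def collapse_haplotypes(alignment: Alignment, missing_policy: str = "strict",
                        lineage: dict | None = None) -> HaplotypeSet:
    """Group identical sequences into haplotypes.

    ``missing_policy='strict'`` drops sequences containing anything but
    unambiguous A/C/G/T before collapsing (complete-case analysis);
    ``'keep'`` retains them (ambiguity codes compare as their own state).
    """
    if missing_policy not in ("strict", "keep"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    keep_rows, dropped = [], []
    for i, name in enumerate(alignment.ids):
        if missing_policy == "strict" and (alignment.matrix[i] == 255).any():
            dropped.append(name)
        else:
            keep_rows.append(i)
    sub = Alignment([alignment.ids[i] for i in keep_rows],
                    alignment.matrix[keep_rows])
    members: dict = {}
    hap_index: dict = {}
    seen: dict = {}
    for i, name in enumerate(sub.ids):
        key = sub.matrix[i].tobytes()
        if key not in seen:
            hap = f"H{len(seen) + 1}"
            seen[key] = hap
            members[hap] = []
            hap_index[hap] = i
        members[seen[key]].append(name)
    return HaplotypeSet(sub, members, hap_index,
                        dict(lineage or {}), dropped)


def diversity_stats(hapset: HaplotypeSet, ids=None) -> dict:
    """S, h, Hd and pi for a group of sequences (default: all retained).

    Hd = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies; pi = mean
    pairwise difference count divided by alignment length; S = number of
    columns with >= 2 observed states.
    """
    ids = list(ids) if ids is not None else list(hapset.alignment.ids)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences for diversity statistics")
    sub = hapset.alignment.subset(ids)
    n, L = sub.n, sub.length
    s_sites = int(sum(len(set(sub.matrix[:, j].tolist()) - {255}) >= 2
                      for j in range(L)))
    keys = [sub.matrix[i].tobytes() for i in range(n)]
    _, counts = np.unique(keys, return_counts=True)
    p = counts / n
    hd = n / (n - 1) * (1 - (p ** 2).sum())
    diffs = _pairwise_differences(sub.matrix)
    iu = np.triu_indices(n, k=1)
    pi = float(diffs[iu].mean()) / L
    return {"S": s_sites, "h": int(len(counts)), "Hd": float(hd), "pi": pi}


def _pairwise_differences(matrix: np.ndarray) -> np.ndarray:
    """Pairwise difference counts over mutually unambiguous sites."""
    n = matrix.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    valid = matrix != 255
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (matrix[i] != matrix[i + 1:]) & both
        out[i, i + 1:] = diff.sum(axis=1)
    return out + out.T


# ---------------------------------------------------------------------------
# K2P distances and neighbour joining


def k2p_matrix(alignment: Alignment) -> np.ndarray:
    """Kimura two-parameter distance matrix with pairwise deletion.

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)), P and Q the transition and
    transversion proportions over sites unambiguous in both sequences.
    Saturated pairs (non-positive log argument) are reported as +inf.
    """
    m = alignment.matrix
    n = alignment.n
    purine = (m == 0) | (m == 2)
    valid = m != 255
    out = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        nsites = both.sum(axis=1).astype(float)
        diff = (m[i] != m[i + 1:]) & both
        ts = diff & (purine[i] == purine[i + 1:])   # same class, different base
        tv = diff & (purine[i] != purine[i + 1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts.sum(axis=1) / nsites
            Q = tv.sum(axis=1) / nsites
            w1 = 1 - 2 * P - Q
            w2 = 1 - 2 * Q
            d = np.where((w1 > 0) & (w2 > 0),
                         -0.5 * np.log(np.clip(w1, 1e-300, None)
                                       * np.sqrt(np.clip(w2, 1e-300, None))),
                         np.inf)
        out[i, i + 1:] = d
    return out + out.T


def nj_tree(matrix: np.ndarray, ids, n_bootstrap: int = 0,
            alignment: Alignment | None = None, seed=None):
    """Neighbour-joining tree (scikit-bio) with optional bootstrap support.

    Bootstrap resamples alignment columns, rebuilds the K2P/NJ tree and
    counts how often each internal bipartition of the point-estimate tree
    recurs; supports (percent) are stored on ``node.support``.  Returns a
    ``skbio.TreeNode``; serialise with ``str(tree)`` (Newick).
    """
    ids = list(ids)
    tree = nj(DistanceMatrix(np.asarray(matrix, dtype=float), ids))
    if n_bootstrap > 0:
        if alignment is None:
            raise ValueError("bootstrap requires the alignment")
        rng = np.random.default_rng(seed)
        taxa = frozenset(ids)
        counts: dict = {}
        for _ in range(n_bootstrap):
            cols = rng.integers(0, alignment.length, size=alignment.length)
            boot = Alignment(list(alignment.ids), alignment.matrix[:, cols])
            bt = nj(DistanceMatrix(_finite(k2p_matrix(boot)), ids))
            for split in _splits(bt, taxa):
                counts[split] = counts.get(split, 0) + 1
        for node in tree.non_tips(include_self=True):
            split = _node_split(node, taxa)
            node.support = (100.0 * counts.get(split, 0) / n_bootstrap
                            if split is not None else None)
    return tree


def _finite(d: np.ndarray) -> np.ndarray:
    if np.isinf(d).any():
        finite_max = d[np.isfinite(d)].max(initial=1.0)
        d = np.where(np.isinf(d), 10 * finite_max, d)
    return d


def _node_split(node, taxa: frozenset):
    side = frozenset(t.name for t in node.tips())
    if len(side) <= 1 or len(side) >= len(taxa) - 1:
        return None
    return min(side, taxa - side, key=lambda s: (len(s), sorted(s)))


def _splits(tree, taxa: frozenset) -> set:
    out = set()
    for node in tree.non_tips(include_self=True):
        split = _node_split(node, taxa)
        if split is not None:
            out.add(split)
    return out


def assign_lineage(queries: Alignment, references: Alignment,
                   ref_lineage: dict, min_overlap: int = 100,
                   n_bootstrap: int = 0, min_support: float | None = None,
                   seed=None) -> pd.DataFrame:
    """Assign each query to the lineage of its NJ-tree neighbourhood.

    A combined K2P/NJ tree is built and each query joins the lineage of its
    nearest reference(s) by tree path distance.  Path length, not the
    rooted clade structure, defines the neighbourhood because NJ topology
    is arbitrary across zero-length branches (identical haplotypes).
    Queries equidistant to references of several lineages are left
    unassigned with a tie diagnostic; with ``min_support`` set, the
    bootstrap support of the node connecting query and nearest reference
    must clear the threshold.  Queries overlapping the references at fewer
    than ``min_overlap`` unambiguous sites are unassigned.
    """
    if len(set(ref_lineage.values())) < 2:
        raise ValueError("references must cover >= 2 lineages")
    combined = Alignment(list(queries.ids) + list(references.ids),
                         np.vstack([queries.matrix, references.matrix]))
    dm = _finite(k2p_matrix(combined))
    tree = nj_tree(dm, combined.ids,
                   n_bootstrap=n_bootstrap, alignment=combined, seed=seed)
    tips = {t.name: t for t in tree.tips()}
    recs = []
    for q in queries.ids:
        qi = combined.ids.index(q)
        overlap_ok = ((combined.matrix[qi] != 255)
                      & (references.matrix != 255).any(axis=0)).sum() \
            >= min_overlap
        if not overlap_ok:
            recs.append({"query": q, "lineage": None,
                         "reason": "insufficient overlap"})
            continue
        dists = {r: tips[q].distance(tips[r]) for r in references.ids}
        dmin = min(dists.values())
        nearest = [r for r, d in dists.items() if d <= dmin + 1e-9]
        labels = {ref_lineage[r] for r in nearest}
        if len(labels) > 1:
            recs.append({"query": q, "lineage": None,
                         "reason": "tie: equidistant to lineages "
                         f"{sorted(labels)}"})
            continue
        label = labels.pop()
        if min_support is not None:
            lca = tree.lowest_common_ancestor([tips[q], tips[nearest[0]]])
            support = getattr(lca, "support", None)
            if support is not None and support < min_support:
                recs.append({"query": q, "lineage": None,
                             "reason": "clade support below threshold"})
                continue
        recs.append({"query": q, "lineage": label, "reason": ""})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# mismatch distribution


def expansion_mismatch_curve(i_max: int, tau: float, theta0: float,
                             theta1: float) -> np.ndarray:
    """Expected pairwise-difference distribution under sudden expansion.

    A pair coalesces at rate 1/theta1 (in mutational time, tau = 2ut)
    until tau and at rate 1/theta0 before; conditional on coalescence time
    s the difference count is Poisson(s).  Integrating gives, with
    a = (theta1 + 1)/theta1 and b = (theta0 + 1)/theta0,

    F_i = a^-(i+1)/theta1 * gammainc(i+1, a tau)
        + exp(tau (1/theta0 - 1/theta1)) * b^-(i+1)/theta0
          * gammaincc(i+1, b tau)

    which reduces to the geometric equilibrium curve
    theta^i / (1 + theta)^(i+1) when tau = 0 and theta0 = theta1.
    """
    i = np.arange(i_max + 1)
    theta0 = max(theta0, 1e-9)
    theta1 = max(theta1, 1e-9)
    a = (theta1 + 1) / theta1
    b = (theta0 + 1) / theta0
    recent = (1 / theta1) * a ** (-(i + 1.0)) * special.gammainc(i + 1.0,
                                                                 a * tau)
    # ancient term in log space: the prefactor explodes for tiny theta0
    # while the upper incomplete gamma vanishes; their product is <= 1
    tail = special.gammaincc(i + 1.0, b * tau)
    log_prefix = (tau * (1 / theta0 - 1 / theta1) - math.log(theta0)
                  - (i + 1.0) * math.log(b))
    with np.errstate(divide="ignore"):
        log_ancient = np.where(tail > 0, log_prefix + np.log(
            np.clip(tail, 1e-300, None)), -np.inf)
    ancient = np.exp(np.clip(log_ancient, -745, 50))
    return recent + ancient


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness over classes 0..d_max with zero padding.

    r = sum (x_i - x_{i-1})^2 with virtual zero classes before 0 and after
    d_max; a point mass at zero differences therefore gives r = 2.
    """
    x = np.concatenate([[0.0], np.asarray(freqs, dtype=float), [0.0]])
    return float((np.diff(x) ** 2).sum())


@dataclass
class MismatchFit:
    histogram: np.ndarray       # observed pair counts per difference class
    tau: float
    theta0: float
    theta1: float
    ssd: float
    raggedness: float
    p_ssd: float = math.nan
    p_raggedness: float = math.nan
    n_bootstrap: int = 0


def _fit_expansion(freqs: np.ndarray):
    """Least-squares (tau, theta0, theta1) for an observed frequency vector."""
    i_max = len(freqs) - 1
    mean_d = float((np.arange(len(freqs)) * freqs).sum())

    def ssd(params):
        tau, theta0, dtheta = params
        exp_curve = expansion_mismatch_curve(
            i_max, tau, theta0, theta0 + dtheta)
        return float(((freqs - exp_curve) ** 2).sum())

    starts = [(max(mean_d, 0.5), 0.1, max(mean_d, 1.0)),
              (max(mean_d / 2, 0.5), 0.5, 2 * max(mean_d, 1.0)),
              (0.5, 1.0, max(mean_d, 1.0))]
    best = None
    bounds = [(0, 4 * (i_max + 1)), (0, 100), (0, 1000)]
    for x0 in starts:
        res = optimize.minimize(ssd, x0, method="Nelder-Mead", bounds=bounds,
                                options={"maxiter": 2000, "xatol": 1e-6,
                                         "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    tau, theta0, dtheta = best.x
    return float(tau), float(theta0), float(theta0 + dtheta), float(best.fun)


def _expansion_mutations(rng, n: int, tau: float, theta0: float,
                         theta1: float) -> list:
    """Tip-membership sets of the mutations on a two-epoch genealogy.

    Kingman coalescent in mutational time (tau = 2ut): pairwise coalescence
    rate 1/theta1 until tau, 1/theta0 before, mutation rate 1/2 per lineage
    per unit.  Each returned array lists the tips below one mutation.
    """
    theta0 = max(theta0, 1e-6)
    theta1 = max(theta1, 1e-6)
    muts = []
    lineages = [np.array([i]) for i in range(n)]
    s = 0.0
    j = n
    while j > 1:
        theta = theta1 if s < tau else theta0
        rate = j * (j - 1) / (2 * theta)
        w = rng.exponential(1 / rate)
        if s < tau and s + w > tau:
            dt = tau - s
            coalesce = False
        else:
            dt = w
            coalesce = True
        n_mut = rng.poisson(j * dt / 2)
        for _ in range(n_mut):
            muts.append(lineages[rng.integers(0, j)])
        s += dt
        if coalesce:
            a, b = rng.choice(j, size=2, replace=False)
            a, b = (a, b) if a < b else (b, a)
            lineages[a] = np.concatenate([lineages[a], lineages[b]])
            del lineages[b]
            j -= 1
    return muts


def _simulate_expansion_diffs(rng, n: int, tau: float, theta0: float,
                              theta1: float) -> np.ndarray:
    """Pairwise difference matrix under the fitted two-epoch coalescent."""
    diffs = np.zeros((n, n), dtype=np.int64)
    for members in _expansion_mutations(rng, n, tau, theta0, theta1):
        mask = np.zeros(n, dtype=bool)
        mask[members] = True
        diffs[np.ix_(mask, ~mask)] += 1
    return diffs + diffs.T - np.diag(np.diag(diffs))


def simulate_expansion_alignment(n: int, length: int = 402, tau: float = 4.0,
                                 theta0: float = 0.5, theta1: float = 50.0,
                                 seed=None) -> Alignment:
    """Synthetic alignment under the sudden-expansion coalescent.

    Mutations from the two-epoch genealogy are placed on random sites
    (finite sites; repeat hits allowed, rare for length >> tau).
    """
    rng = np.random.default_rng(seed)
    mat = np.tile(rng.integers(0, 4, size=length).astype(np.uint8), (n, 1))
    for members in _expansion_mutations(rng, n, tau, theta0, theta1):
        site = rng.integers(0, length)
        shift = rng.integers(1, 4)
        mat[members, site] = (mat[members, site] + shift) % 4
    return Alignment([f"seq{i + 1}" for i in range(n)], mat)


def simulate_lineage_alignment(n_per_lineage=(20, 10), length: int = 402,
                               fixed_differences: int = 23,
                               within_theta: float = 3.0, seed=None):
    """Two divergent mitochondrial lineages with fixed differences.

    Lineage consensus sequences differ at ``fixed_differences`` sites;
    within each lineage, sequences vary by an equilibrium coalescent with
    the given theta.  Returns ``(Alignment, lineage dict)``.
    """
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=length).astype(np.uint8)
    sites = rng.choice(length, size=fixed_differences, replace=False)
    consensus = {"A": base.copy(), "B": base.copy()}
    consensus["B"][sites] = (consensus["B"][sites]
                             + rng.integers(1, 4, size=fixed_differences)) % 4
    ids, rows, lineage = [], [], {}
    for label, n in zip(("A", "B"), n_per_lineage):
        for k in range(n):
            seq = consensus[label].copy()
            ids.append(f"{label}{k + 1}")
            rows.append(seq)
            lineage[ids[-1]] = label
        # within-lineage variation via equilibrium genealogy (tau = 0)
        block = np.stack(rows[-n:])
        for members in _expansion_mutations(rng, n, 0.0, within_theta,
                                            within_theta):
            site = rng.integers(0, length)
            block[members, site] = (block[members, site]
                                    + rng.integers(1, 4)) % 4
        rows[-n:] = list(block)
    return Alignment(ids, np.stack(rows)), lineage


def mismatch_analysis(alignment: Alignment, n_bootstrap: int = 1000,
                      seed=None) -> MismatchFit:
    """Sudden-expansion mismatch test for one group of sequences.

    The observed pairwise-difference histogram is fitted by least squares
    to the closed-form expansion curve; goodness of fit (SSD) and
    Harpending's raggedness are referred to their distributions under the
    fitted model via parametric coalescent bootstrap, each replicate being
    refitted.  p-values use the add-one rule.
    """
    n = alignment.n
    if n < 10:
        warnings.warn(f"mismatch analysis on only {n} sequences",
                      stacklevel=2)
    d = _pairwise_differences(alignment.matrix)
    iu = np.triu_indices(n, k=1)
    obs = np.bincount(d[iu])
    freqs = obs / obs.sum()
    tau, theta0, theta1, ssd_obs = _fit_expansion(freqs)
    rag_obs = raggedness(freqs)
    p_ssd = p_rag = math.nan
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        hits_ssd = hits_rag = 0
        for _ in range(n_bootstrap):
            sim = _simulate_expansion_diffs(rng, n, tau, theta0, theta1)
            sfreq = np.bincount(sim[iu])
            sfreq = sfreq / sfreq.sum()
            _, _, _, ssd_b = _fit_expansion(sfreq)
            if ssd_b >= ssd_obs - 1e-15:
                hits_ssd += 1
            if raggedness(sfreq) >= rag_obs - 1e-15:
                hits_rag += 1
        p_ssd = (hits_ssd + 1) / (n_bootstrap + 1)
        p_rag = (hits_rag + 1) / (n_bootstrap + 1)
    return MismatchFit(obs, tau, theta0, theta1, ssd_obs, rag_obs,
                       p_ssd, p_rag, n_bootstrap)
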