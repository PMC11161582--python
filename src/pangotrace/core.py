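"""Core domain types for diploid microsatellite data.

Genotypes are unordered pairs of allele codes (integer fragment sizes in
base pairs, > 0); a call with any zero entry is treated as missing and
normalised to (0, 0).  The table couples the call matrix with per-sample
metadata (population label, sample class, site coordinates, mtDNA lineage).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0

#: sample classes used throughout the pipeline
CLASSES = ("reference", "market", "seizure")


class FormatError(ValueError):
    """Raised when an input file violates its declared layout."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls plus sample metadata.

    Parameters
    ----------
    individuals
        Ordered unique sample IDs.
    loci
        Ordered locus names.
    calls
        ``(n_individuals, n_loci, 2)`` int array of allele codes;
        ``(0, 0)`` encodes a missing genotype.  Pairs are stored sorted
        ascending so that identical genotypes compare equal.
    metadata
        DataFrame indexed by individual with (at least) columns
        ``population``, ``cls``, ``lon``, ``lat``.  Extra columns (e.g.
        ``true_source``, ``duplicate_of``, ``lineage``) are carried along.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    metadata: pd.DataFrame = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual IDs")
        if (self.calls < 0).any():
            raise ValueError("allele codes must be >= 0 (0 = missing)")
        # half-missing calls are not interpretable: normalise to missing
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        self.calls = np.sort(self.calls, axis=2)
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.individuals))
        else:
            self.metadata = self.metadata.reindex(self.individuals)
        for col, default in (("population", None), ("cls", "reference"),
                             ("lon", np.nan), ("lat", np.nan)):
            if col not in self.metadata.columns:
                self.metadata[col] = default

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n, m)`` mask of non-missing genotypes."""
        return (self.calls != MISSING).all(axis=2)

    def subset(self, ids) -> "GenotypeTable":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeTable(list(ids), list(self.loci),
                             self.calls[idx].copy(),
                             self.metadata.loc[list(ids)].copy())

    def equals(self, other: "GenotypeTable") -> bool:
        return (self.individuals == other.individuals
                and self.loci == other.loci
                and np.array_equal(self.calls, other.calls)
                and list(self.metadata["population"].fillna(""))
                == list(other.metadata["population"].fillna(""))
                and list(self.metadata["cls"]) == list(other.metadata["cls"]))


@dataclass
class PopulationMap:
    """Disjoint mapping population label -> individual IDs."""

    groups: dict
    coords: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for pop, ids in self.groups.items():
            ids = list(ids)
            if seen & set(ids):
                raise ValueError(f"population {pop!r} overlaps another")
            seen |= set(ids)
            self.groups[pop] = ids

    @classmethod
    def from_metadata(cls, table: GenotypeTable,
                      classes=("reference",)) -> "PopulationMap":
        """Group individuals of the given classes by their population label."""
        groups: dict = {}
        coords: dict = {}
        for ind in table.individuals:
            row = table.metadata.loc[ind]
            if classes is not None and row["cls"] not in classes:
                continue
            pop = row["population"]
            if pop is None or (isinstance(pop, float) and math.isnan(pop)):
                continue
            groups.setdefault(pop, []).append(ind)
            if pop not in coords and np.isfinite(row.get("lon", np.nan)):
                coords[pop] = (float(row["lon"]), float(row["lat"]))
        return cls(groups, coords)

    def validate(self, table: GenotypeTable):
        known = set(table.individuals)
        for pop, ids in self.groups.items():
            missing = set(ids) - known
            if missing:
                raise ValueError(
                    f"population {pop!r} references unknown IDs {sorted(missing)}")

    @property
    def populations(self) -> list:
        return list(self.groups)


class AlleleFrequencyTable:
    """Per (population, locus) allele gene-copy counts and frequencies."""

    def __init__(self, populations, loci):
        self.populations = list(populations)
        self.loci = list(loci)
        self._counts = {(p, l): {} for p in self.populations for l in self.loci}

    def counts(self, pop, locus) -> dict:
        return self._counts[(pop, locus)]

    def n_genes(self, pop, locus) -> int:
        return sum(self._counts[(pop, locus)].values())

    def freqs(self, pop, locus) -> dict:
        c = self._counts[(pop, locus)]
        n = sum(c.values())
        if n == 0:
            return {}
        return {a: k / n for a, k in c.items()}

    def alleles(self, locus) -> list:
        out = set()
        for p in self.populations:
            out |= set(self._counts[(p, locus)])
        return sorted(out)

    def pooled(self, pops=None) -> "AlleleFrequencyTable":
        """Merge the given populations (default: all) into one pool."""
        pops = list(pops) if pops is not None else list(self.populations)
        out = AlleleFrequencyTable(["pooled"], self.loci)
        for locus in self.loci:
            acc = out._counts[("pooled", locus)]
            for p in pops:
                for a, k in self._counts[(p, locus)].items():
                    acc[a] = acc.get(a, 0) + k
        return out


# ---------------------------------------------------------------------------
# operations


def allele_counts(table: GenotypeTable, partition: PopulationMap
                  ) -> AlleleFrequencyTable:
    """Tally gene copies per population and locus over non-missing calls."""
    partition.validate(table)
    aft = AlleleFrequencyTable(partition.populations, table.loci)
    index = {ind: i for i, ind in enumerate(table.individuals)}
    for pop, ids in partition.groups.items():
        rows = [index[i] for i in ids]
        sub = table.calls[rows]            # (k, m, 2)
        for j, locus in enumerate(table.loci):
            genos = sub[:, j, :]
            genos = genos[(genos != MISSING).all(axis=1)]
            vals, cnt = np.unique(genos.ravel(), return_counts=True)
            aft._counts[(pop, locus)] = {
                int(a): int(c) for a, c in zip(vals, cnt)}
    return aft


def filter_by_completeness(table: GenotypeTable,
                           min_fraction: float) -> GenotypeTable:
    """Keep individuals typed at >= ``min_fraction`` of loci (order kept)."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = table.typed_mask().mean(axis=1)
    keep = [ind for ind, f in zip(table.individuals, frac)
            if f >= min_fraction]
    return table.subset(keep)


# ---------------------------------------------------------------------------
# GenAlEx codominant CSV dialect


def read_genalex(path) -> GenotypeTable:
    """Read a GenAlEx codominant CSV.

    Layout: row 1 = ``n_loci, n_samples, n_pops, size_1 .. size_k``;
    row 2 = title then blanks then population names; row 3 = ``Sample, Pop``
    followed by two columns per locus (locus name, blank); data rows follow.
    0 encodes a missing allele.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 3:
        raise FormatError("GenAlEx file needs at least 3 header rows")
    head = rows[0]
    try:
        n_loci, n_samples, n_pops = (int(head[0]), int(head[1]), int(head[2]))
        pop_sizes = [int(x) for x in head[3:3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed GenAlEx header row 1: {head!r}") from exc
    header = rows[2]
    allele_cols = [c for c in header[2:] if True]
    if len(header) - 2 < 2 * n_loci:
        raise FormatError(
            f"header row 3 has {len(header) - 2} allele columns, "
            f"expected {2 * n_loci}")
    loci = [header[2 + 2 * j] for j in range(n_loci)]
    data = [r for r in rows[3:] if any(c.strip() for c in r)]
    if len(data) != n_samples:
        raise FormatError(
            f"header declares {n_samples} samples but file has "
            f"{len(data)} data rows (first data row is row 4)")
    if sum(pop_sizes) != n_samples:
        raise FormatError(
            f"population sizes {pop_sizes} do not sum to {n_samples}")
    individuals, pops = [], []
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    for i, row in enumerate(data):
        if len(row) < 2 + 2 * n_loci:
            raise FormatError(f"data row {i + 4} has too few columns")
        individuals.append(row[0])
        pops.append(row[1])
        try:
            for j in range(n_loci):
                calls[i, j, 0] = int(row[2 + 2 * j] or 0)
                calls[i, j, 1] = int(row[3 + 2 * j] or 0)
        except ValueError as exc:
            raise FormatError(
                f"non-integer allele in data row {i + 4}") from exc
    meta = pd.DataFrame({"population": pops, "cls": "reference"},
                        index=individuals)
    return GenotypeTable(individuals, loci, calls, meta)


def write_genalex(table: GenotypeTable, path, title="pangotrace export"):
    """Write the GenAlEx codominant CSV dialect (missing written as 0)."""
    pops_in_order: list = []
    for p in table.metadata["population"].fillna("unknown"):
        if p not in pops_in_order:
            pops_in_order.append(p)
    sizes = {p: 0 for p in pops_in_order}
    for p in table.metadata["population"].fillna("unknown"):
        sizes[p] += 1
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([table.n_loci, table.n_individuals, len(pops_in_order)]
                   + [sizes[p] for p in pops_in_order])
        w.writerow([title, "", ""] + list(pops_in_order))
        hdr = ["Sample", "Pop"]
        for locus in table.loci:
            hdr += [locus, ""]
        w.writerow(hdr)
        pop_col = table.metadata["population"].fillna("unknown")
        # GenAlEx groups samples by population
        for pop in pops_in_order:
            for i, ind in enumerate(table.individuals):
                if pop_col.iloc[i] != pop:
                    continue
                row = [ind, pop]
                for j in range(table.n_loci):
                    row += [int(table.calls[i, j, 0]),
                            int(table.calls[i, j, 1])]
                w.writerow(row)


# ---------------------------------------------------------------------------
# canonical long-format TSV

_TSV_COLS = ["sample", "population", "cls", "lon", "lat",
             "locus", "allele1", "allele2"]


def write_tsv(table: GenotypeTable, path):
    """Write the canonical long TSV (one row per sample x locus).

    Missing alleles become empty fields; the round trip is lossless for
    calls, population labels, classes and coordinates.
    """
    recs = []
    for i, ind in enumerate(table.individuals):
        row = table.metadata.loc[ind]
        for j, locus in enumerate(table.loci):
            a, b = (int(table.calls[i, j, 0]), int(table.calls[i, j, 1]))
            recs.append({
                "sample": ind,
                "population": row["population"] if pd.notna(row["population"]) else "",
                "cls": row["cls"],
                "lon": "" if pd.isna(row["lon"]) else row["lon"],
                "lat": "" if pd.isna(row["lat"]) else row["lat"],
                "locus": locus,
                "allele1": a if a != MISSING else "",
                "allele2": b if b != MISSING else "",
            })
    pd.DataFrame(recs, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "locus": str},
                     keep_default_na=False, na_values=[""])
    missing_cols = set(_TSV_COLS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"TSV lacks columns {sorted(missing_cols)}")
    individuals = list(dict.fromkeys(df["sample"]))
    loci = list(dict.fromkeys(df["locus"]))
    n, m = len(individuals), len(loci)
    calls = np.zeros((n, m, 2), dtype=np.int64)
    iidx = {s: i for i, s in enumerate(individuals)}
    lidx = {l: j for j, l in enumerate(loci)}
    meta = pd.DataFrame(index=individuals,
                        columns=["population", "cls", "lon", "lat"])
    for rec in df.itertuples(index=False):
        i, j = iidx[rec.sample], lidx[rec.locus]
        a1 = 0 if pd.isna(rec.allele1) else int(rec.allele1)
        a2 = 0 if pd.isna(rec.allele2) else int(rec.allele2)
        calls[i, j] = (a1, a2)
        meta.loc[rec.sample, "population"] = (
            rec.population if isinstance(rec.population, str) and rec.population
            else None)
        meta.loc[rec.sample, "cls"] = rec.cls if isinstance(rec.cls, str) else "reference"
        meta.loc[rec.sample, "lon"] = rec.lon if pd.notna(rec.lon) else np.nan
        meta.loc[rec.sample, "lat"] = rec.lat if pd.notna(rec.lat) else np.nan
    meta["lon"] = pd.to_numeric(meta["lon"], errors="coerce")
    meta["lat"] = pd.to_numeric(meta["lat"], errors="coerce")
    return GenotypeTable(individuals, loci, calls, meta)


# ---------------------------------------------------------------------------
# geographic distance

_EARTH_RADIUS_KM = 6371.0088


def geographic_distance_matrix(coords, method="great_circle") -> np.ndarray:
    """Pairwise distances (km) between (lon, lat) decimal-degree points.

    ``great_circle`` uses the haversine formula on a spherical Earth;
    ``euclidean`` treats decimal degrees as planar coordinates scaled by
    km-per-degree at the mean latitude (a common flat-map approximation).
    """
    pts = np.asarray(coords, dtype=float)
    lon = np.radians(pts[:, 0])
    lat = np.radians(pts[:, 1])
    if method == "great_circle":
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (np.sin(dlat / 2) ** 2
             + np.cos(lat)[:, None] * np.cos(lat)[None, :]
             * np.sin(dlon / 2) ** 2)
        return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    if method == "euclidean":
        km_per_deg = 2 * math.pi * _EARTH_RADIUS_KM / 360
        x = pts[:, 0] * km_per_deg * math.cos(lat.mean())
        y = pts[:, 1] * km_per_deg
        dx = x[:, None] - x[None, :]
        dy = y[:, None] - y[None, :]
        return np.sqrt(dx ** 2 + dy ** 2)
    raise ValueError(f"unknown method {method!r}")
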