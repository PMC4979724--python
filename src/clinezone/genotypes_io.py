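"""Reading, validation, and spatial pooling of microsatellite genotype data.

Genotypes are diploid allele-length calls at a set of microsatellite loci.
The two interchange formats supported are the classic GenePop text format
(2- or 3-digit diploid codes, ``00``/``000`` meaning a missing allele) and a
simple CSV dialect with an accompanying collection-site metadata table.

Collection sites sampled close together are pooled into analysis populations
by single-linkage closure over a great-circle distance threshold (default
4 km), with population coordinates taken as the sample-size-weighted mean of
the constituent site coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

ERAS = ("historical", "recent")
SPECIES_DESIGNATIONS = ("pure_fouquettei", "pure_nigrita", "putative_hybrid")

MISSING = 0  # allele code reserved for a missing call


class GenotypeDataError(ValueError):
    """Raised when genotype data violate a structural invariant."""


class GenepopParseError(GenotypeDataError):
    """Raised when a GenePop file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Diploid allele calls for a set of individuals at shared loci.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; an allele value of 0
    marks a missing call (both copies are 0 together — half-missing calls are
    rejected or promoted to fully missing at read time).
    """

    individual_id: list[str]
    collection_site: list[str]
    population_id: list[str]
    era: list[str]
    loci: list[str]
    calls: np.ndarray
    site_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.individual_id)
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (n, len(self.loci), 2):
            raise GenotypeDataError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {len(self.loci)} loci x 2"
            )
        for name, col in (
            ("collection_site", self.collection_site),
            ("population_id", self.population_id),
            ("era", self.era),
        ):
            if len(col) != n:
                raise GenotypeDataError(f"{name} has length {len(col)}, expected {n}")
        if len(set(self.individual_id)) != n:
            dupes = sorted(
                {i for i in self.individual_id if self.individual_id.count(i) > 1}
            )
            raise GenotypeDataError(f"duplicated individual ids: {dupes}")
        bad_era = sorted(set(self.era) - set(ERAS))
        if bad_era:
            raise GenotypeDataError(f"unknown era labels: {bad_era}")
        if np.any(self.calls < 0):
            raise GenotypeDataError("allele lengths must be positive integers")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if np.any(half):
            raise GenotypeDataError(
                "half-missing calls present (exactly one allele of a pair is 0)"
            )
        pop_era = {}
        for pop, era in zip(self.population_id, self.era):
            if pop_era.setdefault(pop, era) != era:
                raise GenotypeDataError(f"population {pop!r} spans multiple eras")

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_id:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.population_id) == population)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def population_sizes(self) -> dict[str, int]:
        return {p: len(self.population_indices(p)) for p in self.populations}

    def subset(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(
            individual_id=[self.individual_id[i] for i in indices],
            collection_site=[self.collection_site[i] for i in indices],
            population_id=[self.population_id[i] for i in indices],
            era=[self.era[i] for i in indices],
            loci=list(self.loci),
            calls=self.calls[indices],
            site_meta=self.site_meta,
        )

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return (self.calls == MISSING).all(axis=2)

    # -- GenePop output --------------------------------------------------

    def write_genepop(self, path, title: str = "clinezone export", digits: int = 3):
        """Write in GenePop format, one ``Pop`` block per population."""
        width = 10 ** digits
        if np.any(self.calls >= width):
            raise GenotypeDataError(
                f"allele lengths exceed {digits}-digit GenePop codes"
            )
        lines = [title]
        lines.extend(self.loci)
        for pop in self.populations:
            lines.append("Pop")
            for i in self.population_indices(pop):
                codes = "".join(
                    f"{a:0{digits}d}{b:0{digits}d} "
                    for a, b in self.calls[i]
                ).rstrip()
                lines.append(f"{self.individual_id[i]} , {codes}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class PopulationMeta:
    """Metadata for one analysis population (possibly a pool of sites)."""

    population_id: str
    era: str
    latitude: float
    longitude: float
    n: int
    weighted_latitude: float | None = None
    weighted_longitude: float | None = None
    species_designation: str = "putative_hybrid"
    transect_x: float | None = None

    def __post_init__(self) -> None:
        if self.weighted_latitude is None:
            self.weighted_latitude = self.latitude
        if self.weighted_longitude is None:
            self.weighted_longitude = self.longitude
        if self.n < 1:
            raise GenotypeDataError(f"population {self.population_id}: N must be >= 1")
        if not -90.0 <= self.latitude <= 90.0:
            raise GenotypeDataError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise GenotypeDataError(f"longitude {self.longitude} out of range")
        if self.era not in ERAS:
            raise GenotypeDataError(f"unknown era {self.era!r}")
        if self.species_designation not in SPECIES_DESIGNATIONS:
            raise GenotypeDataError(
                f"unknown species designation {self.species_designation!r}"
            )


# ---------------------------------------------------------------------------
# GenePop reading
# ---------------------------------------------------------------------------


def read_genepop(path, era: str = "recent") -> GenotypeMatrix:
    """Parse a GenePop file into a :class:`GenotypeMatrix`.

    The first line is a title, followed by locus names (one per line, or all
    on one comma-separated line), then ``Pop`` blocks of individuals written
    as ``id , 001003 002002 ...``. Allele codes are 2- or 3-digit; ``00`` or
    ``000`` marks a missing allele. A half-missing call (one allele coded 0)
    is promoted to fully missing with a warning. Populations are named
    ``pop_1``, ``pop_2``, ... in block order.
    """
    with open(path) as fh:
        raw = fh.readlines()
    if not raw:
        raise GenepopParseError(f"{path}: empty file")

    lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(raw)]
    # locus names: everything between title and first "pop" line
    loci: list[str] = []
    body_start = None
    for j, (_, ln) in enumerate(lines[1:], start=1):
        if ln.strip().lower() == "pop":
            body_start = j
            break
        txt = ln.strip()
        if txt:
            loci.extend(t.strip() for t in txt.split(",") if t.strip())
    if body_start is None:
        raise GenepopParseError(f"{path}: no 'Pop' separator found")
    if not loci:
        raise GenepopParseError(f"{path}: no locus names before first 'Pop'")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    pop_counter = 0
    block_count = 0
    digits = None
    for lineno, ln in lines[body_start:]:
        txt = ln.strip()
        if not txt:
            continue
        if txt.lower() == "pop":
            if pop_counter > 0 and block_count == 0:
                raise GenotypeDataError(
                    f"{path}: line {lineno}: empty Pop block before this separator"
                )
            pop_counter += 1
            block_count = 0
            continue
        if "," not in txt:
            raise GenepopParseError(
                f"{path}: line {lineno}: expected 'id , genotypes'"
            )
        ident, _, geno = txt.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"{path}: line {lineno}: {len(tokens)} genotypes for "
                f"{len(loci)} loci"
            )
        row = np.empty((len(loci), 2), dtype=np.int64)
        for k, tok in enumerate(tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(
                    f"{path}: line {lineno}: malformed allele code {tok!r} "
                    "(expected 4 or 6 digits)"
                )
            d = len(tok) // 2
            if digits is None:
                digits = d
            elif d != digits:
                raise GenepopParseError(
                    f"{path}: line {lineno}: allele code width {d} differs "
                    f"from {digits} used earlier in the file"
                )
            a, b = int(tok[:d]), int(tok[d:])
            if (a == 0) != (b == 0):
                warnings.warn(
                    f"{path}: line {lineno}: half-missing call at locus "
                    f"{loci[k]} promoted to fully missing",
                    stacklevel=2,
                )
                a = b = MISSING
            row[k] = (a, b)
        ids.append(ident.strip())
        pops.append(f"pop_{pop_counter}")
        rows.append(row)
        block_count += 1
    if pop_counter > 0 and block_count == 0:
        raise GenotypeDataError(f"{path}: trailing empty Pop block")
    if not rows:
        raise GenotypeDataError(f"{path}: no individuals found")

    return GenotypeMatrix(
        individual_id=ids,
        collection_site=list(pops),
        population_id=pops,
        era=[era] * len(ids),
        loci=loci,
        calls=np.stack(rows),
    )


# ---------------------------------------------------------------------------
# CSV reading
# ---------------------------------------------------------------------------


def read_genotype_csv(path, meta) -> GenotypeMatrix:
    """Read a long-format genotype CSV plus a collection-site metadata table.

    The genotype table needs columns ``individual, site, locus, allele1,
    allele2``; the metadata table needs ``site, latitude, longitude, era``.
    Missing calls have both allele columns empty (or 0); a half-missing call
    is an error, as is an individual whose site is absent from the metadata.
    """
    geno = pd.read_csv(path)
    geno.columns = [c.strip().lower() for c in geno.columns]
    required = {"individual", "site", "locus", "allele1", "allele2"}
    if not required.issubset(geno.columns):
        raise GenotypeDataError(
            f"genotype CSV missing columns: {sorted(required - set(geno.columns))}"
        )
    meta_df = meta if isinstance(meta, pd.DataFrame) else pd.read_csv(meta)
    meta_df = meta_df.copy()
    meta_df.columns = [c.strip().lower() for c in meta_df.columns]
    if not {"site", "latitude", "longitude", "era"}.issubset(meta_df.columns):
        raise GenotypeDataError(
            "metadata table needs columns site, latitude, longitude, era"
        )
    meta_df["site"] = meta_df["site"].astype(str)
    meta_idx = meta_df.set_index("site")

    missing_sites = sorted(
        set(geno["site"].astype(str)) - set(meta_idx.index)
    )
    if missing_sites:
        bad = sorted(
            geno.loc[geno["site"].astype(str).isin(missing_sites), "individual"]
            .astype(str)
            .unique()
        )
        raise GenotypeDataError(
            f"individuals with sites absent from metadata: {bad}"
        )

    a1 = pd.to_numeric(geno["allele1"], errors="coerce")
    a2 = pd.to_numeric(geno["allele2"], errors="coerce")
    half = a1.isna() != a2.isna()
    if half.any():
        rows = geno.loc[half, ["individual", "locus"]].astype(str)
        raise GenotypeDataError(
            "half-missing calls (one allele empty) for: "
            + ", ".join(f"{r.individual}/{r.locus}" for r in rows.itertuples())
        )
    geno = geno.assign(
        allele1=a1.fillna(MISSING).astype(np.int64),
        allele2=a2.fillna(MISSING).astype(np.int64),
    )
    dup = geno.duplicated(subset=["individual", "locus"], keep=False)
    if dup.any():
        bad = sorted(geno.loc[dup, "individual"].astype(str).unique())
        raise GenotypeDataError(f"duplicated individual/locus rows for: {bad}")

    loci = list(pd.unique(geno["locus"].astype(str)))
    individuals = list(pd.unique(geno["individual"].astype(str)))
    loc_pos = {l: k for k, l in enumerate(loci)}
    ind_pos = {i: k for k, i in enumerate(individuals)}
    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    sites = [None] * len(individuals)
    for row in geno.itertuples():
        i = ind_pos[str(row.individual)]
        k = loc_pos[str(row.locus)]
        calls[i, k] = (row.allele1, row.allele2)
        site = str(row.site)
        if sites[i] is None:
            sites[i] = site
        elif sites[i] != site:
            raise GenotypeDataError(
                f"individual {row.individual!r} assigned to multiple sites"
            )

    has_pop = "population" in meta_idx.columns
    pops = [
        str(meta_idx.loc[s, "population"]) if has_pop else s for s in sites
    ]
    eras = [str(meta_idx.loc[s, "era"]) for s in sites]
    return GenotypeMatrix(
        individual_id=individuals,
        collection_site=sites,
        population_id=pops,
        era=eras,
        loci=loci,
        calls=calls,
        site_meta=meta_df,
    )


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a sphere of radius 6371.0088 km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _letters(i: int) -> str:
    # A, B, ..., Z, AA, AB, ...
    name = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


@dataclass
class PoolingReport:
    """Outcome of site pooling: membership, exclusions, optional FST checks."""

    members: dict[str, list[str]]
    excluded_sites: list[dict]
    fst_checks: pd.DataFrame | None = None


def pool_collection_sites(
    gm: GenotypeMatrix,
    site_meta: pd.DataFrame,
    radius_km: float = 4.0,
    fst_guard: bool = False,
    min_orphan_n: int = 2,
    fst_reps: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[GenotypeMatrix, list[PopulationMeta], PoolingReport]:
    """Pool collection sites within ``radius_km`` into analysis populations.

    Sites are linked whenever their great-circle distance is within the
    radius and merged by single-linkage closure (A–B and B–C within radius
    pools all three even if A–C is not). Pooled population coordinates are
    the individual-count-weighted means of the member site coordinates.
    Populations are named alphabetically west to east by weighted longitude.

    An unpoolable site with fewer than ``min_orphan_n`` individuals is
    excluded with a warning and listed in the report. With ``fst_guard``,
    pairwise FST with permutation p-values is computed for every within-pool
    site pair; pairs still significant after Holm sequential-Bonferroni
    correction are reported (pooling is not blocked).
    """
    meta = site_meta.copy()
    meta.columns = [c.strip().lower() for c in meta.columns]
    meta["site"] = meta["site"].astype(str)
    meta = meta.set_index("site")

    site_arr = np.asarray(gm.collection_site)
    sites = [s for s in meta.index if s in set(site_arr)]
    absent = sorted(set(site_arr) - set(sites))
    if absent:
        raise GenotypeDataError(f"sites without metadata coordinates: {absent}")
    counts = {s: int((site_arr == s).sum()) for s in sites}

    lat = meta.loc[sites, "latitude"].to_numpy(float)
    lon = meta.loc[sites, "longitude"].to_numpy(float)

    # single-linkage closure via union-find
    parent = list(range(len(sites)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if haversine_km(lat[i], lon[i], lat[j], lon[j]) <= radius_km:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(sites)):
        groups.setdefault(find(i), []).append(i)

    excluded: list[dict] = []
    kept_groups: list[list[int]] = []
    for members in groups.values():
        n_total = sum(counts[sites[i]] for i in members)
        if len(members) == 1 and n_total < min_orphan_n:
            s = sites[members[0]]
            excluded.append(
                {
                    "site": s,
                    "n": n_total,
                    "reason": (
                        f"no neighbour within {radius_km} km and "
                        f"N={n_total} < {min_orphan_n}"
                    ),
                }
            )
            warnings.warn(
                f"site {s} excluded: {excluded[-1]['reason']}", stacklevel=2
            )
            continue
        kept_groups.append(members)

    # order pools west -> east by weighted longitude and assign letters
    def wmean(members, vals):
        w = np.array([counts[sites[i]] for i in members], float)
        v = np.array([vals[i] for i in members], float)
        return float(np.sum(w * v) / np.sum(w))

    kept_groups.sort(key=lambda ms: wmean(ms, lon))
    pop_names = [_letters(i) for i in range(len(kept_groups))]

    site_to_pop: dict[str, str] = {}
    metas: list[PopulationMeta] = []
    members_out: dict[str, list[str]] = {}
    for name, members in zip(pop_names, kept_groups):
        member_sites = [sites[i] for i in members]
        for s in member_sites:
            site_to_pop[s] = name
        era = {
            gm.era[k]
            for k, s in enumerate(site_arr)
            if s in member_sites
        }
        if len(era) != 1:
            raise GenotypeDataError(
                f"pooled population {name} would span eras {sorted(era)}"
            )
        metas.append(
            PopulationMeta(
                population_id=name,
                era=era.pop(),
                latitude=wmean(members, lat),
                longitude=wmean(members, lon),
                weighted_latitude=wmean(members, lat),
                weighted_longitude=wmean(members, lon),
                n=sum(counts[sites[i]] for i in members),
            )
        )
        members_out[name] = member_sites

    keep_idx = np.flatnonzero(np.isin(site_arr, list(site_to_pop)))
    pooled = GenotypeMatrix(
        individual_id=[gm.individual_id[i] for i in keep_idx],
        collection_site=[gm.collection_site[i] for i in keep_idx],
        population_id=[site_to_pop[gm.collection_site[i]] for i in keep_idx],
        era=[gm.era[i] for i in keep_idx],
        loci=list(gm.loci),
        calls=gm.calls[keep_idx],
        site_meta=gm.site_meta,
    )

    fst_checks = None
    if fst_guard:
        from .popgen_stats import pairwise_fst  # local import: avoids cycle

        rows = []
        by_site = GenotypeMatrix(
            individual_id=[gm.individual_id[i] for i in keep_idx],
            collection_site=[gm.collection_site[i] for i in keep_idx],
            population_id=[gm.collection_site[i] for i in keep_idx],
            era=[gm.era[i] for i in keep_idx],
            loci=list(gm.loci),
            calls=gm.calls[keep_idx],
        )
        for name, member_sites in members_out.items():
            testable = [s for s in member_sites if counts[s] > 1]
            if len(testable) < 2:
                continue
            idx = np.flatnonzero(np.isin(by_site.population_id, testable))
            res = pairwise_fst(by_site.subset(idx), reps=fst_reps, seed=seed,
                               alpha=alpha)
            for row in res.pairs.itertuples():
                rows.append(
                    {
                        "population": name,
                        "site_a": row.pop_a,
                        "site_b": row.pop_b,
                        "fst": row.fst,
                        "p_value": row.p_value,
                        "significant": row.significant,
                    }
                )
        fst_checks = pd.DataFrame(
            rows,
            columns=["population", "site_a", "site_b", "fst", "p_value",
                     "significant"],
        )
        for row in fst_checks.itertuples():
            if row.significant:
                warnings.warn(
                    f"pooled sites {row.site_a}/{row.site_b} in population "
                    f"{row.population} show significant differentiation "
                    f"(FST={row.fst:.3f}, p={row.p_value:.4f})",
                    stacklevel=2,
                )

    return pooled, metas, PoolingReport(members_out, excluded, fst_checks)


def attach_transect(
    metas: list[PopulationMeta], x: dict[str, float]
) -> list[PopulationMeta]:
    """Return copies of ``metas`` with transect positions filled in."""
    out = []
    for m in metas:
        if m.population_id not in x:
            raise KeyError(f"no transect position for {m.population_id}")
        out.append(replace(m, transect_x=float(x[m.population_id])))
    return out
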