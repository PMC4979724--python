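"""Synthetic microsatellite hybrid-zone datasets with known truth.

The generator emulates the sampling design of a two-species contact zone
surveyed along a one-dimensional transect: two diverged parental
allele-frequency pools, populations placed at fixed transect positions,
and per-individual admixture proportions following a sigmoid cline. Every
pipeline stage (frequency estimation, hybrid indices, cline fitting,
subsampling) can therefore be tested against known parameter values
without any external data.

Individual admixture is drawn around the population-level cline expectation
(a Beta distribution with configurable concentration) rather than from an
explicit pedigree; the downstream analyses consume only allele frequencies
and hybrid indices, so pedigree realism adds nothing to their testability.
Missing data and allele-specific dropout ("null alleles", which surface as
spurious homozygotes) can be layered on for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cline_models import ClineModelSpec, ClineParams, cline_mu
from .genotypes_io import MISSING, GenotypeMatrix, PopulationMeta
from .hybrid_index import ParentalFreqs

# historical-style sampling design: 7 populations spanning ~300 km with the
# uneven N typical of museum collections
DEFAULT_POSITIONS = (0.0, 233.259, 246.778, 253.849, 257.601, 263.314, 299.728)
DEFAULT_N = (16, 4, 17, 25, 6, 30, 19)


@dataclass
class SimulationConfig:
    """Settings for one synthetic hybrid-zone dataset.

    ``divergence`` in [0, 1] tilts the two parental pools apart (0 gives
    identical pools); ``private_allele_fraction`` zeroes that fraction of
    each locus's alleles in exactly one pool. The default of 0.55 matches
    the share of species-private alleles observed in the chorus-frog
    surveys (139 of 245 historical alleles, 147 of 291 recent ones). ``h_concentration`` is the
    Beta concentration of individual admixture around the population cline
    expectation (``inf`` makes individuals deterministic at the
    expectation). The default true cline is a no-tails decreasing sigmoid
    (c = 250 km, w = 15 km) over the historical-style sampling design.
    """

    loci: int = 11
    alleles_per_locus: tuple[int, int] = (4, 10)
    divergence: float = 0.8
    private_allele_fraction: float = 0.55
    positions: tuple = DEFAULT_POSITIONS
    n_per_pop: tuple = DEFAULT_N
    true_params: ClineParams = field(
        default_factory=lambda: ClineParams(center=250.0, width=15.0)
    )
    true_spec: ClineModelSpec = field(
        default_factory=lambda: ClineModelSpec(tails="none",
                                               orientation="decreasing")
    )
    h_concentration: float = 30.0
    missing_rate: float = 0.02
    null_allele_rate: float = 0.0
    era: str = "historical"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.n_per_pop):
            raise ValueError("positions and n_per_pop must share length")
        miss = np.atleast_1d(np.asarray(self.missing_rate, dtype=float))
        if miss.size not in (1, self.loci):
            raise ValueError(
                "missing_rate must be a scalar or one rate per locus"
            )
        for rate in (*miss, self.null_allele_rate, self.divergence,
                     self.private_allele_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if any(n < 1 for n in self.n_per_pop):
            raise ValueError("population sizes must be >= 1")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if (self.alleles_per_locus[0] < 2
                and self.private_allele_fraction > 0):
            raise ValueError(
                "private alleles require at least 2 alleles per locus"
            )


def simulate_parental_frequencies(cfg: SimulationConfig) -> ParentalFreqs:
    """Draw two diverged parental allele-frequency pools.

    Per locus a shared base frequency vector comes from a symmetric
    Dirichlet; each pool is then drawn from a Dirichlet centred on the base
    with concentration ``20 (1 - divergence) / divergence`` (divergence 0
    returns the base itself for both pools, so the pools are identical).
    Finally ``private_allele_fraction`` of the alleles are zeroed in one
    pool (alternating pools) and the vectors renormalised, creating
    pool-private alleles.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.alleles_per_locus
    ref, alt = {}, {}
    loci = [f"loc{j + 1:02d}" for j in range(cfg.loci)]
    for locus in loci:
        k = int(rng.integers(lo, hi + 1))
        base = rng.dirichlet(np.ones(k))
        if cfg.divergence == 0.0:
            p_ref = p_alt = base
        else:
            conc = 20.0 * (1.0 - cfg.divergence) / cfg.divergence + 1e-6
            p_ref = rng.dirichlet(base * conc + 1e-9)
            p_alt = rng.dirichlet(base * conc + 1e-9)
        p_ref, p_alt = p_ref.copy(), p_alt.copy()
        n_private = int(round(cfg.private_allele_fraction * k))
        if n_private:
            chosen = rng.choice(k, size=n_private, replace=False)
            for i, a in enumerate(chosen):
                if i % 2 == 0:
                    p_ref[a] = 0.0
                else:
                    p_alt[a] = 0.0
        for p in (p_ref, p_alt):
            if p.sum() == 0:
                p[rng.integers(k)] = 1.0
        p_ref = p_ref / p_ref.sum()
        p_alt = p_alt / p_alt.sum()
        # microsatellite-style integer allele lengths
        alleles = 100 + 2 * np.arange(k)
        ref[locus] = pd.Series(p_ref, index=alleles)
        alt[locus] = pd.Series(p_alt, index=alleles)
    genes = {l: 10_000 for l in loci}
    return ParentalFreqs(loci, ref, alt, dict(genes), dict(genes), 0.0)


def simulate_hybrid_zone(
    cfg: SimulationConfig, pf: ParentalFreqs
) -> tuple[GenotypeMatrix, list[PopulationMeta], pd.DataFrame]:
    """Simulate genotypes for populations along the true cline.

    Each population at position x has cline expectation q = mu(x; true
    params); each individual draws h ~ Beta(q nu, (1-q) nu) (h = q when the
    concentration is infinite) and then each of its 2 x loci allele copies
    independently from the mixture h f_alt + (1-h) f_ref. Missing-data and
    null-allele masking are applied last. Returns the genotype matrix, the
    population metadata (synthetic coordinates along a west-east line), and
    a truth table with each population's q and each individual's h.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    miss = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.missing_rate, dtype=float)),
        (len(pf.loci),),
    )
    ids, sites, pops, rows = [], [], [], []
    truth_rows = []
    metas = []
    lat0 = 30.5
    km_per_deg_lon = 111.32 * np.cos(np.radians(lat0))
    null_alleles = {}
    if cfg.null_allele_rate > 0:
        for locus in pf.loci:
            alleles = pf.ref[locus].index.to_numpy()
            mask = rng.random(alleles.size) < cfg.null_allele_rate
            null_alleles[locus] = set(alleles[mask])

    for p_idx, (x, n) in enumerate(zip(cfg.positions, cfg.n_per_pop)):
        pop = f"sim{p_idx + 1:02d}"
        q = float(cline_mu(x, cfg.true_params, cfg.true_spec))
        assert 0.0 <= q <= 1.0
        metas.append(
            PopulationMeta(
                population_id=pop, era=cfg.era, latitude=lat0,
                longitude=-92.0 + x / km_per_deg_lon, n=int(n),
                transect_x=float(x),
            )
        )
        for i in range(int(n)):
            if np.isinf(cfg.h_concentration) or q in (0.0, 1.0):
                h = q
            else:
                h = float(rng.beta(q * cfg.h_concentration,
                                   (1.0 - q) * cfg.h_concentration))
            ind = f"{pop}_i{i + 1:03d}"
            row = np.zeros((len(pf.loci), 2), dtype=np.int64)
            for k_loc, locus in enumerate(pf.loci):
                alleles = pf.ref[locus].index.to_numpy()
                mix = (h * pf.alt[locus].to_numpy()
                       + (1.0 - h) * pf.ref[locus].to_numpy())
                pair = rng.choice(alleles, size=2, p=mix / mix.sum())
                nulls = null_alleles.get(locus, ())
                a_null = pair[0] in nulls
                b_null = pair[1] in nulls
                if a_null and b_null:
                    pair = (MISSING, MISSING)
                elif a_null:
                    pair = (pair[1], pair[1])
                elif b_null:
                    pair = (pair[0], pair[0])
                if rng.random() < miss[k_loc]:
                    pair = (MISSING, MISSING)
                row[k_loc] = pair
            ids.append(ind)
            sites.append(pop)
            pops.append(pop)
            rows.append(row)
            truth_rows.append(
                {"individual": ind, "population": pop, "x": x,
                 "true_q": q, "true_h": h}
            )

    gm = GenotypeMatrix(
        individual_id=ids, collection_site=sites, population_id=pops,
        era=[cfg.era] * len(ids), loci=list(pf.loci), calls=np.stack(rows),
    )
    return gm, metas, pd.DataFrame(truth_rows)
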