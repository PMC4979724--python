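"""Per-population diversity statistics and permutation tests.

Covers the descriptive statistics used to characterise each sampling era and
to justify pooling of nearby collection sites: observed/expected
heterozygosity, effective allele numbers, rarefied allelic richness, private
alleles, Monte-Carlo exact Hardy-Weinberg tests, genotypic linkage
disequilibrium G-tests, and pairwise Weir-Cockerham FST with permutation
p-values. Multiple testing uses Holm's sequential Bonferroni where the
original analyses did ("table-wide sequential Bonferroni").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes_io import MISSING, GenotypeDataError, GenotypeMatrix

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Per-locus allele frequencies for one population.

    ``freqs[locus]`` is a Series indexed by allele with values summing to 1;
    ``gene_counts[locus]`` is twice the number of non-missing individuals.
    Loci with no non-missing calls are listed in ``missing_loci`` and absent
    from ``freqs``.
    """

    population: str
    freqs: dict[str, pd.Series]
    gene_counts: dict[str, int]
    missing_loci: list[str]


def allele_frequencies(gm: GenotypeMatrix, population: str) -> FrequencyTable:
    idx = gm.population_indices(population)
    freqs: dict[str, pd.Series] = {}
    counts: dict[str, int] = {}
    absent: list[str] = []
    for k, locus in enumerate(gm.loci):
        alleles = gm.calls[idx, k, :].ravel()
        alleles = alleles[alleles != MISSING]
        if alleles.size == 0:
            absent.append(locus)
            continue
        vals, cts = np.unique(alleles, return_counts=True)
        freqs[locus] = pd.Series(cts / alleles.size, index=vals, name=locus)
        counts[locus] = int(alleles.size)
    return FrequencyTable(population, freqs, counts, absent)


# ---------------------------------------------------------------------------
# Diversity summary
# ---------------------------------------------------------------------------


def _rarefied_richness(allele_counts: np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a random subsample of g genes.

    ``sum_a [1 - C(2n - n_a, g) / C(2n, g)]`` with n_a the observed copy
    count of allele a and 2n the sampled gene count.
    """
    total = int(allele_counts.sum())
    if g > total:
        raise ValueError(f"rarefaction size {g} exceeds gene count {total}")
    # log C(total - n_a, g) - log C(total, g), with C := 0 when total-n_a < g
    rest = total - allele_counts
    with np.errstate(invalid="ignore"):
        log_num = gammaln(rest + 1) - gammaln(g + 1) - gammaln(rest - g + 1)
    log_den = gammaln(total + 1) - gammaln(g + 1) - gammaln(total - g + 1)
    ratio = np.where(rest >= g, np.exp(log_num - log_den), 0.0)
    return float(np.sum(1.0 - ratio))


def diversity_summary(
    gm: GenotypeMatrix,
    rarefaction_g: int = 6,
    unbiased_he: bool = True,
) -> pd.DataFrame:
    """Per-population diversity statistics averaged over loci.

    Columns: ``N`` (individuals), ``num_alleles`` (mean observed alleles per
    locus), ``eff_num_alleles`` (mean of 1/sum p^2), ``allelic_richness``
    (mean rarefied to ``rarefaction_g`` genes), ``H_o``, ``H_e`` (Nei's
    unbiased expected heterozygosity (2n/(2n-1))(1 - sum p^2) unless
    ``unbiased_he`` is off), and ``G_IS`` = 1 - H_o/H_e (NaN when H_e = 0).

    Raises if ``rarefaction_g`` exceeds the smallest per-locus gene count
    among loci with data.
    """
    min_genes = None
    for pop in gm.populations:
        ft = allele_frequencies(gm, pop)
        for locus in ft.freqs:
            gc = ft.gene_counts[locus]
            min_genes = gc if min_genes is None else min(min_genes, gc)
    if min_genes is None:
        raise GenotypeDataError("no genotype data at any locus")
    if rarefaction_g > min_genes:
        raise ValueError(
            f"rarefaction_g={rarefaction_g} exceeds the smallest per-locus "
            f"gene count ({min_genes}); choose g <= {min_genes}"
        )

    rows = []
    for pop in gm.populations:
        idx = gm.population_indices(pop)
        ft = allele_frequencies(gm, pop)
        n_all, eff, ar, ho, he = [], [], [], [], []
        for k, locus in enumerate(gm.loci):
            if locus not in ft.freqs:
                continue
            p = ft.freqs[locus].to_numpy()
            genes = ft.gene_counts[locus]
            n_all.append(p.size)
            sum_p2 = float(np.sum(p * p))
            eff.append(1.0 / sum_p2)
            counts = np.round(ft.freqs[locus].to_numpy() * genes).astype(int)
            ar.append(_rarefied_richness(counts, rarefaction_g))
            calls = gm.calls[idx, k, :]
            ok = calls[:, 0] != MISSING
            ho.append(float(np.mean(calls[ok, 0] != calls[ok, 1])))
            h = 1.0 - sum_p2
            if unbiased_he:
                h *= genes / (genes - 1.0) if genes > 1 else 1.0
            he.append(h)
        mean_ho, mean_he = float(np.mean(ho)), float(np.mean(he))
        gis = 1.0 - mean_ho / mean_he if mean_he > 0 else np.nan
        rows.append(
            {
                "population": pop,
                "N": len(idx),
                "num_alleles": float(np.mean(n_all)),
                "eff_num_alleles": float(np.mean(eff)),
                "allelic_richness": float(np.mean(ar)),
                "H_o": mean_ho,
                "H_e": mean_he,
                "G_IS": gis,
            }
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------


def private_alleles(
    gm: GenotypeMatrix,
    species_assignment: dict[str, str],
    require_full_assignment: bool = True,
) -> pd.DataFrame:
    """Count alleles observed in exactly one species pool, per locus.

    ``species_assignment`` maps population ids to pool labels (typically the
    two parental species). Populations without an assignment are an error
    when ``require_full_assignment``; otherwise they are left out of every
    pool (the convention for excluding hybrid-zone populations).
    """
    unassigned = [p for p in gm.populations if p not in species_assignment]
    if unassigned and require_full_assignment:
        raise GenotypeDataError(
            f"populations without species assignment: {sorted(unassigned)}"
        )
    pools = sorted(set(species_assignment.values()))
    observed: dict[str, dict[str, set]] = {
        pool: {locus: set() for locus in gm.loci} for pool in pools
    }
    for pop in gm.populations:
        pool = species_assignment.get(pop)
        if pool is None:
            continue
        ft = allele_frequencies(gm, pop)
        for locus, fr in ft.freqs.items():
            observed[pool][locus].update(int(a) for a in fr.index)

    rows = []
    for locus in gm.loci:
        row = {"locus": locus}
        for pool in pools:
            others = set().union(
                *(observed[q][locus] for q in pools if q != pool)
            ) if len(pools) > 1 else set()
            row[pool] = len(observed[pool][locus] - others)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("locus")
    out.loc["total"] = out.sum()
    return out


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------


def holm_correction(pvalues, alpha: float = 0.05):
    """Holm step-down (sequential Bonferroni) adjusted p-values and rejections.

    NaN entries are ignored (returned as NaN / not rejected) and do not
    count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m:
        idx = np.flatnonzero(ok)[np.argsort(p[ok], kind="stable")]
        running = 0.0
        for rank, i in enumerate(idx):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
    reject = np.where(ok, adj <= alpha, False)
    return adj, reject


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo)
# ---------------------------------------------------------------------------


def _genotype_log_prob_stat(pairs_min, pairs_max):
    """Variable part of Levene's conditional genotype-table log-probability.

    For genotype counts ``c_g`` with ``h`` heterozygous individuals and fixed
    allele counts, ``log P = const + h ln 2 - sum_g log(c_g!)``. Works on
    batches: ``pairs_min/pairs_max`` have shape (reps, n).
    """
    het = (pairs_min != pairs_max).sum(axis=1)
    key = pairs_min * 4096 + pairs_max
    k = np.sort(key, axis=1)
    n = k.shape[1]
    pos = np.arange(n)
    new_run = np.ones_like(k, dtype=bool)
    new_run[:, 1:] = k[:, 1:] != k[:, :-1]
    run_start = np.where(new_run, pos, 0)
    run_start = np.maximum.accumulate(run_start, axis=1)
    within = pos - run_start + 1  # 1..c within each run
    # sum over g of log(c_g!) equals sum over positions of log(within)
    return het * LN2 - np.log(within).sum(axis=1)


def hwe_test(
    gm: GenotypeMatrix,
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Monte-Carlo exact HWE test per locus x population, Holm-corrected.

    Alleles are shuffled into genotypes within each locus x population and
    the probability-ordering exact p-value is estimated as the fraction of
    shuffles whose conditional genotype-table probability is at most the
    observed one. Loci with fewer than two distinct alleles in a population
    are flagged not applicable. The Holm correction is applied table-wide
    across all testable locus x population pairs.
    """
    if reps < 1_000:
        raise ValueError("reps must be at least 1000")
    rng = np.random.default_rng(seed)
    rows = []
    for pop in gm.populations:
        idx = gm.population_indices(pop)
        for k, locus in enumerate(gm.loci):
            calls = gm.calls[idx, k, :]
            calls = calls[calls[:, 0] != MISSING]
            genes = calls.ravel()
            uniq = np.unique(genes)
            if uniq.size < 2 or calls.shape[0] < 2:
                rows.append(
                    {"population": pop, "locus": locus, "n": calls.shape[0],
                     "p_value": np.nan, "applicable": False}
                )
                continue
            codes = np.searchsorted(uniq, genes)
            n = calls.shape[0]
            obs = _genotype_log_prob_stat(
                np.minimum(codes[::2], codes[1::2])[None, :],
                np.maximum(codes[::2], codes[1::2])[None, :],
            )[0]
            perms = rng.permuted(np.tile(codes, (reps, 1)), axis=1)
            a = perms[:, ::2]
            b = perms[:, 1::2]
            sim = _genotype_log_prob_stat(np.minimum(a, b), np.maximum(a, b))
            p = (1 + int(np.sum(sim <= obs + 1e-9))) / (reps + 1)
            rows.append(
                {"population": pop, "locus": locus, "n": n,
                 "p_value": p, "applicable": True}
            )
    out = pd.DataFrame(rows)
    adj, reject = holm_correction(out["p_value"].to_numpy(), alpha=alpha)
    out["p_holm"] = adj
    out["significant"] = reject
    return out


def hwe_exact_enumeration(genotype_counts: dict[tuple[int, int], int]) -> float:
    """Full-enumeration exact HWE p-value for a biallelic sample.

    ``genotype_counts`` maps unordered genotypes over alleles {0, 1} to
    counts. Enumerates every heterozygote count compatible with the observed
    allele counts (Levene's conditional distribution) and sums the
    probabilities of tables no more probable than the observed one. Used as
    the oracle for the Monte-Carlo test on tiny instances.
    """
    n_aa = genotype_counts.get((0, 0), 0)
    n_ab = genotype_counts.get((0, 1), 0) + genotype_counts.get((1, 0), 0)
    n_bb = genotype_counts.get((1, 1), 0)
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def log_prob(h):
        aa = (n_a - h) // 2
        bb = n - aa - h
        return (
            gammaln(n + 1)
            - gammaln(aa + 1)
            - gammaln(h + 1)
            - gammaln(bb + 1)
            + h * LN2
        )

    hs = [h for h in range(min(n_a, 2 * n - n_a) + 1) if (n_a - h) % 2 == 0]
    logs = np.array([log_prob(h) for h in hs])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    obs = probs[hs.index(n_ab)]
    return float(probs[probs <= obs + 1e-12].sum())


# ---------------------------------------------------------------------------
# Linkage disequilibrium G-test
# ---------------------------------------------------------------------------


def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G = 2 sum O ln(O/E) for a contingency table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def _pair_g(codes1, codes2):
    """Summed genotypic G over populations for two coded genotype vectors."""
    k1 = codes1.max() + 1
    k2 = codes2.max() + 1
    table = np.zeros((k1, k2))
    np.add.at(table, (codes1, codes2), 1.0)
    return g_statistic(table)


def ld_test(
    gm: GenotypeMatrix,
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotypic linkage-disequilibrium G-test for every locus pair.

    Within each population, a genotype x genotype contingency table is built
    for individuals scored at both loci, and the G statistics are summed
    over populations. The null distribution permutes one locus's genotypes
    across individuals within populations. Standard Bonferroni is applied
    across pairs; pairs with a monomorphic member are skipped.
    """
    if reps < 1_000:
        raise ValueError("reps must be at least 1000")
    rng = np.random.default_rng(seed)

    def mono(k):
        genes = gm.calls[:, k, :]
        genes = genes[genes[:, 0] != MISSING].ravel()
        return np.unique(genes).size < 2

    monomorphic = [mono(k) for k in range(len(gm.loci))]
    rows = []
    pairs = list(itertools.combinations(range(len(gm.loci)), 2))
    for k1, k2 in pairs:
        if monomorphic[k1] or monomorphic[k2]:
            rows.append(
                {"locus_a": gm.loci[k1], "locus_b": gm.loci[k2],
                 "g": np.nan, "p_value": np.nan, "applicable": False}
            )
            continue
        per_pop = []
        for pop in gm.populations:
            idx = gm.population_indices(pop)
            c1 = gm.calls[idx, k1, :]
            c2 = gm.calls[idx, k2, :]
            ok = (c1[:, 0] != MISSING) & (c2[:, 0] != MISSING)
            if ok.sum() < 2:
                continue
            g1 = np.sort(c1[ok], axis=1)
            g2 = np.sort(c2[ok], axis=1)
            _, codes1 = np.unique(g1, axis=0, return_inverse=True)
            _, codes2 = np.unique(g2, axis=0, return_inverse=True)
            per_pop.append((codes1.ravel(), codes2.ravel()))
        if not per_pop:
            rows.append(
                {"locus_a": gm.loci[k1], "locus_b": gm.loci[k2],
                 "g": np.nan, "p_value": np.nan, "applicable": False}
            )
            continue
        g_obs = sum(_pair_g(c1, c2) for c1, c2 in per_pop)
        exceed = 0
        for _ in range(reps):
            g_sim = sum(
                _pair_g(c1, rng.permutation(c2)) for c1, c2 in per_pop
            )
            if g_sim >= g_obs - 1e-9:
                exceed += 1
        p = (1 + exceed) / (reps + 1)
        rows.append(
            {"locus_a": gm.loci[k1], "locus_b": gm.loci[k2],
             "g": g_obs, "p_value": p, "applicable": True}
        )
    out = pd.DataFrame(rows)
    m = int(out["applicable"].sum())
    out["p_bonferroni"] = np.minimum(out["p_value"] * max(m, 1), 1.0)
    out["significant"] = out["p_bonferroni"] <= alpha
    return out


# ---------------------------------------------------------------------------
# Pairwise FST (Weir-Cockerham theta)
# ---------------------------------------------------------------------------


def _wc_theta_components(calls_by_pop: list[np.ndarray]):
    """Weir-Cockerham (1984) variance components a, b, c summed over
    alleles, for one locus and r populations. ``calls_by_pop`` holds
    (n_i, 2) arrays of non-missing calls."""
    r = len(calls_by_pop)
    ns = np.array([c.shape[0] for c in calls_by_pop], dtype=float)
    if np.any(ns == 0) or ns.sum() < 2:
        return 0.0, 0.0, 0.0
    alleles = np.unique(np.concatenate([c.ravel() for c in calls_by_pop]))
    if alleles.size < 2:
        return 0.0, 0.0, 0.0
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(ns ** 2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([(c == al).sum() / (2 * n) for c, n in zip(calls_by_pop, ns)])
        h_i = np.array(
            [((c == al).sum(axis=1) == 1).mean() for c in calls_by_pop]
        )
        pbar = np.sum(ns * p_i) / (r * nbar)
        s2 = np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ns * h_i) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta(gm: GenotypeMatrix, populations: list[str] | None = None) -> float:
    """Multi-locus Weir-Cockerham theta over the given populations."""
    pops = populations if populations is not None else gm.populations
    idx = {p: gm.population_indices(p) for p in pops}
    num = den = 0.0
    for k in range(len(gm.loci)):
        per_pop = []
        for p in pops:
            calls = gm.calls[idx[p], k, :]
            per_pop.append(calls[calls[:, 0] != MISSING])
        a, b, c = _wc_theta_components(per_pop)
        num += a
        den += a + b + c
    return num / den if den != 0 else np.nan


@dataclass
class FstResult:
    """Pairwise FST estimates with permutation p-values.

    ``theta``/``pvalues``/``significant`` are square symmetric DataFrames
    (diagonal 0 / NaN / False); ``pairs`` is the long form with
    Holm-adjusted significance.
    """

    theta: pd.DataFrame
    pvalues: pd.DataFrame
    significant: pd.DataFrame
    pairs: pd.DataFrame


def pairwise_fst(
    gm: GenotypeMatrix,
    reps: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> FstResult:
    """Pairwise Weir-Cockerham theta with permutation p-values.

    For each population pair, individuals are permuted between the two
    populations to build the null distribution of theta; Holm sequential
    Bonferroni is applied across pairs. A pair involving a single-individual
    population gets an estimate but no p-value (with a warning).
    """
    pops = gm.populations
    if len(pops) < 2:
        raise GenotypeDataError("pairwise FST needs at least two populations")
    rng = np.random.default_rng(seed)
    theta = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    rows = []
    for pa, pb in itertools.combinations(pops, 2):
        ia, ib = gm.population_indices(pa), gm.population_indices(pb)
        t_obs = wc_theta(gm, [pa, pb])
        theta.loc[pa, pb] = theta.loc[pb, pa] = t_obs
        if min(ia.size, ib.size) < 2:
            warnings.warn(
                f"population pair {pa}/{pb} includes a single-individual "
                "population; FST reported without a permutation p-value",
                stacklevel=2,
            )
            rows.append({"pop_a": pa, "pop_b": pb, "fst": t_obs,
                         "p_value": np.nan})
            continue
        merged_calls = gm.calls[np.concatenate([ia, ib])]
        na, ntot = ia.size, ia.size + ib.size

        def theta_of_split(order):
            num = den = 0.0
            for k in range(merged_calls.shape[1]):
                per_pop = []
                for grp in (order[:na], order[na:]):
                    calls = merged_calls[grp, k, :]
                    per_pop.append(calls[calls[:, 0] != MISSING])
                a, b, c = _wc_theta_components(per_pop)
                num += a
                den += a + b + c
            return num / den if den != 0 else np.nan

        exceed = 0
        for _ in range(reps):
            if theta_of_split(rng.permutation(ntot)) >= t_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (reps + 1)
        pvals.loc[pa, pb] = pvals.loc[pb, pa] = p
        rows.append({"pop_a": pa, "pop_b": pb, "fst": t_obs, "p_value": p})
    pairs = pd.DataFrame(rows)
    adj, reject = holm_correction(pairs["p_value"].to_numpy(), alpha=alpha)
    pairs["p_holm"] = adj
    pairs["significant"] = reject
    sig = pd.DataFrame(False, index=pops, columns=pops)
    for row in pairs.itertuples():
        sig.loc[row.pop_a, row.pop_b] = sig.loc[row.pop_b, row.pop_a] = bool(
            row.significant
        )
    return FstResult(theta, pvals, sig, pairs)
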