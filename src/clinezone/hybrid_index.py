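"""Maximum-likelihood hybrid index with profile-likelihood intervals.

Each individual's admixture proportion ``h`` in [0, 1] is estimated from
parental allele-frequency pools (reference pool at h = 0, alternative pool
at h = 1) by treating every allele copy as an independent draw from the
mixture ``h f_alt + (1 - h) f_ref``:

    lnL(h) = sum over non-missing allele copies ln[h f_alt(a) + (1-h) f_ref(a)]

The 95% interval is the profile-likelihood set {h : lnL(h) >= lnL(h*) -
1.92} (a chi-square_1 / 2 drop) intersected with [0, 1]. Two
classification rules are supported: the 0.25-0.75 cutoff on h, and the
interval rule (hybrid iff the 95% CI excludes both 0 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .cline_models import ClineData
from .genotypes_io import MISSING, GenotypeDataError, GenotypeMatrix

PROFILE_DROP = 1.92  # chi^2_1(0.95) / 2

CLASS_PURE_REF = "pure_reference"
CLASS_PURE_ALT = "pure_alternative"
CLASS_HYBRID = "hybrid"


@dataclass
class ParentalFreqs:
    """Pseudocount-smoothed allele frequencies for the two parental pools.

    Frequencies are defined over every allele observed anywhere in the
    dataset, so any genotype has nonzero likelihood in at least one pool
    when the pseudocount is positive.
    """

    loci: list[str]
    ref: dict[str, pd.Series]
    alt: dict[str, pd.Series]
    ref_genes: dict[str, int]
    alt_genes: dict[str, int]
    pseudocount: float

    def swap(self) -> "ParentalFreqs":
        """Exchange the reference and alternative pools."""
        return ParentalFreqs(self.loci, self.alt, self.ref,
                             self.alt_genes, self.ref_genes, self.pseudocount)


def estimate_parental_frequencies(
    gm: GenotypeMatrix,
    reference_pops: list[str],
    alternative_pops: list[str],
    pseudocount: float = 1e-6,
) -> ParentalFreqs:
    """Pool parental populations into smoothed allele-frequency tables.

    Counts within each pool are summed per locus over every allele observed
    anywhere in the dataset, the pseudocount is added to each allele, and
    the result normalised. Pools must be disjoint and non-empty.
    """
    shared = set(reference_pops) & set(alternative_pops)
    if shared:
        raise GenotypeDataError(f"pools share populations: {sorted(shared)}")
    if not reference_pops or not alternative_pops:
        raise GenotypeDataError("both parental pools must be non-empty")
    for p in list(reference_pops) + list(alternative_pops):
        gm.population_indices(p)

    pop_arr = np.asarray(gm.population_id)
    ref_idx = np.flatnonzero(np.isin(pop_arr, list(reference_pops)))
    alt_idx = np.flatnonzero(np.isin(pop_arr, list(alternative_pops)))

    ref, alt, ref_genes, alt_genes = {}, {}, {}, {}
    for k, locus in enumerate(gm.loci):
        universe = np.unique(gm.calls[:, k, :])
        universe = universe[universe != MISSING]
        if universe.size == 0:
            continue
        out = []
        for idx in (ref_idx, alt_idx):
            genes = gm.calls[idx, k, :].ravel()
            genes = genes[genes != MISSING]
            counts = pd.Series(0.0, index=universe)
            if genes.size:
                vals, cts = np.unique(genes, return_counts=True)
                counts.loc[vals] = cts
            smoothed = counts + pseudocount
            total = smoothed.sum()
            out.append((smoothed / total if total > 0 else smoothed,
                        int(genes.size)))
        ref[locus], ref_genes[locus] = out[0]
        alt[locus], alt_genes[locus] = out[1]
    return ParentalFreqs(list(gm.loci), ref, alt, ref_genes, alt_genes,
                         float(pseudocount))


@dataclass
class HybridIndexResult:
    individual_id: str
    h: float
    lnl_max: float
    ci_low: float
    ci_high: float
    n_loci: int


def _copy_freqs(calls: np.ndarray, pf: ParentalFreqs):
    """Per allele copy (f_ref, f_alt) for the non-missing calls of one
    individual; raises if every locus is missing."""
    fr, fa, bad = [], [], []
    for k, locus in enumerate(pf.loci):
        a, b = calls[k]
        if a == MISSING:
            continue
        for allele in (a, b):
            r = pf.ref.get(locus, pd.Series(dtype=float)).get(allele, 0.0)
            t = pf.alt.get(locus, pd.Series(dtype=float)).get(allele, 0.0)
            if r == 0.0 and t == 0.0:
                bad.append((locus, int(allele)))
            fr.append(r)
            fa.append(t)
    if not fr:
        raise GenotypeDataError("individual has no non-missing loci")
    if bad:
        raise GenotypeDataError(
            "alleles with zero frequency in both parental pools (use a "
            f"positive pseudocount): {bad}"
        )
    return np.asarray(fr), np.asarray(fa)


def hybrid_index_ml(
    calls: np.ndarray,
    pf: ParentalFreqs,
    individual_id: str = "",
) -> HybridIndexResult:
    """Maximum-likelihood hybrid index for one individual's calls.

    ``calls`` is the (n_loci, 2) row aligned with ``pf.loci``. The log
    likelihood is strictly concave in h wherever informative, so a single
    bounded optimisation suffices; endpoints are checked explicitly and
    ties of equal lnL are broken toward the boundary value (flat
    likelihoods arise for uninformative individuals).
    """
    fr, fa = _copy_freqs(np.asarray(calls), pf)
    diff = fa - fr

    def lnl(h):
        # mixture mass can be 0 at the boundaries (allele private to the
        # other pool): lnL = -inf there, which the optimiser handles
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(fr + h * diff)))

    # boundary-first tie-breaking
    best_h, best_val = 0.0, lnl(0.0)
    v1 = lnl(1.0)
    if v1 > best_val + 1e-12:
        best_h, best_val = 1.0, v1
    res = minimize_scalar(
        lambda h: -lnl(h), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if -res.fun > best_val + 1e-12:
        best_h, best_val = float(res.x), float(-res.fun)
    h_star, lnl_star = best_h, best_val

    threshold = lnl_star - PROFILE_DROP

    def g(h):
        return lnl(h) - threshold

    ci_low = 0.0 if g(0.0) >= 0 else brentq(g, 0.0, h_star, xtol=1e-10)
    ci_high = 1.0 if g(1.0) >= 0 else brentq(g, h_star, 1.0, xtol=1e-10)

    n_loci = int(np.sum(np.asarray(calls)[:, 0] != MISSING))
    return HybridIndexResult(
        individual_id=individual_id, h=float(h_star), lnl_max=float(lnl_star),
        ci_low=float(ci_low), ci_high=float(ci_high), n_loci=n_loci,
    )


def hybrid_index_all(gm: GenotypeMatrix, pf: ParentalFreqs) -> pd.DataFrame:
    """Hybrid index for every individual; columns individual, population,
    era, h, lnl_max, ci_low, ci_high, n_loci."""
    rows = []
    for i in range(gm.n_individuals):
        res = hybrid_index_ml(gm.calls[i], pf, gm.individual_id[i])
        rows.append(
            {
                "individual": res.individual_id,
                "population": gm.population_id[i],
                "era": gm.era[i],
                "h": res.h,
                "lnl_max": res.lnl_max,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_loci": res.n_loci,
            }
        )
    return pd.DataFrame(rows)


def classify_hybrids(results: pd.DataFrame, rule: str = "cutoff"):
    """Classify individuals as hybrid or pure under one of two rules.

    ``cutoff``: hybrid iff 0.25 <= h <= 0.75, otherwise pure toward the
    nearer end. ``ci``: hybrid iff the 95% CI excludes both 0 and 1.
    Returns the classified table and per-population hybrid proportions.
    """
    if rule not in ("cutoff", "ci"):
        raise ValueError(f"unknown classification rule {rule!r}")
    out = results.copy()
    if rule == "cutoff":
        hybrid = (out["h"] >= 0.25) & (out["h"] <= 0.75)
    else:
        hybrid = (out["ci_low"] > 0.0) & (out["ci_high"] < 1.0)
    pure_alt = ~hybrid & (out["h"] > 0.5)
    out["class"] = np.where(
        hybrid, CLASS_HYBRID, np.where(pure_alt, CLASS_PURE_ALT, CLASS_PURE_REF)
    )
    proportions = (
        out.assign(is_hybrid=hybrid)
        .groupby("population", sort=False)["is_hybrid"]
        .mean()
        .rename("hybrid_proportion")
    )
    return out, proportions


def population_mean_h(results: pd.DataFrame, meta) -> ClineData:
    """Per-population mean hybrid index as cline-ready data.

    ``meta`` supplies each population's transect position: either a list of
    PopulationMeta (with ``transect_x`` set) or a mapping pop -> x. Raises
    for populations lacking a position.
    """
    if isinstance(meta, dict):
        x_of = dict(meta)
    else:
        x_of = {}
        for m in meta:
            if m.transect_x is None:
                raise GenotypeDataError(
                    f"population {m.population_id} lacks a transect position"
                )
            x_of[m.population_id] = m.transect_x
    grouped = results.groupby("population", sort=False)["h"]
    pops = list(grouped.mean().index)
    missing = [p for p in pops if p not in x_of]
    if missing:
        raise GenotypeDataError(
            f"populations lacking a transect position: {missing}"
        )
    return ClineData(
        population_id=pops,
        x=np.array([x_of[p] for p in pops]),
        p_bar=grouped.mean().to_numpy(),
        n=grouped.size().to_numpy(float),
    )
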