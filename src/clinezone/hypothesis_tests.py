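"""Temporal comparisons between sampling eras.

Two complementary designs test whether the cline changed between the
historical and recent sampling eras:

* **Reciprocal constraint tests** — refit one era's cline with its center,
  width, or both restricted to the 95% credibility interval estimated from
  the other era, and compare constrained to unconstrained fits by the
  likelihood ratio 2LLR = 2 (lnL_con - lnL_uncon) and by the AIC difference
  AIC_uncon - AIC_con. A constrained parameter is treated as no longer free,
  so the constrained model's AIC uses k reduced by the number of constrained
  parameters.

* **Stratified subsampling** — match each historical population to a
  geographically equivalent recent population, subsample individuals so both
  members of every pair have the same N, recompute population mean hybrid
  indices, and refit the simplest (no-tails) cline to both eras; repeated
  over random replicates. A parameter differs significantly in a replicate
  when the two eras' 95% credibility intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cline_models import (
    ClineData,
    ClineFit,
    ClineModelSpec,
    MCMCSettings,
    fit_cline_mcmc,
    fit_cline_ml,
)


# ---------------------------------------------------------------------------
# Constrained fitting and reciprocal tests
# ---------------------------------------------------------------------------


def constrained_fit(
    data: ClineData,
    spec: ClineModelSpec,
    constraints: dict[str, tuple[float, float]],
    settings: MCMCSettings | None = None,
    method: str = "mcmc",
) -> ClineFit:
    """Refit with prior support truncated to the given parameter intervals.

    ``constraints`` maps parameter names (e.g. ``center``, ``width``) to
    closed intervals, typically the 95% credibility interval estimated from
    the other era. A degenerate interval [v, v] fixes the parameter. The
    fitting machinery is identical to the unconstrained case; the reported
    k is reduced by the number of constrained parameters so AIC comparisons
    treat constrained parameters as no longer free.
    """
    if not constraints:
        raise ValueError("no constraints given; use the unconstrained fit")
    k_eff = spec.k - len(constraints)
    if method == "ml":
        return fit_cline_ml(data, spec, constraints=constraints, k_eff=k_eff)
    return fit_cline_mcmc(data, spec, settings=settings,
                          constraints=constraints, k_eff=k_eff)


@dataclass
class ConstraintTestResult:
    """Likelihood-ratio and AIC comparison of constrained vs unconstrained."""

    constrained_params: tuple[str, ...]
    lnl_uncon: float
    aic_uncon: float
    lnl_con: float
    aic_con: float

    @property
    def two_llr(self) -> float:
        return 2.0 * (self.lnl_con - self.lnl_uncon)

    @property
    def delta_aic(self) -> float:
        return self.aic_uncon - self.aic_con


def reciprocal_constraint_test(
    fit_uncon: ClineFit, fit_con: ClineFit
) -> ConstraintTestResult:
    """Compare a constrained fit to the matching unconstrained fit."""
    if fit_uncon.data_digest != fit_con.data_digest:
        raise ValueError("fits do not share the same underlying data")
    if not fit_con.constraints:
        raise ValueError("second fit carries no constraints")
    return ConstraintTestResult(
        constrained_params=tuple(sorted(fit_con.constraints)),
        lnl_uncon=fit_uncon.lnl_max,
        aic_uncon=fit_uncon.aic,
        lnl_con=fit_con.lnl_max,
        aic_con=fit_con.aic,
    )


# ---------------------------------------------------------------------------
# Stratified subsampling
# ---------------------------------------------------------------------------


@dataclass
class SubsampleSummary:
    """Per-replicate no-tails fits for both eras and significance tallies.

    ``replicates`` has one row per replicate with the chosen recent
    populations, matched sample total, and each era's center/width estimate
    and 95% credibility interval. Tallies count replicates whose recent
    interval lies entirely east/west of (center) or entirely above/below
    (width) the historical interval.
    """

    replicates: pd.DataFrame = field(repr=False)
    tallies: dict[str, int]
    means: dict[str, float]
    ranges: dict[str, tuple[float, float]]
    reps: int


def _interval_disjoint(a: tuple[float, float], b: tuple[float, float]) -> int:
    """-1 if a lies wholly below b, +1 wholly above, 0 if overlapping."""
    if a[1] < b[0]:
        return -1
    if a[0] > b[1]:
        return 1
    return 0


def stratified_subsample_analysis(
    hist_h: pd.DataFrame,
    hist_x: dict[str, float],
    recent_h: pd.DataFrame,
    recent_x: dict[str, float],
    mapping: dict[str, list[str]],
    reps: int = 100,
    seed: int = 0,
    settings: MCMCSettings | None = None,
    spec: ClineModelSpec | None = None,
) -> SubsampleSummary:
    """Replicate cline fits on sample-size-matched era subsamples.

    ``hist_h``/``recent_h`` are per-individual hybrid-index tables with
    ``individual``, ``population`` and ``h`` columns; ``hist_x``/``recent_x``
    map populations to transect positions (km). ``mapping`` pairs each
    historical population with its candidate recent equivalents; one
    candidate is drawn uniformly per replicate, then individuals in the
    larger member of each pair are subsampled without replacement so both
    have the matched pair's smaller N. Both eras are refit with the
    simplest model and per-parameter significance is strict non-overlap of
    the 95% credibility intervals.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for hpop, candidates in mapping.items():
        if not candidates:
            raise ValueError(f"empty candidate set for {hpop}")
        if hpop not in hist_x:
            raise KeyError(f"no transect position for historical {hpop}")
        for c in candidates:
            if c not in recent_x:
                raise KeyError(f"no transect position for recent {c}")
    spec = spec or ClineModelSpec(tails="none")
    settings = settings or MCMCSettings(
        burnin=20_000, generations=100_000, thin=100, chains=3
    )
    rng = np.random.default_rng(seed)

    hist_groups = {
        p: g["h"].to_numpy() for p, g in hist_h.groupby("population")
    }
    recent_groups = {
        p: g["h"].to_numpy() for p, g in recent_h.groupby("population")
    }
    missing_h = [p for p in mapping if p not in hist_groups]
    if missing_h:
        raise KeyError(f"historical populations without h values: {missing_h}")

    rows = []
    for rep in range(reps):
        chosen, h_bar, r_bar, h_n, h_xs, r_xs = [], [], [], [], [], []
        total = 0
        for hpop in mapping:
            rpop = mapping[hpop][rng.integers(len(mapping[hpop]))]
            chosen.append(rpop)
            hv = hist_groups[hpop]
            rv = recent_groups[rpop]
            n_pair = min(hv.size, rv.size)
            hv_sub = rng.choice(hv, size=n_pair, replace=False)
            rv_sub = rng.choice(rv, size=n_pair, replace=False)
            total += n_pair
            h_bar.append(hv_sub.mean())
            r_bar.append(rv_sub.mean())
            h_n.append(n_pair)
            h_xs.append(hist_x[hpop])
            r_xs.append(recent_x[rpop])
        hist_data = ClineData(list(mapping), np.array(h_xs),
                              np.clip(h_bar, 0, 1), np.array(h_n, float))
        rec_data = ClineData(chosen, np.array(r_xs),
                             np.clip(r_bar, 0, 1), np.array(h_n, float))
        fits = {}
        for era, d in (("hist", hist_data), ("recent", rec_data)):
            s = MCMCSettings(
                burnin=settings.burnin, generations=settings.generations,
                thin=settings.thin, chains=settings.chains,
                seed=int(rng.integers(2**31 - 1)),
            )
            fits[era] = fit_cline_mcmc(d, spec, settings=s)
        row = {"replicate": rep, "recent_pops": "+".join(chosen),
               "matched_n": total}
        for era in ("hist", "recent"):
            f = fits[era]
            row[f"{era}_center"] = f.params.center
            row[f"{era}_width"] = f.params.width
            row[f"{era}_center_lo"], row[f"{era}_center_hi"] = f.cri["center"]
            row[f"{era}_width_lo"], row[f"{era}_width_hi"] = f.cri["width"]
        rows.append(row)

    df = pd.DataFrame(rows)
    tallies = {"recent_sig_east": 0, "recent_sig_west": 0,
               "recent_sig_wider": 0, "recent_sig_narrower": 0}
    for row in df.itertuples():
        side = _interval_disjoint(
            (row.recent_center_lo, row.recent_center_hi),
            (row.hist_center_lo, row.hist_center_hi),
        )
        if side > 0:
            tallies["recent_sig_east"] += 1
        elif side < 0:
            tallies["recent_sig_west"] += 1
        side = _interval_disjoint(
            (row.recent_width_lo, row.recent_width_hi),
            (row.hist_width_lo, row.hist_width_hi),
        )
        if side > 0:
            tallies["recent_sig_wider"] += 1
        elif side < 0:
            tallies["recent_sig_narrower"] += 1

    means, ranges = {}, {}
    for col in ("hist_center", "hist_width", "recent_center", "recent_width"):
        means[col] = float(df[col].mean())
        ranges[col] = (float(df[col].min()), float(df[col].max()))
    return SubsampleSummary(df, tallies, means, ranges, reps)
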