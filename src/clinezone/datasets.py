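"""Bundled summary data for the chorus-frog contact zone.

The package ships the published population-level summary of the Pseudacris
fouquettei x P. nigrita contact zone across the Pearl River (south-eastern
USA): collection-site coordinates and sample sizes for the recent
(2001-2012) sampling, pooled population metadata for both the recent and
the historical (1976) eras, transect positions along the regression-line
transect, per-population mean hybrid indices (h = 1 denotes pure
P. fouquettei on the western side), and the maximised log-likelihoods and
parameter counts of the five cline models per dataset. These tables are the
inputs for re-running the cline analyses without access to the raw
genotypes.
"""

from __future__ import annotations

import pandas as pd

from .cline_models import ClineData

# population, era, transect x (km), N, mean hybrid index, weighted latitude,
# weighted longitude, species designation
_POPULATIONS = [
    # historical sampling (1976), west to east
    ("H1", "historical", 0.000, 16, 1.000, 31.91924, -92.30716, "pure_fouquettei"),
    ("H2", "historical", 233.259, 4, 0.911, 30.43180, -89.90839, "putative_hybrid"),
    ("H3", "historical", 246.778, 17, 0.893, 30.37827, -89.76851, "putative_hybrid"),
    ("H4", "historical", 253.849, 25, 0.824, 30.40496, -89.69406, "putative_hybrid"),
    ("H5", "historical", 257.601, 6, 0.756, 30.43631, -89.65414, "putative_hybrid"),
    ("H6", "historical", 263.314, 30, 0.087, 30.52175, -89.59249, "pure_nigrita"),
    ("H7", "historical", 299.728, 19, 0.000, 30.57552, -89.21105, "pure_nigrita"),
    # recent sampling (2001-2012), west to east
    ("A", "recent", 62.242, 7, 1.000, 30.33090, -91.69640, "pure_fouquettei"),
    ("B", "recent", 139.325, 11, 0.604, 30.70434, -90.88263, "putative_hybrid"),
    ("C", "recent", 151.918, 8, 0.599, 30.77479, -90.74948, "putative_hybrid"),
    ("D", "recent", 159.133, 4, 0.547, 30.82229, -90.67302, "putative_hybrid"),
    ("E", "recent", 228.813, 6, 0.698, 30.39453, -89.95570, "putative_hybrid"),
    ("F", "recent", 233.257, 5, 0.660, 30.40007, -89.90917, "putative_hybrid"),
    ("G", "recent", 248.348, 23, 0.563, 30.37421, -89.75222, "putative_hybrid"),
    ("H", "recent", 254.347, 4, 0.595, 30.47999, -89.68708, "putative_hybrid"),
    ("I", "recent", 257.891, 9, 0.511, 30.43316, -89.65119, "putative_hybrid"),
    ("J", "recent", 263.043, 26, 0.279, 30.42711, -89.59754, "putative_hybrid"),
    ("K", "recent", 277.598, 22, 0.323, 30.40376, -89.44613, "putative_hybrid"),
    ("L", "recent", 328.889, 13, 0.276, 30.50104, -88.90835, "putative_hybrid"),
    ("M", "recent", 611.863, 5, 0.000, 30.48225, -85.95448, "pure_nigrita"),
    ("N", "recent", 615.434, 5, 0.000, 30.73710, -85.91129, "pure_nigrita"),
    ("O", "recent", 706.278, 4, 0.000, 30.14370, -84.97660, "pure_nigrita"),
    ("P", "recent", 749.345, 9, 0.000, 31.23799, -84.50169, "pure_nigrita"),
]

# recent collection sites before pooling: site, latitude, longitude, n,
# year, pooled population (None = discarded orphan)
_COLLECTION_SITES = [
    ("M1", 30.33090, -91.69640, 7, 2006, "A"),
    ("M23", 30.68889, -90.88944, 2, 2001, "B"),
    ("M14", 30.70778, -90.88111, 9, 2010, "B"),
    ("M16", 30.77500, -90.75917, 5, 2010, "C"),
    ("M15", 30.77444, -90.73333, 3, 2010, "C"),
    ("M17", 30.82229, -90.67302, 4, 2010, "D"),
    ("M25", 30.40008, -89.95806, 5, 2012, "E"),
    ("M24", 30.36677, -89.94389, 1, 2012, "E"),
    ("M26", 30.40007, -89.90917, 5, 2012, "F"),
    ("M22", 30.56551, -89.87149, 1, 2003, None),
    ("M5", 30.38400, -89.75540, 10, 2003, "G"),
    ("M2", 30.35981, -89.75119, 5, 2003, "G"),
    ("M3", 30.36296, -89.74986, 3, 2006, "G"),
    ("M4", 30.37580, -89.74830, 5, 2006, "G"),
    ("M13", 30.47576, -89.69263, 1, 2003, "H"),
    ("M12", 30.46701, -89.68592, 2, 2006, "H"),
    ("M20", 30.51020, -89.68387, 1, 2012, "H"),
    ("M11", 30.43992, -89.65759, 3, 2003, "I"),
    ("M10", 30.42978, -89.64799, 6, 2003, "I"),
    ("M18", 30.42554, -89.60114, 5, 2012, "J"),
    ("M19", 30.42898, -89.59735, 5, 2012, "J"),
    ("M9", 30.42702, -89.59648, 16, 2006, "J"),
    ("M6", 30.38572, -89.47497, 4, 2007, "K"),
    ("M7", 30.39767, -89.44804, 8, 2007, "K"),
    ("M8", 30.41585, -89.43307, 10, 2007, "K"),
    ("M21", 30.50104, -88.90835, 13, 2003, "L"),
    ("M29", 30.48225, -85.95448, 5, 2005, "M"),
    ("M28", 30.73710, -85.91129, 5, 2005, "N"),
    ("M27", 30.14370, -84.97660, 4, 2003, "O"),
    ("M30", 31.23799, -84.50169, 9, 2003, "P"),
]

# published maximised log-likelihoods and parameter counts of the five
# cline models, per dataset (inputs for the AIC model-selection arithmetic)
_MODEL_STATS = {
    "historical": [
        ("none", -3.8951, 2), ("west", -0.4025, 4), ("east", -3.8951, 4),
        ("symmetric", -1.8687, 4), ("asymmetric", -0.1183, 6),
    ],
    "recent": [
        ("none", -4.7955, 2), ("west", -4.7955, 4), ("east", -4.7955, 4),
        ("symmetric", -4.7955, 4), ("asymmetric", -4.7956, 6),
    ],
    "recent_excl_bcd": [
        ("none", -2.5206, 2), ("west", -2.5206, 4), ("east", -1.6163, 4),
        ("symmetric", -2.5206, 4), ("asymmetric", -1.9397, 6),
    ],
}

# published 95% credibility intervals of the no-tails and (historical only)
# west-tail fits, used to set reciprocal constraint intervals
CREDIBILITY_INTERVALS = {
    ("historical", "none"): {"center": (255.620, 259.487),
                             "width": (9.898, 21.074)},
    ("historical", "west"): {"center": (255.619, 259.487),
                             "width": (8.653, 21.071)},
    ("recent", "none"): {"center": (195.238, 259.191),
                         "width": (232.372, 582.217)},
    ("recent_excl_bcd", "none"): {"center": (221.395, 268.026),
                                  "width": (109.162, 396.677)},
}

# published reciprocally constrained log-likelihood / AIC pairs: rows are
# (model fitted, source of the constraint, lnL_uncon, AIC_uncon, then
# (lnL_con, AIC_con) for center-, width-, and both-constrained analyses)
_CONSTRAINT_STATS = [
    ("historical/none", "recent", -3.895, 11.790,
     (-3.895, 9.790), (-30.220, 62.440), (-30.220, 60.440)),
    ("historical/none", "recent_excl_bcd", -3.895, 11.790,
     (-2.323, 6.647), (-30.223, 62.445), (-30.220, 60.440)),
    ("historical/west", "recent", -0.403, 8.805,
     (-3.895, 13.790), (-22.820, 51.639), (-22.821, 49.642)),
    ("historical/west", "recent_excl_bcd", -0.403, 8.805,
     (-1.646, 9.292), (-22.822, 51.644), (-22.821, 49.642)),
    ("recent/none", "historical/none", -4.796, 13.591,
     (-6.089, 14.177), (-248.311, 498.621), (-249.220, 498.440)),
    ("recent/none", "historical/west", -4.796, 13.591,
     (-6.088, 14.176), (-248.352, 498.705), (-249.254, 498.509)),
    ("recent_excl_bcd/none", "historical/none", -2.521, 9.041,
     (-2.695, 7.390), (-71.149, 144.297), (-71.148, 142.296)),
    ("recent_excl_bcd/none", "historical/west", -2.521, 9.041,
     (-2.695, 7.389), (-71.162, 144.325), (-71.161, 142.322)),
]


def population_table() -> pd.DataFrame:
    """Pooled population metadata for both eras, west to east."""
    return pd.DataFrame(
        _POPULATIONS,
        columns=["population_id", "era", "transect_x", "n", "mean_h",
                 "latitude", "longitude", "species_designation"],
    )


def collection_sites() -> pd.DataFrame:
    """Recent collection sites before pooling (with expected pooling)."""
    return pd.DataFrame(
        _COLLECTION_SITES,
        columns=["site", "latitude", "longitude", "n", "year",
                 "expected_population"],
    )


def _cline_data(era: str) -> ClineData:
    t = population_table()
    t = t[t["era"] == era]
    return ClineData(
        population_id=list(t["population_id"]),
        x=t["transect_x"].to_numpy(),
        p_bar=t["mean_h"].to_numpy(),
        n=t["n"].to_numpy(float),
    )


def historical_cline_data() -> ClineData:
    """The seven 1976 populations: x, mean h, N."""
    return _cline_data("historical")


def recent_cline_data(exclude=()) -> ClineData:
    """The sixteen 2001-2012 populations, optionally excluding some (the
    western outliers B, C, D are the documented exclusion set)."""
    d = _cline_data("recent")
    return d.exclude(exclude) if exclude else d


def model_selection_inputs(dataset: str) -> pd.DataFrame:
    """Published per-model maximised lnL and k for one dataset
    (``historical``, ``recent``, or ``recent_excl_bcd``)."""
    rows = _MODEL_STATS[dataset]
    return pd.DataFrame(rows, columns=["model", "lnl", "k"])


def constraint_test_inputs() -> pd.DataFrame:
    """Published constrained/unconstrained lnL and AIC pairs."""
    rows = []
    for model, source, lnl_u, aic_u, ctr, wid, both in _CONSTRAINT_STATS:
        for params, (lnl_c, aic_c) in (
            ("center", ctr), ("width", wid), ("both", both)
        ):
            rows.append(
                {"model": model, "constraint_source": source,
                 "constrained": params, "lnl_uncon": lnl_u,
                 "aic_uncon": aic_u, "lnl_con": lnl_c, "aic_con": aic_c}
            )
    return pd.DataFrame(rows)


def credibility_interval_inputs(dataset: str, model: str) -> dict:
    """Published 95% credibility intervals for a dataset/model pair, used
    to set reciprocal constraint intervals."""
    return {k: tuple(v) for k, v in
            CREDIBILITY_INTERVALS[(dataset, model)].items()}


def subsampling_mapping(east_anchor: str = "proximate") -> dict[str, list[str]]:
    """Historical-to-recent population matching for stratified subsampling.

    ``east_anchor`` chooses the recent equivalent of the easternmost
    historical population: ``proximate`` (population L) or
    ``pure_parental`` (the westernmost pure P. nigrita population, M).
    """
    if east_anchor not in ("proximate", "pure_parental"):
        raise ValueError(f"unknown east_anchor {east_anchor!r}")
    mapping = {
        "H1": ["A"], "H2": ["E", "F"], "H3": ["G"], "H4": ["H"],
        "H5": ["I"], "H6": ["J", "K"],
        "H7": ["L"] if east_anchor == "proximate" else ["M"],
    }
    return mapping


def transect_positions(era: str | None = None) -> dict[str, float]:
    """Published transect positions (km) keyed by population."""
    t = population_table()
    if era is not None:
        t = t[t["era"] == era]
    return dict(zip(t["population_id"], t["transect_x"].astype(float)))
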