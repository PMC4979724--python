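"""Projection of population coordinates onto a one-dimensional transect.

Coordinates are first mapped to a locally scaled planar frame
(equirectangular: longitude scaled by the cosine of the mean latitude,
degrees converted to km at 111.32 km/degree). A regression line of latitude
on longitude is fitted through all populations, each population is
orthogonally projected onto it in the scaled frame, and the signed distance
along the line from the westernmost projection gives the transect position
x (km). Printed distance tables can be loaded verbatim instead, bypassing
the projection entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KM_PER_DEGREE = 111.32


@dataclass
class Transect:
    """Anchor, direction (unit vector in the scaled km frame), and per-
    population positions in km."""

    anchor: tuple[float, float]  # (latitude, longitude) of the frame origin
    direction: tuple[float, float]  # (east, north) unit vector
    x: dict[str, float]

    def positions(self) -> pd.Series:
        return pd.Series(self.x, name="transect_x")


def _planar(lat, lon, lat0, lon0):
    ke = KM_PER_DEGREE * np.cos(np.radians(lat0))
    east = (np.asarray(lon) - lon0) * ke
    north = (np.asarray(lat) - lat0) * KM_PER_DEGREE
    return east, north


def project_to_transect(meta, origin_policy: str = "westmost") -> Transect:
    """Fit a regression line through all populations and project onto it.

    ``meta`` is a list of PopulationMeta (weighted coordinates are used) or
    a DataFrame with population_id/latitude/longitude columns. The line is
    an ordinary least-squares fit of latitude on longitude in the scaled
    planar frame; the direction points east so the westernmost projection
    has the minimum x, set to 0 under ``origin_policy='westmost'``.
    """
    if origin_policy not in ("westmost", "none"):
        raise ValueError(f"unknown origin policy {origin_policy!r}")
    if isinstance(meta, pd.DataFrame):
        ids = list(meta["population_id"].astype(str))
        lat = meta["latitude"].to_numpy(float)
        lon = meta["longitude"].to_numpy(float)
    else:
        ids = [m.population_id for m in meta]
        lat = np.array([m.weighted_latitude for m in meta], float)
        lon = np.array([m.weighted_longitude for m in meta], float)
    if len(ids) < 2:
        raise ValueError("projection needs at least two populations")
    lat0, lon0 = float(lat.mean()), float(lon.mean())
    east, north = _planar(lat, lon, lat0, lon0)
    if np.allclose(east, east[0]) and np.allclose(north, north[0]):
        raise ValueError("all population coordinates coincide")

    if np.allclose(east, east[0]):
        # meridional data: regression of lat on lon is undefined; use north
        direction = np.array([0.0, 1.0])
    else:
        slope = np.sum((east - east.mean()) * (north - north.mean())) / np.sum(
            (east - east.mean()) ** 2
        )
        direction = np.array([1.0, slope])
        direction /= np.linalg.norm(direction)
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction

    t = east * direction[0] + north * direction[1]
    if origin_policy == "westmost":
        t = t - t.min()
    return Transect(
        anchor=(lat0, lon0),
        direction=(float(direction[0]), float(direction[1])),
        x={i: float(v) for i, v in zip(ids, t)},
    )


def load_printed_distances(meta, table) -> Transect:
    """Build a transect from a supplied distance table, verbatim.

    ``table`` is a DataFrame or a CSV/TSV path with columns
    ``population_id`` and ``transect_x`` (km). Every population in ``meta``
    must appear; input row order is irrelevant.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep=None, engine="python")
    df = df.copy()
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"population_id", "transect_x"}.issubset(df.columns):
        raise ValueError("table needs population_id and transect_x columns")
    df["population_id"] = df["population_id"].astype(str)
    x_of = dict(zip(df["population_id"], df["transect_x"].astype(float)))

    if isinstance(meta, pd.DataFrame):
        ids = list(meta["population_id"].astype(str))
    elif meta and hasattr(meta[0], "population_id"):
        ids = [m.population_id for m in meta]
    else:
        ids = [str(m) for m in meta]
    missing = [i for i in ids if i not in x_of]
    if missing:
        raise KeyError(f"populations absent from distance table: {missing}")
    xs = {i: x_of[i] for i in ids}
    return Transect(anchor=(float("nan"), float("nan")),
                    direction=(1.0, 0.0), x=xs)
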