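"""Raster and point bookkeeping for burned-area accounting.

Implements the pre-modelling data rules: the ≥70% classification-confidence
filter, the ≥30% tree-cover filter, the post-2015 fire overlay (the
management map is nominally a 2015 snapshot, so only later fire-loss years
count), per-class burned-area ledgers on a one-degree grid, capped
stratified sampling within one-degree cells, and the rule that a country
enters the modelling stage only if burns exceed 0.1% of its matched points.

One-degree cells are anchored at integer degrees and half-open [d, d+1);
cell ids are ``"lonfloor_latfloor"`` strings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import Raster
from .synthetic import MGMT_CODES

__all__ = [
    "filter_confidence",
    "filter_tree_cover",
    "overlay_burned",
    "pixel_area_ha",
    "cell_id",
    "area_by_class",
    "stratified_sample",
    "country_inclusion",
]

_CODE_TO_CLASS = {v: k for k, v in MGMT_CODES.items()}


def filter_confidence(points: pd.DataFrame, threshold: float = 0.70) -> pd.DataFrame:
    """Keep points whose classification confidence is ≥ ``threshold``.

    The boundary is inclusive (a mapped confidence of exactly 70% is kept);
    pass a slightly larger threshold for a strict cut.  Row order preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"confidence threshold must be in [0,1], got {threshold}")
    return points[points["confidence"] >= threshold]


def filter_tree_cover(points: pd.DataFrame, min_cover: float = 0.30) -> pd.DataFrame:
    """Keep points with tree cover ≥ ``min_cover`` (inclusive).

    Removes low-cover systems (savannahs) that burn often but carry little
    timber.
    """
    if not 0.0 <= min_cover <= 1.0:
        raise ValueError(f"min_cover must be in [0,1], got {min_cover}")
    return points[points["tree_cover"] >= min_cover]


def overlay_burned(
    mgmt_raster: Raster, fire_year_raster: Raster, year_min: int = 2016
) -> np.ndarray:
    """Per-pixel stand-replacing burn flags from the two input grids.

    A pixel is burned (1) iff its fire-loss year is ≥ ``year_min`` AND it
    carries one of the three timber-management class codes; pixels that are
    nodata in either grid propagate as -1.  Non-timber pixels are 0.
    """
    if not mgmt_raster.same_grid(fire_year_raster):
        raise ValueError(
            "raster grids differ: management "
            f"{mgmt_raster.geotransform()} + shape {mgmt_raster.shape} vs fire "
            f"{fire_year_raster.geotransform()} + shape {fire_year_raster.shape}"
        )
    mgmt = mgmt_raster.data
    fire = fire_year_raster.data
    nodata = (mgmt == mgmt_raster.nodata) & (mgmt_raster.nodata != 0) | (
        fire == fire_year_raster.nodata
    )
    is_timber = np.isin(mgmt, list(_CODE_TO_CLASS))
    burned = (is_timber & (fire >= year_min) & ~nodata).astype(int)
    burned[nodata] = -1
    return burned


def pixel_area_ha(lat: float | np.ndarray, resolution: float, geographic: bool = True) -> np.ndarray:
    """Nominal pixel area in hectares.

    For geographic grids (``resolution`` in degrees) the equatorial cell area
    is scaled by cos(latitude); for projected metric grids (``resolution`` in
    metres) the area is a constant.
    """
    lat = np.asarray(lat, dtype=float)
    if geographic and np.any(np.abs(lat) >= 90.0):
        raise ValueError("latitude must satisfy |lat| < 90")
    if geographic:
        # one degree of a great circle ≈ 111.320 km at the equator
        edge_m = resolution * 111_320.0
        return edge_m * edge_m * np.cos(np.deg2rad(lat)) / 10_000.0
    const = resolution * resolution / 10_000.0
    return np.full(lat.shape, const) if lat.shape else np.asarray(const)


def cell_id(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Half-open one-degree cell ids ``"lonfloor_latfloor"``."""
    lonf = np.floor(np.asarray(lon)).astype(int)
    latf = np.floor(np.asarray(lat)).astype(int)
    return np.char.add(np.char.add(lonf.astype(str), "_"), latf.astype(str))


def area_by_class(
    points: pd.DataFrame, pixel_area: float | np.ndarray = 1.0
) -> pd.DataFrame:
    """Burned-area ledger by (country, one-degree cell, management class).

    ``points`` needs ``country``, ``lon``, ``lat``, ``mgmt_class`` and
    ``burned``; ``pixel_area`` is per-pixel hectares (scalar or per-row).
    Burned proportions are derivable as ``burned_area_ha / total_area_ha``.
    """
    unknown = set(points["mgmt_class"]) - set(MGMT_CODES)
    if unknown:
        raise ValueError(f"unknown management classes: {sorted(unknown)}")
    df = points.copy()
    df["cell_id"] = cell_id(df["lon"].to_numpy(), df["lat"].to_numpy())
    df["_area"] = np.broadcast_to(np.asarray(pixel_area, float), (len(df),))
    df["_burned_area"] = df["_area"] * (df["burned"] == 1)
    g = df.groupby(["country", "cell_id", "mgmt_class"], sort=True)
    out = g.agg(
        total_area_ha=("_area", "sum"),
        burned_area_ha=("_burned_area", "sum"),
        n_pixels=("_area", "size"),
        n_burned_pixels=("burned", lambda b: int((b == 1).sum())),
    ).reset_index()
    return out


def stratified_sample(
    points: pd.DataFrame,
    cell_deg: float = 1.0,
    max_per_class: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample up to ``max_per_class`` points per class per one-degree cell.

    Within each (cell, management class) stratum, draws
    ``min(n, max_per_class)`` distinct points uniformly without replacement;
    strata are then pooled (downstream stages pool per country).  The cap
    keeps country samples tractable while still covering each country's full
    extent, which plain random sampling of large countries does not.
    """
    if max_per_class < 1:
        raise ValueError(f"max_per_class must be >= 1, got {max_per_class}")
    cells = np.char.add(
        np.char.add(
            np.floor(points["lon"].to_numpy() / cell_deg).astype(int).astype(str), "_"
        ),
        np.floor(points["lat"].to_numpy() / cell_deg).astype(int).astype(str),
    )
    rng = np.random.default_rng(seed)
    keep_parts = []
    # sort groups for a deterministic stratum order independent of row order
    df = points.assign(_cell=cells)
    for _, grp in df.groupby(["_cell", "mgmt_class"], sort=True):
        if len(grp) <= max_per_class:
            keep_parts.append(grp.index.to_numpy())
        else:
            keep_parts.append(
                rng.choice(grp.index.to_numpy(), size=max_per_class, replace=False)
            )
    keep = np.concatenate(keep_parts) if keep_parts else np.array([], dtype=int)
    return points.loc[np.sort(keep)]


def country_inclusion(
    matched_points: pd.DataFrame, min_burn_frac: float = 0.001
) -> pd.Series:
    """Per-country keep/drop flags by matched-point burn fraction.

    A country is kept iff strictly more than ``min_burn_frac`` of its matched
    timber points burned — countries where fire is a negligible process add
    noise, not signal, to the burn-probability model.
    """
    flags = {}
    for country, grp in matched_points.groupby("country", sort=True):
        if len(grp) == 0:
            warnings.warn(f"country {country!r} has no matched points; dropped")
            flags[country] = False
            continue
        flags[country] = (grp["burned"] == 1).mean() > min_burn_frac
    return pd.Series(flags, name="keep")
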