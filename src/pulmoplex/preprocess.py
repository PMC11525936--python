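"""Table-level preprocessing: background subtraction, arcsinh
normalization, region-based artifact exclusion, and cell density.

The canonical order is subtract -> exclude -> normalize; exclusion is
idempotent and normalization commutes with row subsetting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .io import RegionSet

__all__ = [
    "subtract_background",
    "arcsinh_normalize",
    "exclude_regions",
    "cell_density",
]

#: arcsinh cofactor default, the flow/mass-cytometry convention
DEFAULT_COFACTOR = 5.0


def subtract_background(table: pd.DataFrame, spec, week=None) -> pd.DataFrame:
    """Subtract per-marker constant background, clipping at zero.

    ``spec`` is either a mapping marker -> value or a DataFrame with
    columns (marker, week, value); in the latter case ``week`` selects the
    row set (defaulting to the table's own week column when unique).
    """
    if isinstance(spec, pd.DataFrame):
        sub = spec
        if "week" in sub.columns:
            if week is None and "week" in table.columns and table["week"].nunique() == 1:
                week = table["week"].iloc[0]
            if week is not None:
                sub = sub[sub["week"] == week]
        spec = dict(zip(sub["marker"], sub["value"]))
    out = table.copy()
    for marker, bg in spec.items():
        if marker not in out.columns:
            raise KeyError(f"marker {marker!r} in background spec but not in table")
        if bg < 0:
            raise ValueError(f"marker {marker!r}: background must be >= 0")
        out[marker] = np.clip(out[marker].to_numpy(dtype=float) - bg, 0.0, None)
    return out


def arcsinh_normalize(table: pd.DataFrame, markers, cofactor: float = DEFAULT_COFACTOR) -> pd.DataFrame:
    """x -> asinh(x / cofactor) per marker column; monotone and
    order-preserving."""
    if cofactor <= 0:
        raise ValueError("cofactor must be > 0")
    out = table.copy()
    for m in markers:
        out[m] = np.arcsinh(out[m].to_numpy(dtype=float) / cofactor)
    return out


def exclude_regions(table: pd.DataFrame, regions: RegionSet | None) -> pd.DataFrame:
    """Drop cells inside any exclude polygon, or outside all include
    polygons when includes are given.  Centroids exactly on a polygon
    boundary count as inside."""
    if regions is None or len(regions) == 0:
        return table.copy()
    includes = [prep(r["polygon"]) for r in regions.with_role("include")]
    excludes = [prep(r["polygon"]) for r in regions.with_role("exclude")]
    xs = table["x_um"].to_numpy(dtype=float)
    ys = table["y_um"].to_numpy(dtype=float)
    keep = np.ones(len(table), dtype=bool)
    for i in range(len(table)):
        p = Point(xs[i], ys[i])
        if includes and not any(g.intersects(p) for g in includes):
            keep[i] = False
            continue
        if any(g.intersects(p) for g in excludes):
            keep[i] = False
    return table.loc[keep].copy()


def cell_density(table: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Cells per mm^2 per week, using the include-region polygon area."""
    includes = regions.with_role("include")
    if not includes:
        raise ValueError("cell_density needs at least one include region")
    area_um2 = sum(r["polygon"].area for r in includes)
    if area_um2 <= 0:
        raise ValueError("include region has zero area")
    area_mm2 = area_um2 / 1e6
    weeks = table["week"] if "week" in table.columns else pd.Series(0.0, index=table.index)
    counts = table.groupby(weeks).size()
    return pd.DataFrame({
        "week": counts.index.to_numpy(),
        "n_cells": counts.to_numpy(),
        "density_per_mm2": counts.to_numpy() / area_mm2,
    })
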