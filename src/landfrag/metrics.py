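"""Class-level fragmentation metrics: ED, CLUMPY, AREA_AM, SHAPE_AM.

All four are FRAGSTATS-style class metrics: each integrates every patch of one
land-cover class within a landscape (or zone treated as its own landscape).

* ED (edge density, m/ha): total length of edge between the class and other
  substantive classes, divided by landscape area.
* CLUMPY (dimensionless, [-1, 1]): deviation of the class's like-adjacency
  proportion from its areal proportion; -1 maximally disaggregated, 0 no
  different from random, 1 maximally clumped.
* AREA_AM (ha): area-weighted mean patch size, sum(a_j^2) / sum(a_j).
* SHAPE_AM (dimensionless, >= 1): area-weighted mean of the patch shape index
  p_j / min_p(a_j), where min_p is the smallest perimeter any raster patch of
  the same cell count can have (1 for a square, growing with irregularity).

Metrics that are undefined (absent class, single-class landscape) are returned
as NaN, never as zero.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .raster import (
    CLASS_NAMES,
    AdjacencyTable,
    CategoricalRaster,
    PatchSet,
    ZoneMask,
    adjacency_table,
    apply_zone,
    label_patches,
)

__all__ = [
    "min_perimeter_sides",
    "shape_index",
    "edge_density",
    "clumpy",
    "area_am",
    "shape_am",
    "class_metrics",
    "metrics_for_series",
    "metrics_long",
]


def min_perimeter_sides(area_cells: int) -> int:
    """Minimum perimeter, in cell sides, of a raster patch of given cell count.

    Achieved by the most square-like arrangement: with n = floor(sqrt(z)),
    the minimum is 4n for a perfect square, 4n + 2 while z <= n(n+1), and
    4n + 4 beyond.
    """
    z = int(area_cells)
    if z < 1:
        raise ValueError("area_cells must be >= 1")
    n = math.isqrt(z)
    if n * n == z:
        return 4 * n
    if z <= n * (n + 1):
        return 4 * n + 2
    return 4 * n + 4


def shape_index(perimeter_m: float, area_cells: int, cell_size: float) -> float:
    """Patch shape index: observed perimeter over the minimum possible.

    1 for a square patch; increasingly above 1 for irregular patches.
    """
    return perimeter_m / (min_perimeter_sides(area_cells) * cell_size)


def edge_density(raster: CategoricalRaster, class_code: int,
                 zone_area_ha: float | None = None,
                 count_boundary: bool = False) -> float:
    """Edge density of one class in m/ha.

    Sums the lengths of cell sides between the class and a *different
    substantive class* and divides by the landscape (zone) area.  Sides facing
    nodata or the grid boundary are excluded by default; ``count_boundary``
    includes them.  An A|B side counts toward both ED(A) and ED(B).  A class
    absent from the zone has ED 0.
    """
    area = raster.area_ha() if zone_area_ha is None else zone_area_ha
    if area <= 0:
        raise ValueError("landscape area must be > 0")
    grid = raster.grid
    is_class = grid == class_code
    sides = 0
    for a, b in ((grid[:, :-1], grid[:, 1:]), (grid[:-1, :], grid[1:, :])):
        ca, cb = a == class_code, b == class_code
        unlike = (ca ^ cb)
        internal = (a != raster.nodata) & (b != raster.nodata)
        sides += int((unlike & internal).sum())
    if count_boundary:
        padded = np.pad(grid, 1, constant_values=raster.nodata)
        core = padded[1:-1, 1:-1]
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            neigh = padded[1 + dr: padded.shape[0] - 1 + dr,
                           1 + dc: padded.shape[1] - 1 + dc]
            sides += int((is_class & (neigh == raster.nodata)).sum())
    return sides * raster.cell_size / area


def clumpy(adj: AdjacencyTable, class_code: int) -> float:
    """Clumpiness index of one class from its rook adjacency row.

    G_i = g_ii / (sum_k g_ik - min_e_i), where min_e_i is the minimum
    perimeter (in sides) of a maximally compact patch holding the whole class
    area; when that denominator is not positive the uncorrected ratio
    g_ii / sum_k g_ik is used.  CLUMPY is (G_i - P_i) / P_i when G_i < P_i and
    P_i < 0.5, else (G_i - P_i) / (1 - P_i), clamped to [-1, 1].

    Undefined (NaN) for an absent class or a class filling the landscape.
    """
    i = adj.index(class_code)
    count = int(adj.cell_counts[i])
    P = float(adj.P[i])
    if count == 0 or P >= 1.0:
        return float("nan")
    g_ii = float(adj.g[i, i])
    sum_g = float(adj.g[i].sum())
    if sum_g <= 0:
        G = 0.0
    else:
        denom = sum_g - min_perimeter_sides(count)
        G = g_ii / denom if denom > 0 else g_ii / sum_g
    if G < P and P < 0.5:
        value = (G - P) / P
    else:
        value = (G - P) / (1.0 - P)
    return float(np.clip(value, -1.0, 1.0))


def area_am(patches: PatchSet, class_code: int) -> float:
    """Area-weighted mean patch size (ha): sum(a_j^2) / sum(a_j).

    Lies between the smallest and largest patch area; NaN if the class has no
    patches.
    """
    a = patches.for_class(class_code)["area_ha"].to_numpy()
    if a.size == 0:
        return float("nan")
    return float((a**2).sum() / a.sum())


def shape_am(patches: PatchSet, class_code: int) -> float:
    """Area-weighted mean patch shape index; NaN if the class has no patches."""
    sub = patches.for_class(class_code)
    if len(sub) == 0:
        return float("nan")
    a = sub["area_ha"].to_numpy()
    si = np.array([
        shape_index(p, z, patches.cell_size)
        for p, z in zip(sub["perimeter_m"], sub["area_cells"])
    ])
    return float((si * a).sum() / a.sum())


def class_metrics(raster: CategoricalRaster, zone_label: str = "all",
                  count_boundary: bool = False) -> pd.DataFrame:
    """All four metrics for every substantive class of one (zoned) raster.

    Returns one row per class with columns year, zone, class_code, class,
    ED, CLUMPY, AREA_AM, SHAPE_AM, class_area_ha, n_patches.
    """
    patches = label_patches(raster)
    adj = adjacency_table(raster)
    area = raster.area_ha()
    rows = []
    for code in raster.class_codes:
        sub = patches.for_class(code)
        rows.append({
            "year": raster.year,
            "zone": zone_label,
            "class_code": code,
            "class": CLASS_NAMES.get(code, str(code)),
            "ED": edge_density(raster, code, area, count_boundary),
            "CLUMPY": clumpy(adj, code),
            "AREA_AM": area_am(patches, code),
            "SHAPE_AM": shape_am(patches, code),
            "class_area_ha": raster.area_ha(code),
            "n_patches": len(sub),
        })
    return pd.DataFrame(rows)


def metrics_for_series(rasters: list[CategoricalRaster],
                       zones: list[ZoneMask] | None = None,
                       count_boundary: bool = False,
                       site: str | None = None) -> pd.DataFrame:
    """Metric table for a raster time series, stratified by zones.

    One row per year x zone x class; undefined metrics propagate as NaN.
    With no zones the whole landscape is the single zone ``"all"``.
    """
    frames = []
    for raster in rasters:
        if zones is None:
            frames.append(class_metrics(raster, "all", count_boundary))
        else:
            for zone in zones:
                zoned = apply_zone(raster, zone)
                frames.append(class_metrics(zoned, zone.label, count_boundary))
    out = pd.concat(frames, ignore_index=True)
    if site is not None:
        out.insert(0, "site", site)
    return out


def metrics_long(table: pd.DataFrame) -> pd.DataFrame:
    """Melt the wide metric table to (site?, year, zone, class, metric, value)."""
    ids = [c for c in ("site", "year", "zone", "class") if c in table.columns]
    return table.melt(
        id_vars=ids,
        value_vars=["ED", "CLUMPY", "AREA_AM", "SHAPE_AM"],
        var_name="metric",
        value_name="value",
    )
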