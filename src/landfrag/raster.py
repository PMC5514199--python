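"""Categorical raster data model, zone masking, patch delineation and adjacency counts.

The substrate for all fragmentation metrics: a land-cover map is a 2-D grid of
integer class codes (mature forest, non-forest, secondary forest) plus a nodata
code.  Patches are maximal connected components of equal-class cells (queen /
8-neighbour connectivity by default); adjacency counts for aggregation indices
use rook (shared-side) relations with the double-count convention.

Grid boundary and nodata cells are "outside the landscape": they contribute to
a patch's perimeter but not to adjacency tallies, and by default not to edge
density either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

#: default class codes for the three substantive land-cover classes
MF, NF, SF = 1, 2, 3
NODATA = 0

CLASS_NAMES = {MF: "MF", NF: "NF", SF: "SF"}

_QUEEN = np.ones((3, 3), dtype=int)
_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class CategoricalRaster:
    """One year's land-cover map: class-coded grid + cell size + nodata code.

    ``origin`` is the (xllcorner, yllcorner) of the grid in map units and,
    together with ``crs``, is carried through I/O untouched; all internal
    computation is in 0-based row/col space.
    """

    grid: np.ndarray
    cell_size: float = 30.0
    nodata: int = NODATA
    year: int | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None
    class_codes: tuple[int, ...] = (MF, NF, SF)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integer class codes")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        allowed = set(self.class_codes) | {self.nodata}
        present = set(np.unique(self.grid).tolist())
        unknown = present - allowed
        if unknown:
            raise ValueError(
                f"grid contains codes {sorted(unknown)} outside "
                f"class_codes {self.class_codes} and nodata {self.nodata}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (cell_size is metres per side)."""
        return self.cell_size**2 / 1e4

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return self.grid != self.nodata

    def area_ha(self, code: int | None = None) -> float:
        """Area in hectares of one class, or of all non-nodata cells."""
        n = int(self.valid.sum()) if code is None else int((self.grid == code).sum())
        return n * self.cell_area_ha

    def counts(self) -> dict[int, int]:
        """Cell counts per substantive class."""
        return {c: int((self.grid == c).sum()) for c in self.class_codes}


@dataclass
class ZoneMask:
    """Boolean zone aligned to a raster, e.g. inside vs outside a conservation unit."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("zone mask must be 2-D")

    @property
    def complement(self) -> "ZoneMask":
        return ZoneMask(~self.mask, f"not_{self.label}")


def binary_zones(mask: np.ndarray, inside: str = "inside_CU",
                 outside: str = "outside_CU") -> list[ZoneMask]:
    """Inside/outside stratification from one boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    return [ZoneMask(mask, inside), ZoneMask(~mask, outside)]


def check_partition(zones: list[ZoneMask], raster: CategoricalRaster) -> None:
    """Zones of one stratification must partition the non-nodata cells."""
    total = np.zeros(raster.shape, dtype=int)
    for z in zones:
        if z.mask.shape != raster.shape:
            raise ValueError(f"zone {z.label!r} shape {z.mask.shape} != raster {raster.shape}")
        total += z.mask
    bad = total[raster.valid]
    if bad.size and ((bad > 1).any() or (bad < 1).any()):
        raise ValueError("zones overlap or leave non-nodata cells uncovered")


@dataclass
class PatchSet:
    """8-connected (by default) patches of each class with areas and perimeters.

    ``labels`` assigns a unique positive id to every patch across classes;
    0 marks nodata.  ``patches`` is a table with one row per patch:
    patch_id, class_code, area_cells, area_ha, perimeter_m.
    """

    labels: np.ndarray
    patches: pd.DataFrame
    cell_size: float

    def for_class(self, code: int) -> pd.DataFrame:
        return self.patches[self.patches["class_code"] == code]


@dataclass
class AdjacencyTable:
    """Rook cell-side adjacency counts between classes (double-count convention).

    ``g[i, k]`` counts ordered adjacent cell pairs (class i cell, class k
    neighbour) over internal sides only, so one like-class side contributes 2
    to ``g[i, i]`` and one unlike side contributes 1 to each direction.
    Sides facing nodata or the grid boundary are excluded.  ``P`` is each
    class's share of the non-nodata area.
    """

    classes: tuple[int, ...]
    g: np.ndarray
    cell_counts: np.ndarray
    P: np.ndarray

    def index(self, code: int) -> int:
        return self.classes.index(code)


# ---------------------------------------------------------------------------
# core operations

def apply_zone(raster: CategoricalRaster, zone: ZoneMask) -> CategoricalRaster:
    """Restrict a raster to a zone: cells outside become nodata.

    Patches are thereby clipped at the zone boundary; the zoned raster's
    non-nodata area is the density denominator for that zone.
    """
    if zone.mask.shape != raster.shape:
        raise ValueError(f"zone shape {zone.mask.shape} != raster shape {raster.shape}")
    if not zone.mask.any():
        raise ValueError(f"zone {zone.label!r} is empty")
    grid = np.where(zone.mask, raster.grid, raster.nodata).astype(raster.grid.dtype)
    return replace(raster, grid=grid)


def label_patches(raster: CategoricalRaster, connectivity: int = 8) -> PatchSet:
    """Delineate per-class patches and measure their areas and perimeters.

    A patch is a maximal set of equal-class cells connected under the chosen
    neighbourhood (8 = queen, the default; 4 = rook).  Perimeter counts every
    cell side adjoining a different class, nodata, or the grid boundary, in
    metres.
    """
    structure = _QUEEN if connectivity == 8 else _ROOK
    labels = np.zeros(raster.shape, dtype=np.int32)
    offset = 0
    rows: list[tuple[int, int, int]] = []  # (patch_id, class_code, area_cells)
    for code in raster.class_codes:
        lab, n = ndimage.label(raster.grid == code, structure=structure)
        if n == 0:
            continue
        areas = np.bincount(lab.ravel())[1:]
        labels[lab > 0] = lab[lab > 0] + offset
        rows.extend((offset + i + 1, code, int(a)) for i, a in enumerate(areas))
        offset += n

    # exposed sides per cell: neighbours differing in value, with nodata padding
    padded = np.pad(raster.grid, 1, constant_values=raster.nodata)
    core = padded[1:-1, 1:-1]
    exposed = np.zeros(raster.shape, dtype=np.int32)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        exposed += neigh != core
    per_label = np.bincount(labels.ravel(), weights=exposed.ravel(), minlength=offset + 1)

    df = pd.DataFrame(rows, columns=["patch_id", "class_code", "area_cells"],
                      dtype=np.int64)
    df["area_ha"] = df["area_cells"] * raster.cell_area_ha
    df["perimeter_m"] = per_label[df["patch_id"].to_numpy(dtype=np.int64)] * raster.cell_size
    return PatchSet(labels=labels, patches=df, cell_size=raster.cell_size)


def adjacency_table(raster: CategoricalRaster) -> AdjacencyTable:
    """Tally rook adjacencies between substantive classes, internal sides only.

    Raises if the raster is entirely nodata.
    """
    if not raster.valid.any():
        raise ValueError("raster is entirely nodata")
    classes = tuple(raster.class_codes)
    k = len(classes)
    g = np.zeros((k, k), dtype=np.int64)
    grid = raster.grid
    for a, b in (
        (grid[:, :-1], grid[:, 1:]),
        (grid[:-1, :], grid[1:, :]),
    ):
        ok = (a != raster.nodata) & (b != raster.nodata)
        ai = a[ok].ravel()
        bi = b[ok].ravel()
        if ai.size == 0:
            continue
        ia = _map_codes(ai, classes)
        ib = _map_codes(bi, classes)
        np.add.at(g, (ia, ib), 1)
        np.add.at(g, (ib, ia), 1)
    counts = np.array([(grid == c).sum() for c in classes], dtype=np.int64)
    total = counts.sum()
    P = counts / total if total else np.zeros(k)
    return AdjacencyTable(classes=classes, g=g, cell_counts=counts, P=P)


def _map_codes(values: np.ndarray, classes: tuple[int, ...]) -> np.ndarray:
    lut = np.full(max(classes) + 1, -1, dtype=np.int64)
    for i, c in enumerate(classes):
        lut[c] = i
    return lut[values]


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and GeoTIFF

def read_raster(path: str | Path, year: int | None = None,
                remap: dict[int, int] | None = None,
                class_codes: tuple[int, ...] = (MF, NF, SF)) -> CategoricalRaster:
    """Read a land-cover map from GeoTIFF or ESRI ASCII grid.

    ``remap`` translates file codes to the package's class codes before
    validation; any code not mapped into ``class_codes`` or nodata is an
    error.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        grid, meta = _read_geotiff(path)
    else:
        grid, meta = _read_ascii(path)
    if remap:
        src = grid.copy()
        for old, new in remap.items():
            grid[src == old] = new
    if year is not None:
        meta["year"] = year
    return CategoricalRaster(grid=grid, class_codes=class_codes, **meta)


def write_raster(raster: CategoricalRaster, path: str | Path) -> Path:
    """Write to GeoTIFF or ESRI ASCII grid, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(raster, path)
    else:
        _write_ascii(raster, path)
    return path


def _read_ascii(path: Path) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    grid = np.loadtxt(path, skiprows=n_header, dtype=np.int16, ndmin=2)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match header")
    return grid, {
        "cell_size": header["cellsize"],
        "nodata": int(header.get("nodata_value", NODATA)),
        "origin": (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    }


def _write_ascii(raster: CategoricalRaster, path: Path) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.grid, fmt="%d")


def _read_geotiff(path: Path) -> tuple[np.ndarray, dict]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        grid = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return grid.astype(np.int16), {
        "cell_size": float(meta.get("cell_size", 30.0)),
        "nodata": int(meta.get("nodata", NODATA)),
        "year": meta.get("year"),
        "origin": tuple(meta.get("origin", (0.0, 0.0))),
        "crs": meta.get("crs"),
    }


def _write_geotiff(raster: CategoricalRaster, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size": raster.cell_size,
        "nodata": raster.nodata,
        "year": raster.year,
        "origin": list(raster.origin),
        "crs": raster.crs,
    }
    tifffile.imwrite(path, raster.grid.astype(np.int16), description=json.dumps(meta))


def zones_from_geojson(path: str | Path, like: CategoricalRaster,
                       label_property: str = "label") -> list[ZoneMask]:
    """Rasterize GeoJSON polygons onto a raster's grid by centre-point containment.

    Each feature becomes one ZoneMask named by its ``label_property``; cell
    centres are computed from the raster's origin and cell size (y increases
    upward from yllcorner, row 0 is the top of the grid).
    """
    import shapely
    from shapely.geometry import shape as shp_shape

    with open(path) as fh:
        gj = json.load(fh)
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    nrows, ncols = like.shape
    x0, y0 = like.origin
    cols = x0 + (np.arange(ncols) + 0.5) * like.cell_size
    rows = y0 + (nrows - np.arange(nrows) - 0.5) * like.cell_size
    xx, yy = np.meshgrid(cols, rows)
    zones = []
    for i, feat in enumerate(features):
        geom = shp_shape(feat["geometry"])
        mask = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(nrows, ncols)
        label = feat.get("properties", {}).get(label_property, f"zone_{i}")
        zones.append(ZoneMask(mask, str(label)))
    return zones
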