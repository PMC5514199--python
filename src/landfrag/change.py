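"""Inter-map transition accounting and the relative incidence of deforestation.

Deforestation here is the transition of a mature-forest (MF) pixel to
non-forest (NF) between two consecutive maps.  Because secondary forest must
be preceded by non-forest, direct MF->SF transitions should not occur; when
they do (classification noise), they are tallied in a QC column and excluded
from the deforested area D unless explicitly requested.

The relative incidence of deforestation for zone class i is

    RID_i = (D_i / D_total) / (A_i / A_total)

the zone's share of deforested area over its share of landscape area.  RID = 1
means deforestation proportional to area; < 1 less than proportional (e.g. an
effective conservation unit); > 1 disproportionate deforestation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import MF, NF, SF, CategoricalRaster, ZoneMask, check_partition

__all__ = ["TransitionTally", "transitions", "rid", "rid_series"]

_ORDER = (MF, NF, SF)  # matrix rows/cols; index 3 is nodata


@dataclass
class TransitionTally:
    """Per-zone cross-tabulation of class transitions over one map interval.

    ``counts[i, j]`` is the number of zone pixels going from class i (rows)
    to class j (columns), classes ordered (MF, NF, SF, nodata).
    """

    year_from: int
    year_to: int
    zone: str
    counts: np.ndarray
    cell_size: float

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4

    @property
    def A_ha(self) -> float:
        """Zone area (ha): non-nodata cells at the interval start."""
        return float(self.counts[:3].sum()) * self.cell_area_ha

    def D_ha(self, include_sf_clearing: bool = False) -> float:
        """Deforested area (ha): MF->NF, optionally plus SF->NF."""
        d = self.counts[0, 1]
        if include_sf_clearing:
            d = d + self.counts[2, 1]
        return float(d) * self.cell_area_ha

    @property
    def qc_mf_to_sf_ha(self) -> float:
        """MF->SF area (ha): a succession-rule violation surfaced for QC."""
        return float(self.counts[0, 2]) * self.cell_area_ha


def transitions(r_from: CategoricalRaster, r_to: CategoricalRaster,
                zones: list[ZoneMask]) -> list[TransitionTally]:
    """Cross-tabulate class transitions between two maps, per zone."""
    if r_from.shape != r_to.shape:
        raise ValueError(f"misaligned rasters: {r_from.shape} vs {r_to.shape}")
    if r_from.cell_size != r_to.cell_size:
        raise ValueError("rasters differ in cell size")
    if r_from.year is not None and r_to.year is not None and r_from.year >= r_to.year:
        raise ValueError("year_from must precede year_to")
    check_partition(zones, r_from)

    def to_index(grid: np.ndarray, nodata: int) -> np.ndarray:
        out = np.full(grid.shape, 3, dtype=np.int64)
        for i, code in enumerate(_ORDER):
            out[grid == code] = i
        out[grid == nodata] = 3
        return out

    ia = to_index(r_from.grid, r_from.nodata)
    ib = to_index(r_to.grid, r_to.nodata)
    tallies = []
    for zone in zones:
        counts = np.zeros((4, 4), dtype=np.int64)
        np.add.at(counts, (ia[zone.mask], ib[zone.mask]), 1)
        tallies.append(TransitionTally(
            year_from=r_from.year if r_from.year is not None else 0,
            year_to=r_to.year if r_to.year is not None else 1,
            zone=zone.label,
            counts=counts,
            cell_size=r_from.cell_size,
        ))
    return tallies


def rid(tallies: list[TransitionTally], include_sf_clearing: bool = False,
        annualize: bool = False) -> pd.DataFrame:
    """RID per zone class for one interval's tallies.

    Undefined (NaN) for every zone when no deforestation occurred; 0 for a
    zone with none while others had some.  ``annualize`` divides the reported
    D_ha by the interval length in years (RID itself, a ratio of shares, is
    unaffected).
    """
    if not tallies:
        raise ValueError("no tallies given")
    D = np.array([t.D_ha(include_sf_clearing) for t in tallies])
    A = np.array([t.A_ha for t in tallies])
    A_total = A.sum()
    if A_total <= 0:
        raise ValueError("total zone area is zero")
    D_total = D.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (D / D_total) / (A / A_total) if D_total > 0 else np.full(len(D), np.nan)
    span = max(tallies[0].year_to - tallies[0].year_from, 1)
    D_out = D / span if annualize else D
    return pd.DataFrame({
        "interval_start": [t.year_from for t in tallies],
        "interval_end": [t.year_to for t in tallies],
        "zone": [t.zone for t in tallies],
        "D_ha": D_out,
        "A_ha": A,
        "RID": values,
        "qc_mf_to_sf_ha": [t.qc_mf_to_sf_ha for t in tallies],
    })


def rid_series(rasters: list[CategoricalRaster], zones: list[ZoneMask],
               include_sf_clearing: bool = False, annualize: bool = False,
               site: str | None = None) -> pd.DataFrame:
    """RID per consecutive-map interval per zone class.

    n maps yield n-1 intervals; the interval bounds are kept so longer gap
    intervals remain identifiable.
    """
    if len(rasters) < 2:
        raise ValueError("need at least 2 maps")
    frames = []
    for r_from, r_to in zip(rasters[:-1], rasters[1:]):
        tallies = transitions(r_from, r_to, zones)
        frames.append(rid(tallies, include_sf_clearing, annualize))
    out = pd.concat(frames, ignore_index=True)
    if site is not None:
        out.insert(0, "site", site)
    return out
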