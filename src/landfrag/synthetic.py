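"""Synthetic 3-class land-cover time series generator.

Emulates the landscape dynamics of Amazonian colonisation frontiers so the
whole analysis pipeline can be exercised without satellite-derived maps:

* a landscape starting as mature forest with a road network (spontaneous
  lines or a planned "fishbone" settlement: one spine with perpendicular ribs);
* deforestation spreading contagiously — clearing probability concentrated on
  cells adjacent to already-cleared land, blended with an exponential
  road-proximity kernel;
* reduced clearing probability inside a conservation-unit mask
  (``protection_factor`` multiplies clearing weight; 0 = inviolate);
* episodic wildfires burning irregular connected scars into mature forest;
* regrowth: non-forest left fallow for ``min_fallow`` years converts to
  secondary forest with an annual probability, and secondary forest can be
  re-cleared — so secondary forest is always preceded by non-forest, by
  construction;
* quasi-annual output with optional 2-4 year gaps (gap years are simulated
  internally but omitted from the output series).

Defaults are 30 m cells on annual steps 1984-2011.  All stochastic draws
come from one seeded generator; runs are reproducible from the scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .raster import MF, NF, SF, CategoricalRaster, ZoneMask

__all__ = [
    "SyntheticScenario",
    "fishbone_roads",
    "generate_series",
    "scenario_presets",
]

Polyline = list[tuple[int, int]]

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_QUEEN = np.ones((3, 3), dtype=int)


@dataclass
class SyntheticScenario:
    """Parameters of one simulated deforestation history."""

    shape: tuple[int, int] = (80, 80)
    cell_size: float = 30.0
    year_start: int = 1984
    year_end: int = 2011
    gap_years: tuple[int, ...] = ()
    roads: list[Polyline] = field(default_factory=list)
    settlement_mode: str = "spontaneous"  # or "fishbone"
    annual_budget: int = 40               # cells cleared per year
    plot_cells: int = 6                   # compact plot size per clearing event
    contagion: float = 0.6                # weight on NF-adjacency vs road kernel
    road_decay_cells: float = 8.0         # e-folding Chebyshev distance of road kernel
    cu_mask: np.ndarray | None = None
    protection_factor: float = 0.5        # multiplies clearing weight inside the CU
    wildfires: list[tuple[int, int, float]] = field(default_factory=list)
    # (year, target size in cells, irregularity in [0, 1])
    regrowth_prob: float = 0.15           # annual NF->SF after the fallow period
    min_fallow: int = 2                   # years NF must persist before regrowth
    reclear_prob: float = 0.05            # annual SF->NF
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contagion", "protection_factor", "regrowth_prob", "reclear_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.annual_budget < 0:
            raise ValueError("annual_budget must be >= 0")
        if self.min_fallow < 1:
            raise ValueError("min_fallow must be >= 1 year")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        for year, size, irr in self.wildfires:
            if not 0.0 <= irr <= 1.0:
                raise ValueError(f"wildfire irregularity must be in [0, 1], got {irr}")
            if size < 1:
                raise ValueError("wildfire size must be >= 1")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @property
    def output_years(self) -> list[int]:
        return [y for y in self.years if y not in self.gap_years]

    def cu_zone(self) -> ZoneMask | None:
        if self.cu_mask is None:
            return None
        return ZoneMask(self.cu_mask, "inside_CU")


def fishbone_roads(shape: tuple[int, int], orientation: str = "horizontal",
                   spacing: int = 8) -> list[Polyline]:
    """Planned-settlement road geometry: one spine plus perpendicular ribs.

    The spine runs through the grid middle; full-length ribs branch off at
    every ``spacing`` cells (so a 40-cell spine with spacing 8 has 4 ribs).
    """
    nrows, ncols = shape
    if spacing < 2:
        raise ValueError("spacing must be >= 2 cells")
    if spacing >= max(nrows, ncols):
        raise ValueError(f"spacing {spacing} larger than grid {shape}")
    roads: list[Polyline] = []
    if orientation.startswith("h"):
        mid = nrows // 2
        roads.append([(mid, 0), (mid, ncols - 1)])
        for c in range(spacing, ncols, spacing):
            roads.append([(0, c), (nrows - 1, c)])
    else:
        mid = ncols // 2
        roads.append([(0, mid), (nrows - 1, mid)])
        for r in range(spacing, nrows, spacing):
            roads.append([(r, 0), (r, ncols - 1)])
    return roads


def rasterize_roads(shape: tuple[int, int], roads: list[Polyline]) -> np.ndarray:
    """Boolean mask of road cells from polyline vertices (Bresenham segments)."""
    mask = np.zeros(shape, dtype=bool)
    for poly in roads:
        for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            mask[rr, cc] = True
    return mask


def _road_kernel(road_mask: np.ndarray, decay_cells: float) -> np.ndarray:
    """exp(-d/decay) with d the Chebyshev distance to the nearest road cell."""
    if not road_mask.any():
        return np.ones(road_mask.shape)
    dist = ndimage.distance_transform_cdt(~road_mask, metric="chessboard")
    return np.exp(-dist / decay_cells)


def _grow_scar(rng: np.random.Generator, burnable: np.ndarray, size: int,
               irregularity: float, start: tuple[int, int] | None = None,
               spotting: bool = True) -> np.ndarray:
    """Grow an irregular connected scar by biased random accretion.

    Frontier cells compete with weight u * exp(lambda * compactness), where
    compactness is the fraction of rook neighbours already burning, u is
    uniform noise, and lambda = 4 * (1 - 2 * irregularity): irregularity 0
    fills concavities first (near-disc), 0.5 is unbiased Eden growth, and 1
    prefers low-contact frontier cells, branching into a dendritic scar.
    """
    avail = int(burnable.sum())
    if size > avail:
        raise ValueError(f"wildfire size {size} exceeds burnable cells {avail}")
    nrows, ncols = burnable.shape
    if start is None:
        seeds = np.argwhere(burnable)
        start = tuple(seeds[rng.integers(len(seeds))])
    scar = np.zeros_like(burnable)
    scar[start] = True
    while scar.sum() < size:
        frontier_mask = ndimage.binary_dilation(scar, structure=_ROOK) & burnable & ~scar
        frontier = np.argwhere(frontier_mask)
        if len(frontier) == 0:
            if not spotting:
                break  # a clearing plot stops at its connected extent
            # connected fuel exhausted: the fire spots to a new ignition point
            remaining = np.argwhere(burnable & ~scar)
            scar[tuple(remaining[rng.integers(len(remaining))])] = True
            continue
        neigh = np.zeros(scar.shape, dtype=np.int8)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            shifted = np.zeros_like(neigh)
            rs = slice(max(dr, 0), nrows + min(dr, 0))
            rd = slice(max(-dr, 0), nrows + min(-dr, 0))
            cs = slice(max(dc, 0), ncols + min(dc, 0))
            cd = slice(max(-dc, 0), ncols + min(-dc, 0))
            shifted[rd, cd] = scar[rs, cs]
            neigh += shifted
        compact = neigh[frontier[:, 0], frontier[:, 1]] / 4.0
        lam = 4.0 * (1.0 - 2.0 * irregularity)
        w = rng.random(len(frontier)) * np.exp(lam * compact)
        w = np.maximum(w, 1e-12)
        pick = frontier[rng.choice(len(frontier), p=w / w.sum())]
        scar[pick[0], pick[1]] = True
    return scar


def generate_series(scenario: SyntheticScenario) -> list[CategoricalRaster]:
    """Simulate the land-cover history and return the (non-gap) annual maps.

    Year 0 is mature forest everywhere except road cells (non-forest).  Each
    subsequent year: (1) clear ``annual_budget`` mature-forest cells sampled
    proportionally to contagion/road/protection weights; (2) burn any
    scheduled wildfire scar; (3) convert eligible fallow non-forest to
    secondary forest; (4) re-clear secondary forest at the re-clearing rate.
    """
    rng = np.random.default_rng(scenario.seed)
    shape = scenario.shape
    roads = scenario.roads
    if scenario.settlement_mode == "fishbone" and not roads:
        roads = fishbone_roads(shape)
    road_mask = rasterize_roads(shape, roads)
    kernel = _road_kernel(road_mask, scenario.road_decay_cells)
    protection = np.ones(shape)
    if scenario.cu_mask is not None:
        if scenario.cu_mask.shape != shape:
            raise ValueError("cu_mask shape mismatch")
        protection[scenario.cu_mask] = scenario.protection_factor

    grid = np.full(shape, MF, dtype=np.int16)
    grid[road_mask] = NF
    fallow_age = np.zeros(shape, dtype=np.int16)
    fires = {year: (size, irr) for year, size, irr in scenario.wildfires}

    out: list[CategoricalRaster] = []

    def snapshot(year: int) -> CategoricalRaster:
        return CategoricalRaster(grid=grid.copy(), cell_size=scenario.cell_size,
                                 year=year)

    first = True
    for year in scenario.years:
        if not first:
            _step(grid, fallow_age, scenario, rng, kernel, protection,
                  road_mask, fires.get(year))
        first = False
        if year not in scenario.gap_years:
            out.append(snapshot(year))
    return out


def _step(grid: np.ndarray, fallow_age: np.ndarray, sc: SyntheticScenario,
          rng: np.random.Generator, kernel: np.ndarray, protection: np.ndarray,
          road_mask: np.ndarray, fire: tuple[int, float] | None) -> None:
    nf_at_start = grid == NF  # fallow only accrues over completed years as NF

    # 1. contagious clearing of mature forest, in compact plots
    # (anthropogenic clearings are regular blocks, in contrast to fire scars)
    remaining = sc.annual_budget
    while remaining > 0:
        mf = grid == MF
        clearable = mf & (protection > 0)
        adj_nf = ndimage.binary_dilation(grid == NF, structure=_QUEEN) & mf
        w = (sc.contagion * adj_nf + (1.0 - sc.contagion) * kernel) * protection * mf
        flat = w.ravel()
        total = flat.sum()
        if total <= 0 or not clearable.any():
            break
        seed_flat = rng.choice(np.flatnonzero(flat > 0),
                               p=flat[flat > 0] / total)
        seed = np.unravel_index(seed_flat, grid.shape)
        size = min(sc.plot_cells, remaining, int(clearable.sum()))
        plot = _grow_scar(rng, clearable, size, irregularity=0.0,
                          start=tuple(seed), spotting=False)
        grid[plot] = NF
        fallow_age[plot] = 0
        remaining -= int(plot.sum())

    # 2. scheduled wildfire
    if fire is not None:
        size, irr = fire
        burnable = grid == MF
        scar = _grow_scar(rng, burnable, int(size), float(irr))
        grid[scar] = NF
        fallow_age[scar] = 0

    # 3. regrowth NF -> SF after the fallow period (roads never regrow)
    nf = (grid == NF) & ~road_mask
    fallow_age[nf & nf_at_start] += 1
    fallow_age[grid != NF] = 0
    eligible = nf & (fallow_age >= sc.min_fallow)
    if sc.regrowth_prob > 0 and eligible.any():
        regrow = eligible & (rng.random(grid.shape) < sc.regrowth_prob)
        grid[regrow] = SF
        fallow_age[regrow] = 0

    # 4. re-clearing SF -> NF
    sf = grid == SF
    if sc.reclear_prob > 0 and sf.any():
        reclear = sf & (rng.random(grid.shape) < sc.reclear_prob)
        grid[reclear] = NF
        fallow_age[reclear] = 0


def scenario_presets(shape: tuple[int, int] = (80, 80)) -> dict[str, SyntheticScenario]:
    """Three contrasting named scenarios.

    * ``isolated_low_pressure`` — remote landscape, little clearing, strong
      protection, no fires.
    * ``spontaneous_with_fires`` — moderate spontaneous colonisation along a
      road with two large wildfire years.
    * ``planned_settlement`` — fishbone road grid with heavy, highly
      contagious clearing.
    """
    nrows, ncols = shape
    ncells = nrows * ncols
    cu = np.zeros(shape, dtype=bool)
    cu[:, : int(0.4 * ncols)] = True  # western 40% protected
    # axis-aligned highway corridor through the grid middle
    corridor: list[Polyline] = [[(nrows // 2, 0), (nrows // 2, ncols - 1)]]
    return {
        "isolated_low_pressure": SyntheticScenario(
            shape=shape, roads=corridor, annual_budget=max(ncells // 450, 1),
            contagion=0.4, cu_mask=cu, protection_factor=0.15,
            gap_years=(1987, 1994, 2005),
        ),
        "spontaneous_with_fires": SyntheticScenario(
            shape=shape, roads=corridor, annual_budget=max(ncells // 130, 1),
            contagion=0.6, cu_mask=cu, protection_factor=0.4,
            wildfires=[(1993, max(ncells // 18, 4), 0.7),
                       (1998, max(ncells // 13, 4), 0.8)],
            gap_years=(1988, 2002),
        ),
        "planned_settlement": SyntheticScenario(
            shape=shape, settlement_mode="fishbone", annual_budget=max(ncells // 80, 1),
            contagion=0.8, cu_mask=cu, protection_factor=0.3,
            gap_years=(1991, 1999, 2000, 2007),
        ),
    }
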