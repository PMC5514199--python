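"""Class-level metric definitions: worked cases, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from landfrag import (
    MF, NF, SF,
    CategoricalRaster,
    adjacency_table,
    area_am,
    class_metrics,
    clumpy,
    edge_density,
    label_patches,
    metrics_for_series,
    metrics_long,
    min_perimeter_sides,
    shape_am,
    shape_index,
)

from .oracles import (
    area_am_oracle,
    clumpy_oracle,
    edge_density_oracle,
    enumerate_polyominoes,
    min_perimeter_closed_form,
    polyomino_perimeter,
    shape_am_oracle,
)

RTOL = 1e-9


def _raster(grid, **kw):
    return CategoricalRaster(np.asarray(grid, dtype=np.int16), **kw)


class TestMinPerimeter:
    @given(st.integers(1, 5000))
    def test_agrees_with_closed_form(self, z):
        assert min_perimeter_sides(z) == min_perimeter_closed_form(z)

    def test_eight_cell_minimum_by_exhaustion(self):
        """All 8-cell polyominoes have perimeter >= 12, attained."""
        perims = {polyomino_perimeter(p) for p in enumerate_polyominoes(8)}
        assert min(perims) == 12 == min_perimeter_sides(8)

    def test_square_strip_values(self):
        assert min_perimeter_sides(1) == 4
        assert min_perimeter_sides(9) == 12
        assert min_perimeter_sides(6) == 10   # 2x3 rectangle


class TestShapeIndex:
    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_square_patch_is_one(self, n):
        grid = np.full((n + 2, n + 2), NF, dtype=np.int16)
        grid[1:1 + n, 1:1 + n] = MF
        patches = label_patches(_raster(grid))
        row = patches.for_class(MF).iloc[0]
        assert shape_index(row["perimeter_m"], row["area_cells"], 30.0) == pytest.approx(1.0)

    def test_strip_eight_cells(self):
        grid = np.full((3, 10), NF, dtype=np.int16)
        grid[1, 1:9] = MF
        patches = label_patches(_raster(grid))
        row = patches.for_class(MF).iloc[0]
        assert row["perimeter_m"] == 18 * 30.0
        assert shape_index(row["perimeter_m"], row["area_cells"], 30.0) == pytest.approx(1.5)


class TestEdgeDensity:
    def test_absent_class_is_zero(self, square_in_matrix):
        assert edge_density(square_in_matrix, SF) == 0.0

    def test_class_filling_zone_is_zero(self):
        assert edge_density(_raster(np.full((5, 5), MF)), MF) == 0.0

    def test_small_patch_worked_case(self, square_in_matrix):
        # 2x2 patch: 8 unlike sides x 30 m = 240 m over 9 ha
        assert edge_density(square_in_matrix, MF) == pytest.approx(240 / 9.0, rel=RTOL)

    def test_boundary_flag_adds_nodata_sides(self):
        r = _raster(np.full((5, 5), MF))
        assert edge_density(r, MF, count_boundary=True) == pytest.approx(
            20 * 30 / r.area_ha(), rel=RTOL)


class TestClumpy:
    def test_checkerboard_is_minus_one(self, checkerboard):
        adj = adjacency_table(checkerboard)
        assert clumpy(adj, MF) == -1.0
        assert clumpy(adj, NF) == -1.0

    def test_single_class_is_undefined(self):
        adj = adjacency_table(_raster(np.full((4, 4), MF)))
        assert np.isnan(clumpy(adj, MF))
        assert np.isnan(clumpy(adj, NF))  # absent class

    def test_random_landscapes_average_near_zero(self):
        """i.i.d. placement (p = 0.3) is 'no different than random': mean ~ 0."""
        rng = np.random.default_rng(42)
        vals = []
        for _ in range(60):
            grid = np.where(rng.random((100, 100)) < 0.3, MF, NF).astype(np.int16)
            vals.append(clumpy(adjacency_table(_raster(grid)), MF))
        assert abs(np.mean(vals)) <= 0.02

    def test_solid_block_is_clumped(self):
        grid = np.full((10, 10), NF, dtype=np.int16)
        grid[2:8, 2:8] = MF
        val = clumpy(adjacency_table(_raster(grid)), MF)
        assert val > 0.9


class TestAreaWeightedMeans:
    def test_single_patch_identity(self, square_in_matrix):
        patches = label_patches(square_in_matrix)
        assert area_am(patches, MF) == pytest.approx(4 * 0.09, rel=RTOL)

    def test_two_patches_weighted(self):
        # patches of 1 ha and 3 ha -> (1 + 9) / 4 = 2.5 ha
        cell = 100.0  # 1 ha cells
        grid = np.full((5, 7), NF, dtype=np.int16)
        grid[2, 1] = MF
        grid[2, 3:6] = MF
        patches = label_patches(_raster(grid, cell_size=cell))
        assert area_am(patches, MF) == pytest.approx(2.5, rel=RTOL)

    def test_equal_patches_equal_mean(self):
        grid = np.full((5, 8), NF, dtype=np.int16)
        grid[1, 1] = grid[1, 4] = grid[3, 2] = grid[3, 6] = MF
        patches = label_patches(_raster(grid))
        assert area_am(patches, MF) == pytest.approx(0.09, rel=RTOL)

    def test_absent_class_undefined(self, square_in_matrix):
        patches = label_patches(square_in_matrix)
        assert np.isnan(area_am(patches, SF))
        assert np.isnan(shape_am(patches, SF))

    def test_shape_am_square_plus_strip(self):
        # 2x2 square (SHAPE 1, weight 1/3) + 1x8 strip (SHAPE 1.5, weight 2/3)
        grid = np.full((6, 12), NF, dtype=np.int16)
        grid[1:3, 1:3] = MF
        grid[4, 2:10] = MF
        patches = label_patches(_raster(grid))
        assert shape_am(patches, MF) == pytest.approx(1 / 3 + 1.5 * 2 / 3, rel=RTOL)

    def test_all_square_patches_give_one(self, square_in_matrix):
        patches = label_patches(square_in_matrix)
        assert shape_am(patches, MF) == pytest.approx(1.0, rel=RTOL)


class TestOracleEquivalence:
    @settings(max_examples=80, deadline=None)
    @given(st.integers(0, 2**63 - 1))
    def test_random_three_class_grids(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.choice([MF, NF, SF], size=(10, 10)).astype(np.int16)
        r = _raster(grid)
        patches = label_patches(r)
        adj = adjacency_table(r)
        glist = grid.tolist()
        for code in (MF, NF, SF):
            assert edge_density(r, code) == pytest.approx(
                edge_density_oracle(glist, code, 30.0), rel=RTOL)
            want_c = clumpy_oracle(glist, code)
            got_c = clumpy(adj, code)
            if want_c is None:
                assert np.isnan(got_c)
            else:
                assert got_c == pytest.approx(want_c, rel=RTOL)
            for got, want in ((area_am(patches, code), area_am_oracle(glist, code, 30.0)),
                              (shape_am(patches, code), shape_am_oracle(glist, code))):
                if want is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=RTOL)


class TestMetricInvariants:
    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**63 - 1))
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.choice([MF, NF, SF, 0], size=(9, 9)).astype(np.int16)
        if not (grid != 0).any():
            return
        r = _raster(grid)
        patches = label_patches(r)
        adj = adjacency_table(r)
        for code in (MF, NF, SF):
            c = clumpy(adj, code)
            assert np.isnan(c) or -1.0 <= c <= 1.0
            a = area_am(patches, code)
            sub = patches.for_class(code)
            if len(sub):
                assert sub["area_ha"].min() - 1e-12 <= a <= sub["area_ha"].max() + 1e-12
                s = shape_am(patches, code)
                assert s >= 1.0 - 1e-12
            assert edge_density(r, code) >= 0.0

    def test_carving_holes_monotone(self):
        """Isolated single-cell holes increase ED(MF), weakly decrease AREA_AM."""
        grid = np.full((12, 12), MF, dtype=np.int16)
        holes = [(2, 2), (2, 6), (5, 4), (7, 8), (9, 2), (4, 9), (9, 9), (6, 1)]
        prev_ed, prev_am = -1.0, np.inf
        for r0, c0 in holes:
            grid[r0, c0] = NF
            r = _raster(grid)
            ed = edge_density(r, MF)
            am = area_am(label_patches(r), MF)
            assert ed > prev_ed
            assert am <= prev_am + 1e-12
            prev_ed, prev_am = ed, am

    def test_cell_size_scaling(self):
        rng = np.random.default_rng(5)
        grid = rng.choice([MF, NF, SF], size=(12, 12)).astype(np.int16)
        r30, r60 = _raster(grid, cell_size=30.0), _raster(grid, cell_size=60.0)
        p30, p60 = label_patches(r30), label_patches(r60)
        a30, a60 = adjacency_table(r30), adjacency_table(r60)
        for code in (MF, NF, SF):
            assert clumpy(a30, code) == pytest.approx(clumpy(a60, code), rel=RTOL, nan_ok=True)
            assert shape_am(p30, code) == pytest.approx(shape_am(p60, code), rel=RTOL)
            assert area_am(p60, code) == pytest.approx(4 * area_am(p30, code), rel=RTOL)
            assert edge_density(r60, code) == pytest.approx(
                edge_density(r30, code) / 2, rel=RTOL)


class TestSeriesTable:
    def test_cardinality(self, clearing_series):
        from landfrag import binary_zones
        zones = binary_zones(np.indices((6, 6)).sum(axis=0) < 6)
        table = metrics_for_series(clearing_series, zones)
        assert len(table) == 3 * 2 * 3  # years x zones x classes

    def test_static_series_is_constant(self, square_in_matrix):
        import dataclasses
        series = [dataclasses.replace(square_in_matrix, year=y) for y in (2000, 2001, 2002)]
        table = metrics_for_series(series)
        by_year = table.groupby("year")[["ED", "CLUMPY", "AREA_AM", "SHAPE_AM"]]
        first = by_year.get_group(2000).reset_index(drop=True)
        for _, grp in by_year:
            np.testing.assert_array_equal(
                grp.reset_index(drop=True).to_numpy(dtype=float),
                first.to_numpy(dtype=float),
            )

    def test_clearing_event_raises_mf_edge_density(self, clearing_series):
        table = metrics_for_series(clearing_series)
        ed = table[table["class_code"] == MF].set_index("year")["ED"]
        assert ed[2001] > ed[2000]

    def test_missing_propagates_as_nan_not_zero(self, clearing_series):
        table = metrics_for_series(clearing_series)
        sf_2000 = table[(table["year"] == 2000) & (table["class_code"] == SF)]
        assert np.isnan(sf_2000["AREA_AM"].item())
        assert np.isnan(sf_2000["CLUMPY"].item())

    def test_long_format(self, clearing_series):
        table = metrics_for_series(clearing_series, site="demo")
        long = metrics_long(table)
        assert set(long.columns) == {"site", "year", "zone", "class", "metric", "value"}
        assert len(long) == 4 * len(table)
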