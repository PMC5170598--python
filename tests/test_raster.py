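import datetime as dt
import json

import numpy as np
import pytest
import tifffile

from irrimap.raster import (
    CategoricalMap,
    GridSpec,
    IrrigationMap,
    NdviStack,
    ScalarMap,
    align_to_grid,
    build_ndvic,
    read_raster,
    water_year_window,
    write_raster,
)


def make_grid(n_rows=4, n_cols=4, ps=250.0, ox=0.0, oy=1000.0, **kw):
    return GridSpec(n_rows, n_cols, ox, oy, ps, crs_id="EPSG:32643", **kw)


class TestRoundTrip:
    def test_scalar_roundtrip_preserves_values_and_grid(self, tmp_path):
        grid = make_grid()
        vals = np.arange(16, dtype=np.float32).reshape(4, 4) / 16
        path = write_raster(ScalarMap(grid, vals, units="percent"), tmp_path / "s.tif")
        back = read_raster(path)
        assert isinstance(back, ScalarMap)
        np.testing.assert_allclose(back.values, vals, atol=1e-6)
        assert back.grid.approx_equal(grid)
        assert back.units == "percent"

    def test_integer_map_roundtrip_is_exact(self, tmp_path):
        grid = make_grid()
        codes = np.array([[1, 2], [3, 4]] * 2 + [[0, 0], [0, 0]] * 0, dtype=np.int32).reshape(4, 2)
        codes = np.tile(codes, (1, 2))
        cmap = CategoricalMap(grid, codes, legend={1: "crop"}, nodata_code=-1)
        back = read_raster(write_raster(cmap, tmp_path / "c.tif"))
        np.testing.assert_array_equal(back.codes, codes)
        assert back.legend[1] == "crop"

    def test_irrigation_map_written_as_binary_integers(self, tmp_path):
        grid = make_grid()
        label = np.zeros((4, 4), dtype=np.uint8)
        label[0, :2] = 1
        path = write_raster(IrrigationMap(grid, label, "2000-01"), tmp_path / "irr.tif")
        raw = tifffile.imread(path)
        assert raw.dtype == np.uint8
        assert set(np.unique(raw)) <= {0, 1}
        back = read_raster(path)
        np.testing.assert_array_equal(back.label, label)
        assert back.water_year_label == "2000-01"

    def test_all_zero_irrigation_map_reads_back_all_zero(self, tmp_path):
        grid = make_grid()
        back = read_raster(write_raster(IrrigationMap(grid, np.zeros((4, 4))), tmp_path / "z.tif"))
        assert set(np.unique(back.label)) == {0}

    def test_nodata_sentinel_preserved_in_metadata(self, tmp_path):
        grid = make_grid(nodata=-555.0)
        vals = np.full((4, 4), -555.0, dtype=np.float32)
        vals[0, 0] = 0.5
        back = read_raster(write_raster(ScalarMap(grid, vals), tmp_path / "n.tif"))
        assert back.grid.nodata == -555.0

    def test_stack_roundtrip_keeps_band_order_and_dates(self, tmp_path):
        grid = make_grid()
        dates = [dt.date(2000, 6, 1) + dt.timedelta(days=16 * i) for i in range(23)]
        vals = np.linspace(0, 0.8, 23)[:, None, None] * np.ones((23, 4, 4))
        stack = NdviStack(grid, vals, dates, "2000-01")
        back = read_raster(write_raster(stack, tmp_path / "nd.tif"))
        assert back.n_composites == 23
        assert back.composite_start_dates == dates
        np.testing.assert_allclose(back.values, vals, atol=1e-6)

    def test_band_selection_subsets_stack(self, tmp_path):
        grid = make_grid()
        dates = [dt.date(2000, 6, 1) + dt.timedelta(days=16 * i) for i in range(5)]
        stack = NdviStack(grid, np.linspace(0.1, 0.5, 5)[:, None, None] * np.ones((5, 4, 4)), dates)
        path = write_raster(stack, tmp_path / "b.tif")
        back = read_raster(path, band_selection=[0, 2])
        assert back.n_composites == 2
        assert back.composite_start_dates == [dates[0], dates[2]]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_raster(tmp_path / "nope.tif")


def test_declared_integer_scale_factor_converts_to_float(tmp_path):
    grid = make_grid(nodata=-3000)
    data = np.full((4, 4), 8000, dtype=np.int16)
    data[0, 0] = -3000
    meta = {"kind": "scalar", "scale_factor": 0.0001, "crs_id": grid.crs_id, "nodata": -3000.0}
    tifffile.imwrite(
        tmp_path / "i.tif", data, description=json.dumps(meta),
        extratags=[(33550, "d", 3, (250.0, 250.0, 0.0)),
                   (33922, "d", 6, (0, 0, 0, 0.0, 1000.0, 0.0)),
                   (42113, "s", 0, "-3000")],
    )
    back = read_raster(tmp_path / "i.tif")
    assert back.values[1, 1] == pytest.approx(0.8)
    assert back.values[0, 0] == -3000  # nodata passes through unscaled


def test_undeclared_nodata_warns(tmp_path):
    tifffile.imwrite(tmp_path / "w.tif", np.zeros((4, 4), dtype=np.float32))
    with pytest.warns(UserWarning):
        read_raster(tmp_path / "w.tif")


class TestBuildNdvic:
    @staticmethod
    def composites(start, n, grid):
        dates = [start + dt.timedelta(days=16 * i) for i in range(n)]
        return [
            (ScalarMap(grid, np.full((grid.n_rows, grid.n_cols), 0.1 + 0.01 * i, dtype=np.float32)), d)
            for i, d in enumerate(dates)
        ]

    def test_two_calendar_years_of_composites_give_23_layer_water_year(self):
        grid = make_grid()
        comps = self.composites(dt.date(2000, 1, 1), 46, grid)
        start, end = water_year_window("2000-01")
        expected = sorted(d for _, d in comps if start <= d <= end)
        stack = build_ndvic(comps, "2000-01")
        assert stack.n_composites == len(expected) == 23
        assert stack.composite_start_dates == expected
        assert stack.composite_start_dates[0] >= dt.date(2000, 6, 1)

    def test_order_invariance_under_shuffle(self):
        grid = make_grid()
        comps = self.composites(dt.date(2000, 6, 1), 10, grid)
        shuffled = [comps[i] for i in [3, 0, 9, 5, 1, 8, 2, 7, 4, 6]]
        a = build_ndvic(comps, "2000-01")
        b = build_ndvic(shuffled, "2000-01")
        np.testing.assert_array_equal(a.values, b.values)
        assert a.composite_start_dates == b.composite_start_dates

    def test_errors_for_empty_window_duplicates_and_grid_mismatch(self):
        grid = make_grid()
        comps = self.composites(dt.date(2000, 6, 1), 3, grid)
        with pytest.raises(ValueError, match="no composites"):
            build_ndvic(comps, "2005-06")
        with pytest.raises(ValueError, match="duplicate"):
            build_ndvic(comps + [comps[0]], "2000-01")
        other = ScalarMap(make_grid(ox=99.0), np.zeros((4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="different grid"):
            build_ndvic(comps + [(other, dt.date(2000, 8, 1))], "2000-01")


class TestAlignToGrid:
    def test_identity_on_matching_grids(self):
        grid = make_grid()
        src = CategoricalMap(grid, np.arange(16, dtype=np.int32).reshape(4, 4))
        out = align_to_grid(src, grid, "majority")
        np.testing.assert_array_equal(out.codes, src.codes)

    def test_majority_vote_with_tie_to_lowest_code(self):
        fine = make_grid(n_rows=2, n_cols=2, ps=125.0, oy=250.0)
        coarse = make_grid(n_rows=1, n_cols=1, ps=250.0, oy=250.0)
        src = CategoricalMap(fine, np.array([[1, 1], [2, 3]], dtype=np.int32))
        assert align_to_grid(src, coarse, "majority").codes[0, 0] == 1
        tied = CategoricalMap(fine, np.array([[2, 2], [1, 1]], dtype=np.int32))
        assert align_to_grid(tied, coarse, "majority").codes[0, 0] == 1

    def test_scalar_mean_is_area_weighted(self):
        fine = make_grid(n_rows=2, n_cols=2, ps=125.0, oy=250.0)
        coarse = make_grid(n_rows=1, n_cols=1, ps=250.0, oy=250.0)
        src = ScalarMap(fine, np.array([[10.0, 10.0], [30.0, 30.0]], dtype=np.float32))
        assert align_to_grid(src, coarse, "mean").values[0, 0] == pytest.approx(20.0)

    def test_crs_mismatch_refused(self):
        src = ScalarMap(make_grid(), np.zeros((4, 4), dtype=np.float32))
        target = GridSpec(4, 4, 0.0, 1000.0, 250.0, crs_id="EPSG:4326")
        with pytest.raises(ValueError, match="CRS"):
            align_to_grid(src, target, "mean")

    def test_disjoint_grids_refused(self):
        src = ScalarMap(make_grid(), np.zeros((4, 4), dtype=np.float32))
        target = make_grid(ox=1e7)
        with pytest.raises(ValueError, match="overlap"):
            align_to_grid(src, target, "mean")
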