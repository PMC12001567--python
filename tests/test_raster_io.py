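import logging

import numpy as np
import pandas as pd
import pytest

import esdm
from esdm.exceptions import AlignmentError, EmptyDataError, FormatError
from esdm.raster_io import EARTH_RADIUS_KM, GridTransform, write_grid

from conftest import presences_at, stack_from_arrays


def _write_asc(path, grid, x0=0.0, yll=0.0, cell=1.0, nodata=-9999.0):
    grid = np.asarray(grid, float)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {x0}\nyllcorner {yll}\ncellsize {cell}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in grid:
            fh.write(" ".join(str(v) for v in row) + "\n")


class TestReadStack:
    def test_two_aligned_rasters(self, tmp_path):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(10, 10)), rng.normal(size=(10, 10))
        _write_asc(tmp_path / "a.asc", a)
        _write_asc(tmp_path / "b.asc", b)
        stack = esdm.read_stack([tmp_path / "a.asc", tmp_path / "b.asc"], ["a", "b"])
        assert stack.shape == (10, 10)
        assert stack.layer_names == ["a", "b"]
        np.testing.assert_array_equal(stack.layers["a"], a)

    def test_shape_mismatch_names_offending_file(self, tmp_path):
        _write_asc(tmp_path / "a.asc", np.zeros((10, 10)))
        _write_asc(tmp_path / "b.asc", np.zeros((10, 11)))
        with pytest.raises(AlignmentError, match="b.asc"):
            esdm.read_stack([tmp_path / "a.asc", tmp_path / "b.asc"], ["a", "b"])

    def test_transform_mismatch(self, tmp_path):
        _write_asc(tmp_path / "a.asc", np.zeros((5, 5)), x0=0.0)
        _write_asc(tmp_path / "b.asc", np.zeros((5, 5)), x0=3.0)
        with pytest.raises(AlignmentError, match="b.asc"):
            esdm.read_stack([tmp_path / "a.asc", tmp_path / "b.asc"], ["a", "b"])

    def test_union_nodata_mask(self, tmp_path):
        a = np.ones((4, 4))
        a[0, 0] = -9999.0
        b = np.ones((4, 4))
        _write_asc(tmp_path / "a.asc", a)
        _write_asc(tmp_path / "b.asc", b)
        stack = esdm.read_stack([tmp_path / "a.asc", tmp_path / "b.asc"], ["a", "b"])
        assert stack.nodata_mask[0, 0]
        assert stack.nodata_mask.sum() == 1
        assert np.isnan(stack.layers["b"][0, 0])  # mask applied to all layers

    def test_duplicate_layer_name_rejected(self, tmp_path):
        _write_asc(tmp_path / "a.asc", np.zeros((3, 3)))
        with pytest.raises(ValueError, match="duplicate"):
            esdm.read_stack([tmp_path / "a.asc", tmp_path / "a.asc"], ["a", "a"])

    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        grid = rng.normal(size=(7, 7))
        grid[2, 3] = np.nan
        stack = stack_from_arrays({"x": grid}, transform=GridTransform(1.5, 9.25, 0.25, 0.25))
        esdm.write_stack(stack, tmp_path)
        back = esdm.read_stack([tmp_path / "x.asc"], ["x"])
        finite = np.isfinite(grid)
        np.testing.assert_array_equal(back.layers["x"][finite], grid[finite])
        np.testing.assert_array_equal(back.nodata_mask, ~finite)
        assert back.transform.close_to(stack.transform)

    def test_malformed_header_rejected(self, tmp_path):
        (tmp_path / "bad.asc").write_text("ncols x\n1 2\n")
        with pytest.raises(FormatError):
            esdm.read_stack([tmp_path / "bad.asc"], ["bad"])


class TestOccurrences:
    def _csv(self, path, rows):
        pd.DataFrame(rows, columns=["species", "lon", "lat"]).to_csv(path, index=False)

    def test_reads_requested_species_only(self, tmp_path):
        p = tmp_path / "occ.csv"
        self._csv(p, [["A", 1, 2], ["B", 3, 4], ["A", 5, 6], ["A", 7, 8]])
        occ = esdm.read_occurrences(p, "A")
        assert occ.n_presence == 3
        occ_b = esdm.read_occurrences(p, "B")
        assert occ_b.n_presence == 1
        assert occ_b.points["x"].tolist() == [3.0]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "occ.csv"
        pd.DataFrame({"species": ["A"], "lon": [1.0]}).to_csv(p, index=False)
        with pytest.raises(FormatError, match="lat"):
            esdm.read_occurrences(p, "A")

    def test_absent_species_is_empty_set_error(self, tmp_path):
        p = tmp_path / "occ.csv"
        self._csv(p, [["A", 1, 2]])
        with pytest.raises(EmptyDataError):
            esdm.read_occurrences(p, "Z")


class TestExtractFeatures:
    def test_constant_layer_extracts_constant(self, gradient_stack):
        occ = presences_at([(500, 500), (1500, 2500), (9500, 9500), (4500, 500), (500, 9500)])
        table = esdm.extract_features(gradient_stack, occ)
        assert (table["flat"] == 7.0).all()
        assert len(table) == 5

    def test_layer_equal_to_coordinate_function_is_exact(self, gradient_stack):
        # 'grad' equals the column index: a point in column c must read c
        occ = presences_at([(2500.0, 500.0), (7500.0, 8500.0)])
        table = esdm.extract_features(gradient_stack, occ)
        assert table["grad"].tolist() == [2.0, 7.0]

    def test_boundary_point_goes_right_and_below(self, gradient_stack):
        # x=2000 is the shared edge of columns 1|2 -> column 2 (right);
        # y=5000 is the shared edge of rows 4|5 -> row 5 (below)
        occ = presences_at([(2000.0, 5000.0)])
        table = esdm.extract_features(gradient_stack, occ)
        assert table["col"].tolist() == [2]
        assert table["row"].tolist() == [5]

    def test_nodata_points_dropped_and_logged(self, caplog):
        grid = np.ones((4, 4))
        grid[0, :] = np.nan
        stack = stack_from_arrays({"v": grid})
        pts = [(500.0, 3500.0), (1500.0, 3500.0), (500.0, 500.0), (2500.0, 1500.0)]
        with caplog.at_level(logging.INFO, logger="esdm.raster_io"):
            table = esdm.extract_features(stack, presences_at(pts))
        assert len(table) == 2
        assert "2" in caplog.text

    def test_all_nodata_is_error(self):
        stack = stack_from_arrays({"v": np.full((2, 2), np.nan)})
        with pytest.raises(EmptyDataError):
            esdm.extract_features(stack, presences_at([(500.0, 500.0)]))


class TestCellArea:
    def test_projected_km_cells(self, gradient_stack):
        areas = esdm.cell_area_km2(gradient_stack)
        np.testing.assert_allclose(areas, 1.0)

    def test_geographic_equator_matches_spherical_cap(self):
        cell = 1.0 / 120.0  # 30 arc-seconds
        stack = stack_from_arrays(
            {"v": np.zeros((1, 1))}, transform=GridTransform(0.0, cell, cell, cell),
            crs="geographic",
        )
        area = esdm.cell_area_km2(stack)[0]
        # analytic spherical-cap oracle for the same band
        import math

        oracle = EARTH_RADIUS_KM**2 * math.radians(cell) * (math.sin(math.radians(cell)) - 0.0)
        np.testing.assert_allclose(area, oracle, rtol=1e-12)
        # and within 1% of the flat-earth approximation at the equator
        approx = (111.32 / 120.0) ** 2
        assert abs(area - approx) / approx < 0.01

    def test_total_area_invariant_under_layer_reorder(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
        a[1, 1] = np.nan
        t = GridTransform(30.0, 29.0, 0.01, 0.01)
        s1 = stack_from_arrays({"a": a, "b": b}, transform=t, crs="geographic")
        s2 = stack_from_arrays({"b": b, "a": a}, transform=t, crs="geographic")
        assert esdm.total_area_km2(s1) == esdm.total_area_km2(s2)

    def test_zero_cell_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GridTransform(0.0, 1.0, 0.0, 1.0)

    def test_unknown_crs_demands_override(self, gradient_stack):
        gradient_stack.crs = "EPSG:32636"
        with pytest.raises(ValueError, match="override"):
            esdm.cell_area_km2(gradient_stack)


def test_write_grid_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    grid = rng.uniform(size=(5, 5))
    grid[0, 4] = np.nan
    t = GridTransform(33.5, 28.9, 1 / 120, 1 / 120)
    write_grid(tmp_path / "g.asc", grid, t)
    back = esdm.read_stack([tmp_path / "g.asc"], ["g"])
    finite = np.isfinite(grid)
    np.testing.assert_array_equal(back.layers["g"][finite], grid[finite])
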