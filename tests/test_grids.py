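"""Grid geometry, raster I/O, occurrence ingestion and value extraction."""

import logging
import math

import numpy as np
import pytest
import tifffile

from paleosdm.grids import (
    EmptyOccurrenceError,
    EnvStack,
    GridFormatError,
    GridSpec,
    Occurrence,
    OccurrenceSet,
    Raster,
    UnsupportedGeometryError,
    extract_values,
    read_occurrences,
    read_raster,
    write_occurrences,
    write_raster,
)

from conftest import occurrences_at, random_stack


class TestGridSpec:
    def test_rejects_degenerate_geometry(self):
        with pytest.raises(ValueError):
            GridSpec(0, 3, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            GridSpec(3, 3, 0.0, 0.0, -1.0)

    def test_alignment_is_an_equivalence(self, small_spec):
        same = GridSpec(4, 5, -60.0, 2.0, 0.5, nodata_value=-1.0)
        shifted = GridSpec(4, 5, -59.5, 2.0, 0.5)
        assert small_spec.aligned_with(small_spec)
        # nodata is not part of the geometry
        assert small_spec.aligned_with(same) and same.aligned_with(small_spec)
        assert not small_spec.aligned_with(shifted)

    @pytest.mark.parametrize(
        "lon,lat,expected",
        [
            (-59.75, 1.75, (0, 0)),      # center of the NW cell
            (-60.0, 2.0, (0, 0)),        # west and north outer edges included
            (-60.0 + 1e-9, 1.75, (0, 0)),  # barely inside the west edge
            (-59.5, 1.75, (0, 1)),       # interior vertical boundary -> east cell
            (-59.75, 1.5, (1, 0)),       # interior horizontal boundary -> south cell
            (-57.5, 1.75, None),         # east outer edge excluded
            (-59.75, 0.0, None),         # south outer edge excluded
            (10.0, 50.0, None),
        ],
    )
    def test_half_open_cell_membership(self, small_spec, lon, lat, expected):
        assert small_spec.cell_of(lon, lat) == expected


class TestRasterIO:
    def test_ascii_grid_with_nodata_cell(self, tmp_path):
        text = (
            "ncols 3\nnrows 3\nxllcorner 10.0\nyllcorner 20.0\ncellsize 1.0\n"
            "NODATA_value -9999\n1 2 3\n4 -9999 6\n7 8 9\n"
        )
        path = tmp_path / "g.asc"
        path.write_text(text)
        r = read_raster(path)
        assert r.spec.n_rows == r.spec.n_cols == 3
        assert r.spec.y_origin == 23.0  # yllcorner + nrows * cellsize
        assert r.valid_mask.sum() == 8
        assert r.values[0, 2] == 3.0

    def test_roundtrip_both_formats(self, tmp_path, small_stack):
        raster = small_stack.layers[0]
        for fname in ("out.asc", "out.tif"):
            path = tmp_path / fname
            write_raster(raster, path)
            back = read_raster(path)
            assert back.spec.aligned_with(raster.spec)
            assert back.spec.nodata_value == raster.spec.nodata_value
            np.testing.assert_array_equal(back.values, raster.values)

    @pytest.mark.parametrize(
        "text,missing",
        [
            ("ncols 3\nnrows 3\nxllcorner 0\ncellsize 1\n1 2 3\n", "yllcorner"),
            ("ncols 3\nnrows 3\nxllcorner 0\nyllcorner 0\n1 2 3\n", "cellsize"),
        ],
    )
    def test_malformed_header_names_field(self, tmp_path, text, missing):
        path = tmp_path / "bad.asc"
        path.write_text(text)
        with pytest.raises(GridFormatError, match=missing):
            read_raster(path)

    def test_shape_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.asc"
        path.write_text(
            "ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 1\n"
            "NODATA_value -9999\n1 2 3\n"
        )
        with pytest.raises(GridFormatError):
            read_raster(path)

    def test_geotiff_written_by_independent_writer(self, tmp_path):
        """Values written directly with tifffile (plus the standard geo tags)
        are read back correctly, spot-checked at 10 cells."""
        rng = np.random.default_rng(11)
        values = rng.uniform(-5, 40, size=(8, 6))
        path = tmp_path / "ext.tif"
        tifffile.imwrite(
            path,
            values,
            extratags=[
                (33550, "d", 3, (0.25, 0.25, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, -70.0, 12.0, 0.0)),
                (42113, "s", 0, "-9999.0"),
            ],
        )
        r = read_raster(path)
        assert r.spec.cell_size == 0.25
        assert (r.spec.x_origin, r.spec.y_origin) == (-70.0, 12.0)
        for row, col in rng.integers(0, (8, 6), size=(10, 2)):
            assert r.values[row, col] == values[row, col]

    def test_non_square_cells_rejected(self, tmp_path):
        path = tmp_path / "aniso.tif"
        tifffile.imwrite(
            path,
            np.zeros((4, 4)),
            extratags=[
                (33550, "d", 3, (0.25, 0.5, 0.0)),
                (33922, "d", 6, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
            ],
        )
        with pytest.raises(UnsupportedGeometryError):
            read_raster(path)


class TestEnvStack:
    def test_masks_intersected_at_construction(self, small_spec):
        a = np.ones((4, 5))
        b = np.ones((4, 5))
        a[0, 0] = small_spec.nodata_value
        b[3, 4] = small_spec.nodata_value
        stack = EnvStack([Raster(small_spec, a, "a"), Raster(small_spec, b, "b")])
        for lyr in stack.layers:
            assert not lyr.valid_mask[0, 0]
            assert not lyr.valid_mask[3, 4]
        assert stack.valid_mask.sum() == 18

    def test_duplicate_names_rejected(self, small_spec):
        a = Raster(small_spec, np.ones((4, 5)), "x")
        with pytest.raises(ValueError, match="duplicate"):
            EnvStack([a, Raster(small_spec, np.ones((4, 5)), "x")])

    def test_misaligned_layers_rejected(self, small_spec):
        other = GridSpec(4, 5, -61.0, 2.0, 0.5)
        with pytest.raises(ValueError, match="aligned"):
            EnvStack(
                [
                    Raster(small_spec, np.ones((4, 5)), "a"),
                    Raster(other, np.ones((4, 5)), "b"),
                ]
            )


class TestExtractValues:
    def test_cell_center_and_edges(self, small_stack):
        spec = small_stack.spec
        lon, lat = spec.cell_center(2, 3)
        occ = occurrences_at([(lon, lat), (spec.x_origin + 1e-9, lat)])
        result = extract_values(small_stack, occ)
        assert result.rejected == []
        np.testing.assert_array_equal(
            result.sample.matrix[0],
            [small_stack.layers[0].values[2, 3], small_stack.layers[1].values[2, 3]],
        )
        # a hair inside the western edge falls in the westernmost column
        np.testing.assert_array_equal(
            result.sample.matrix[1],
            [small_stack.layers[0].values[2, 0], small_stack.layers[1].values[2, 0]],
        )

    def test_masked_and_out_of_bounds_reported_not_dropped(self, small_stack):
        spec = small_stack.spec
        masked_lonlat = spec.cell_center(1, 2)
        occ = occurrences_at([masked_lonlat, (150.0, 80.0), spec.cell_center(0, 0)])
        result = extract_values(small_stack, occ)
        assert len(result.sample) == 1
        reasons = {p.index: p.reason for p in result.rejected}
        assert reasons == {0: "masked_cell", 1: "out_of_bounds"}

    def test_matches_brute_force_on_random_points(self):
        stack = random_stack(20, 20, 3, seed=42)
        spec = stack.spec
        rng = np.random.default_rng(1)
        lons = rng.uniform(spec.x_origin, spec.x_max - 1e-9, size=50)
        lats = rng.uniform(spec.y_min + 1e-9, spec.y_origin, size=50)
        occ = occurrences_at(list(zip(lons, lats)))
        result = extract_values(stack, occ)
        # independent index arithmetic: truncate offsets from the raster origin
        kept = 0
        for i, (lon, lat) in enumerate(zip(lons, lats)):
            col = int((lon - spec.x_origin) // spec.cell_size)
            row = int((spec.y_origin - lat) // spec.cell_size)
            if not stack.valid_mask[row, col]:
                assert i in {p.index for p in result.rejected}
                continue
            expected = [lyr.values[row, col] for lyr in stack.layers]
            np.testing.assert_array_equal(result.sample.matrix[kept], expected)
            kept += 1
        assert kept == len(result.sample)

    def test_permutation_equivariance(self, small_stack):
        spec = small_stack.spec
        pts = [spec.cell_center(r, c) for r, c in [(0, 0), (2, 1), (3, 4), (0, 3)]]
        occ = occurrences_at(pts)
        base = extract_values(small_stack, occ).sample.matrix
        perm = [2, 0, 3, 1]
        shuffled = occurrences_at([pts[i] for i in perm])
        permuted = extract_values(small_stack, shuffled).sample.matrix
        np.testing.assert_array_equal(permuted, base[perm])


class TestOccurrenceIO:
    def test_three_row_table(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text(
            "species,longitude,latitude\nbee,-55.5,-3.25\nbee,-54.0,1.0\nbee,-60.0,-10.0\n"
        )
        occ = read_occurrences(path)
        assert occ.species == "bee"
        assert len(occ) == 3
        assert occ.records[0] == Occurrence(-55.5, -3.25, "")

    def test_header_order_free_and_tsv(self, tmp_path):
        csv = tmp_path / "a.csv"
        csv.write_text("species,longitude,latitude\nbee,-55.5,-3.25\n")
        tsv = tmp_path / "b.tsv"
        tsv.write_text("lat\tspecies\tlon\n-3.25\tbee\t-55.5\n")
        a, b = read_occurrences(csv), read_occurrences(tsv)
        assert a.records == b.records

    def test_out_of_range_latitude_skipped_with_log(self, tmp_path, caplog):
        path = tmp_path / "occ.csv"
        path.write_text("species,longitude,latitude\nbee,-55.5,91.0\nbee,-54.0,1.0\n")
        with caplog.at_level(logging.WARNING, logger="paleosdm.grids"):
            occ = read_occurrences(path)
        assert len(occ) == 1
        assert any("out of range" in rec.message for rec in caplog.records)

    def test_unparseable_coordinate_skipped_with_row_number(self, tmp_path, caplog):
        path = tmp_path / "occ.csv"
        path.write_text("species,longitude,latitude\nbee,xxx,1.0\nbee,-54.0,1.0\n")
        with caplog.at_level(logging.WARNING, logger="paleosdm.grids"):
            occ = read_occurrences(path)
        assert len(occ) == 1
        assert any("row 2" in rec.message for rec in caplog.records)

    def test_duplicates_retained(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text("species,lon,lat\nbee,-55.5,-3.25\nbee,-55.5,-3.25\n")
        assert len(read_occurrences(path)) == 2

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(EmptyOccurrenceError):
            read_occurrences(path)

    def test_roundtrip(self, tmp_path):
        occ = OccurrenceSet("bee", [Occurrence(-55.5, -3.25, "museum")], role="raw")
        path = tmp_path / "out.csv"
        write_occurrences(occ, path)
        assert read_occurrences(path).records == occ.records

    def test_invalid_coordinates_rejected_at_construction(self):
        with pytest.raises(ValueError, match="latitude"):
            OccurrenceSet("bee", [Occurrence(0.0, 95.0)])
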