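"""Height-map I/O, validation and leveling."""

import numpy as np
import pytest

from microwear import (
    DegeneracyError,
    FormatError,
    HeightMap,
    PARAM_ORDER,
    ValidationError,
    level_surface,
    read_height_map,
    read_parameter_table,
    write_height_map,
    write_parameter_table,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReaders:
    def test_csv_matrix_of_zeros(self, tmp_path):
        p = write(tmp_path, "z.csv", "# spacing_um=1,1\n0,0,0\n0,0,0\n0,0,0\n")
        s = read_height_map(p, "csv-matrix")
        assert s.n_valid == 9
        assert np.all(s.heights == 0)
        assert s.spacing_x == s.spacing_y == 1.0

    def test_xyz_equivalent_to_csv_matrix(self, tmp_path):
        vals = np.arange(9.0).reshape(3, 3)
        csv = write(tmp_path, "m.csv", "# spacing_um=1,1\n" + "\n".join(
            ",".join(str(v) for v in row) for row in vals))
        xyz_lines = [f"{c} {r} {vals[r, c]}" for r in range(3) for c in range(3)]
        xyz = write(tmp_path, "m.xyz", "# comment\n" + "\n".join(xyz_lines))
        a = read_height_map(csv, "csv-matrix")
        b = read_height_map(xyz, "xyz-points")
        np.testing.assert_array_equal(a.heights, b.heights)
        assert (a.spacing_x, a.spacing_y) == (b.spacing_x, b.spacing_y)

    def test_na_cell_masks_point(self, tmp_path):
        p = write(tmp_path, "na.csv", "1,2,3\n4,NA,6\n7,8,9\n")
        s = read_height_map(p, "csv-matrix")
        assert s.n_valid == 8
        assert not s.mask[1, 1]
        assert np.isnan(s.heights[1, 1])

    def test_xyz_missing_lattice_cell_is_masked(self, tmp_path):
        lines = [f"{c} {r} {r + c}" for r in range(3) for c in range(3) if (r, c) != (2, 2)]
        p = write(tmp_path, "gap.xyz", "\n".join(lines))
        s = read_height_map(p, "xyz-points")
        assert s.n_valid == 8
        assert not s.mask[2, 2]

    def test_ascii_grid_parses_header_and_na(self, tmp_path):
        p = write(tmp_path, "g.asc",
                  "ncols 3\nnrows 2\nspacing_um 0.5 0.25\n1 2 NA\n4 5 6\n")
        s = read_height_map(p, "ascii-grid")
        assert s.shape == (2, 3)
        assert (s.spacing_x, s.spacing_y) == (0.5, 0.25)
        assert s.n_valid == 5

    @pytest.mark.parametrize("fmt", ["ascii-grid", "csv-matrix", "xyz-points"])
    def test_write_read_round_trip(self, tmp_path, rng, fmt):
        z = rng.standard_normal((7, 5))
        mask = np.ones_like(z, dtype=bool)
        mask[2, 3] = False
        s = HeightMap(z, 0.35, 0.7, mask=mask)
        path = tmp_path / f"rt-{fmt}"
        write_height_map(s, path, fmt)
        back = read_height_map(path, fmt)
        np.testing.assert_array_equal(back.mask, s.mask)
        np.testing.assert_allclose(back.valid_heights, s.valid_heights, rtol=1e-11)
        assert np.isclose(back.spacing_x, s.spacing_x, rtol=1e-11)


class TestReaderErrors:
    def test_ragged_csv_names_line(self, tmp_path):
        p = write(tmp_path, "bad.csv", "1,2,3\n4,5\n")
        with pytest.raises(FormatError, match="line 2"):
            read_height_map(p, "csv-matrix")

    def test_bad_token_names_line(self, tmp_path):
        p = write(tmp_path, "bad2.csv", "1,2,3\n4,x,6\n7,8,9\n")
        with pytest.raises(FormatError, match="line 2"):
            read_height_map(p, "csv-matrix")

    def test_missing_ascii_header(self, tmp_path):
        p = write(tmp_path, "h.asc", "ncols 3\nspacing_um 1 1\n0 0 0\n")
        with pytest.raises(FormatError, match="line 2"):
            read_height_map(p, "ascii-grid")

    def test_non_positive_spacing_rejected(self, tmp_path):
        p = write(tmp_path, "sp.asc", "ncols 2\nnrows 2\nspacing_um 0 1\n0 0\n0 0\n")
        with pytest.raises(ValidationError, match="spacing"):
            read_height_map(p, "ascii-grid")

    def test_xyz_off_lattice_rejected(self, tmp_path):
        lines = ["0 0 1", "1 0 1", "2.5001 0 1", "0 1 1", "1 1 1", "2.5001 1 1"]
        p = write(tmp_path, "off.xyz", "\n".join(lines))
        with pytest.raises(ValidationError, match="lattice"):
            read_height_map(p, "xyz-points")

    def test_unknown_format(self, tmp_path):
        p = write(tmp_path, "x.csv", "0,0\n0,0\n")
        with pytest.raises(ValidationError, match="format"):
            read_height_map(p, "sur")


class TestHeightMapValidation:
    def test_too_few_valid_points(self):
        z = np.full((3, 3), np.nan)
        z[0, 0] = z[0, 1] = z[1, 0] = 1.0
        with pytest.raises(ValidationError):
            HeightMap(z, 1, 1)

    def test_negative_spacing(self):
        with pytest.raises(ValidationError):
            HeightMap(np.zeros((2, 2)), -1, 1)


class TestLeveling:
    def test_tilted_plane_levels_to_zero(self):
        yy, xx = np.mgrid[0:16, 0:16]
        s = HeightMap(0.1 * xx + 0.05 * yy + 3.0, 1, 1)
        out = level_surface(s)
        np.testing.assert_allclose(out.valid_heights, 0.0, atol=1e-9)

    def test_adding_a_plane_does_not_change_leveled_output(self, random_surface):
        yy, xx = np.mgrid[0:64, 0:64]
        plane = 0.3 * xx - 0.2 * yy + 5.0
        a = level_surface(random_surface)
        b = level_surface(random_surface.with_heights(random_surface.heights + plane))
        np.testing.assert_allclose(a.valid_heights, b.valid_heights, atol=1e-9)

    def test_idempotent(self, rng):
        for _ in range(5):
            s = HeightMap(rng.standard_normal((20, 20)), 0.5, 0.5)
            once = level_surface(s)
            twice = level_surface(once)
            np.testing.assert_allclose(once.valid_heights, twice.valid_heights, atol=1e-9)

    def test_already_level_unchanged_up_to_mean(self, rng):
        z = rng.standard_normal((12, 12))
        s = HeightMap(z - z.mean(), 1, 1)
        out = level_surface(s)
        # residual differs from input only by the (tiny) plane fitted to noise
        assert abs(out.valid_heights.mean()) < 1e-12

    def test_collinear_points_degenerate(self):
        z = np.full((3, 5), np.nan)
        z[1, :] = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(DegeneracyError, match="collinear"):
            level_surface(HeightMap(z, 1, 1))


class TestParameterTable:
    def zero_params(self):
        return {k: 0.0 for k in PARAM_ORDER}

    def test_single_zero_row(self, tmp_path):
        path = tmp_path / "p.csv"
        write_parameter_table([("sp1", "village", self.zero_params())], path)
        df = read_parameter_table(path)
        assert len(df) == 1
        assert list(df.columns[2:]) == list(PARAM_ORDER)
        assert (df.iloc[0, 2:] == 0).all()

    def test_round_trip_12_significant_digits(self, tmp_path, rng):
        vals = {k: float(v) for k, v in zip(PARAM_ORDER, rng.lognormal(size=30))}
        path = tmp_path / "rt.csv"
        write_parameter_table([("a", "g1", vals)], path)
        back = read_parameter_table(path)
        for k in PARAM_ORDER:
            assert np.isclose(back[k][0], vals[k], rtol=1e-11)

    def test_label_order_preserved(self, tmp_path):
        path = tmp_path / "two.csv"
        write_parameter_table(
            [("s1", "village", self.zero_params()), ("s2", "rainforest", self.zero_params())],
            path,
        )
        df = read_parameter_table(path)
        assert list(df["group_label"]) == ["village", "rainforest"]

    def test_inconsistent_names_rejected(self, tmp_path):
        bad = self.zero_params()
        bad.pop("Sa")
        bad["Sx"] = 1.0
        with pytest.raises(ValidationError, match="parameter names"):
            write_parameter_table([("s", "g", bad)], tmp_path / "bad.csv")
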