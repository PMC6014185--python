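import numpy as np
import pandas as pd
import pytest

from podomap import rasterops as ro
from podomap.raster import RasterGrid, RasterStack

from conftest import make_grid


class TestResampleNearest:
    def test_identity_when_grids_match(self, unit_grid):
        src = unit_grid.copy_with(np.arange(100.0).reshape(10, 10))
        out = ro.resample_nearest(src, unit_grid)
        assert np.array_equal(out.data, src.data)

    def test_upsample_replicates_blocks(self):
        src = make_grid([[1.0, 2.0], [3.0, 4.0]], cell=2.0, north=4.0)
        target = make_grid(np.zeros((4, 4)), cell=1.0, north=4.0)
        out = ro.resample_nearest(src, target)
        expected = np.repeat(np.repeat(src.data, 2, axis=0), 2, axis=1)
        assert np.array_equal(out.data, expected)

    def test_matches_exhaustive_nearest_centre_search(self):
        rng = np.random.default_rng(42)
        src = make_grid(rng.normal(size=(10, 10)), west=0.0, north=10.0, cell=1.0)
        # irrational-ish offsets avoid exact ties
        target = RasterGrid(
            data=np.zeros((8, 9)), west=1.137, north=9.421, cell=0.83,
        )
        out = ro.resample_nearest(src, target)
        sX, sY = src.cell_centers()
        scenters = np.column_stack([sX.ravel(), sY.ravel()])
        tX, tY = target.cell_centers()
        for i in range(8):
            for j in range(9):
                d2 = (scenters[:, 0] - tX[i, j]) ** 2 + (scenters[:, 1] - tY[i, j]) ** 2
                assert out.data[i, j] == src.data.ravel()[np.argmin(d2)]

    def test_disjoint_extents_error_names_bounds(self):
        src = make_grid(np.zeros((4, 4)), west=0.0, north=4.0)
        target = make_grid(np.zeros((4, 4)), west=100.0, north=4.0)
        with pytest.raises(ValueError, match="disjoint"):
            ro.resample_nearest(src, target)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        src = make_grid(rng.normal(size=(6, 6)))
        target = RasterGrid(data=np.zeros((5, 5)), west=0.31, north=5.77, cell=1.13)
        once = ro.resample_nearest(src, target)
        twice = ro.resample_nearest(once, target)
        assert np.array_equal(once.data, twice.data)

    def test_nodata_preserved(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        src = make_grid(np.ones((4, 4)), mask=mask, cell=2.0, north=8.0)
        target = make_grid(np.zeros((8, 8)), cell=1.0, north=8.0)
        out = ro.resample_nearest(src, target)
        assert out.mask[:2, :2].all()
        assert not out.mask[2:, 2:].any()


class TestEuclideanDistance:
    def test_zero_at_feature_cell_centre(self, unit_grid):
        out = ro.euclidean_distance(np.array([[2.5, 3.5]]), unit_grid)
        r, c = unit_grid.xy_to_rowcol(2.5, 3.5)
        assert out.data[r, c] == 0.0
        assert (out.data >= 0).all()

    def test_two_points_min_decomposition(self, unit_grid):
        p1, p2 = np.array([1.0, 1.0]), np.array([8.0, 9.0])
        both = ro.euclidean_distance(np.array([p1, p2]), unit_grid)
        d1 = ro.euclidean_distance(p1[None], unit_grid)
        d2 = ro.euclidean_distance(p2[None], unit_grid)
        assert np.allclose(both.data, np.minimum(d1.data, d2.data))

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(17)
        grid = make_grid(np.zeros((50, 50)))
        pts = rng.uniform(0, 50, size=(50, 2))
        out = ro.euclidean_distance(pts, grid)
        X, Y = grid.cell_centers()
        brute = np.full(grid.shape, np.inf)
        for px, py in pts:
            brute = np.minimum(brute, np.hypot(X - px, Y - py))
        assert np.allclose(out.data, brute, rtol=0, atol=1e-12)

    def test_distance_surface_is_lipschitz(self, rng):
        grid = make_grid(np.zeros((30, 30)))
        pts = rng.uniform(0, 30, size=(5, 2))
        d = ro.euclidean_distance(pts, grid)
        X, Y = grid.cell_centers()
        flat_d, fx, fy = d.data.ravel(), X.ravel(), Y.ravel()
        i = rng.integers(0, flat_d.size, 200)
        j = rng.integers(0, flat_d.size, 200)
        sep = np.hypot(fx[i] - fx[j], fy[i] - fy[j])
        assert (np.abs(flat_d[i] - flat_d[j]) <= sep + 1e-12).all()

    def test_empty_feature_set_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="at least one"):
            ro.euclidean_distance(np.empty((0, 2)), unit_grid)

    def test_degree_crs_refused(self):
        grid = RasterGrid(data=np.zeros((5, 5)), west=0, north=5, cell=1, crs="EPSG:4326")
        with pytest.raises(ValueError, match="projected CRS"):
            ro.euclidean_distance(np.array([[1.0, 1.0]]), grid)


def horn_slope_oracle(z, cell_km, z_unit_per_km=1000.0):
    """Independent per-cell loop re-implementation of the Horn operator."""
    rows, cols = z.shape
    zp = np.pad(z, 1, mode="edge") / z_unit_per_km
    out = np.empty_like(z, dtype=float)
    for r in range(rows):
        for c in range(cols):
            win = zp[r : r + 3, c : c + 3]
            dzdx = (
                (win[0, 2] + 2 * win[1, 2] + win[2, 2])
                - (win[0, 0] + 2 * win[1, 0] + win[2, 0])
            ) / (8 * cell_km)
            dzdy = (
                (win[2, 0] + 2 * win[2, 1] + win[2, 2])
                - (win[0, 0] + 2 * win[0, 1] + win[0, 2])
            ) / (8 * cell_km)
            out[r, c] = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return out


class TestSlope:
    def test_constant_elevation_flat(self):
        g = make_grid(np.full((6, 6), 321.0))
        assert np.allclose(ro.slope_degrees(g).data, 0.0)

    def test_inclined_plane_45_degrees(self):
        # z = x with z in metres and x in metres -> 45 degrees everywhere
        cell_km = 1.0
        x_m = (np.arange(8) + 0.5) * cell_km * 1000.0
        g = make_grid(np.tile(x_m, (8, 1)), cell=cell_km)
        slope = ro.slope_degrees(g).data
        assert np.allclose(slope[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_matches_independent_horn_kernel(self, rng):
        z = rng.normal(scale=50.0, size=(12, 15)).cumsum(axis=1)
        g = make_grid(z, cell=0.5, north=6.0)
        got = ro.slope_degrees(g).data
        want = horn_slope_oracle(z, 0.5)
        assert np.allclose(got, want, atol=1e-9)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="3"):
            ro.slope_degrees(make_grid(np.zeros((2, 5))))

    def test_range_is_sub_vertical(self, rng):
        g = make_grid(rng.uniform(0, 5000, size=(10, 10)))
        s = ro.slope_degrees(g).data
        assert (s >= 0).all() and (s < 90).all()


class TestExtractFeatures:
    def _stack(self):
        a = make_grid(np.arange(16.0).reshape(4, 4))
        b = make_grid(np.arange(16.0).reshape(4, 4) * 10)
        return RasterStack({"a": a, "b": b})

    def _surveys(self, rows):
        return pd.DataFrame(
            rows, columns=["community_id", "x_km", "y_km", "n_screened", "n_cases"]
        )

    def test_point_at_cell_centre_gets_cell_values(self):
        stack = self._stack()
        surveys = self._surveys([("c0", 1.5, 2.5, 100, 0)])
        out = ro.extract_features(stack, surveys)
        # (1.5, 2.5) is row 1, col 1 on a 4x4 grid with north=4
        assert out.loc[0, "a"] == stack["a"].data[1, 1]
        assert out.loc[0, "b"] == stack["b"].data[1, 1]

    def test_presence_labelling_rule(self):
        stack = self._stack()
        surveys = self._surveys(
            [("z", 0.5, 0.5, 100, 0), ("p", 1.5, 1.5, 100, 3), ("q", 2.5, 2.5, 50, 1)]
        )
        out = ro.extract_features(stack, surveys)
        assert out.set_index("community_id")["label"].to_dict() == {
            "z": 0, "p": 1, "q": 1,
        }

    def test_outside_and_nodata_points_dropped_and_counted(self):
        a = make_grid(np.ones((4, 4)))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True  # cell containing (0.5, 3.5)
        b = make_grid(np.ones((4, 4)), mask=mask)
        stack = RasterStack({"a": a, "b": b})
        surveys = self._surveys(
            [("in", 2.5, 2.5, 10, 0), ("out", 99.0, 2.5, 10, 0), ("nod", 0.5, 3.5, 10, 0)]
        )
        out = ro.extract_features(stack, surveys)
        assert list(out["community_id"]) == ["in"]
        assert out.attrs["n_dropped_outside"] == 1
        assert out.attrs["n_dropped_nodata"] == 1

    def test_permutation_equivariant(self, small_world):
        surveys = small_world["surveys"]
        stack = small_world["stack"]
        shuffled = surveys.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = ro.extract_features(stack, surveys).set_index("community_id").sort_index()
        b = ro.extract_features(stack, shuffled).set_index("community_id").sort_index()
        pd.testing.assert_frame_equal(a, b)


def test_standardize_stack_zscores_layers(small_world):
    std, consts = ro.standardize_stack(small_world["stack"])
    for name in std.names:
        vals = std[name].valid_values()
        assert vals.mean() == pytest.approx(0.0, abs=1e-10)
        assert vals.std() == pytest.approx(1.0, abs=1e-10)
    assert set(consts["layer"]) == set(std.names)
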