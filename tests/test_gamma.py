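"""Gamma engine: interpolation, analytic limits, oracle equivalence, invariants."""

import numpy as np
import pytest

from vmatqa import (
    DoseGrid,
    GammaCriteria,
    GridValidationError,
    brute_force_gamma,
    extract_plane,
    gamma_map,
    resample,
)


def _bilinear_oracle(xs, ys, values, qx, qy):
    """Independent bilinear evaluation at one query point (plain index math)."""
    i = min(np.searchsorted(xs, qx, side="right") - 1, len(xs) - 2)
    j = min(np.searchsorted(ys, qy, side="right") - 1, len(ys) - 2)
    tx = (qx - xs[i]) / (xs[i + 1] - xs[i])
    ty = (qy - ys[j]) / (ys[j + 1] - ys[j])
    return (
        values[i, j] * (1 - tx) * (1 - ty)
        + values[i + 1, j] * tx * (1 - ty)
        + values[i, j + 1] * (1 - tx) * ty
        + values[i + 1, j + 1] * tx * ty
    )


class TestResample:
    def test_reproduces_nodes_at_native_spacing(self, rng):
        grid = DoseGrid((0, 0, 0), (3, 3, 3), rng.random((6, 5, 4)))
        out = resample(grid, 3.0)
        assert np.allclose(out.values, grid.values, atol=1e-12)

    def test_linear_midpoint(self):
        grid = DoseGrid((0, 0, 0), (2, 1, 1), np.array([0.0, 2.0]).reshape(2, 1, 1))
        out = resample(grid, 1.0)
        assert out.values[1, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_bilinear(self, rng):
        values = rng.random((8, 8))
        grid = DoseGrid((0, 0, 0), (4, 4, 1), values[:, :, None])
        out = resample(grid, 1.0)
        xs, ys = grid.axis_coords(0), grid.axis_coords(1)
        for _ in range(50):
            i = rng.integers(0, out.dims[0])
            j = rng.integers(0, out.dims[1])
            qx, qy = out.origin[0] + i * 1.0, out.origin[1] + j * 1.0
            expected = _bilinear_oracle(xs, ys, values, qx, qy)
            assert abs(out.values[i, j, 0] - expected) <= 1e-12

    def test_step_beyond_extent_errors(self):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), np.zeros((3, 3, 3)))
        with pytest.raises(GridValidationError, match="extent"):
            resample(grid, 10.0)


class TestExtractPlane:
    def test_matches_direct_slice_and_restacks(self, rng):
        grid = DoseGrid((0, 0, 0), (3, 3, 3), rng.random((4, 5, 6)))
        for idx in range(grid.dims[2]):
            plane = extract_plane(grid, "z", idx)
            assert np.array_equal(plane.values[:, :, 0], grid.values[:, :, idx])
            assert plane.origin[2] == grid.origin[2] + idx * 3
        restack = np.concatenate(
            [extract_plane(grid, 2, i).values for i in range(grid.dims[2])], axis=2
        )
        assert np.array_equal(restack, grid.values)

    def test_out_of_range(self, rng):
        grid = DoseGrid((0, 0, 0), (1, 1, 1), rng.random((3, 3, 3)))
        with pytest.raises(IndexError):
            extract_plane(grid, "x", 3)

    def test_plane_through_max_contains_global_max(self, prostate_plan):
        grid, _ = prostate_plan
        k = int(np.unravel_index(np.argmax(grid.values), grid.dims)[2])
        plane = extract_plane(grid, "z", k)
        assert plane.values.max() == grid.values.max()


class TestGammaMap:
    def test_identity_pair_gamma_zero(self, small_grid_pair):
        ref, _ = small_grid_pair
        result = gamma_map(ref, ref, GammaCriteria(3, 3))
        assert result.gp == 100.0
        assert np.nanmax(result.gamma) == 0.0

    def test_uniform_offset_exactly_at_tolerance(self):
        ref = DoseGrid((0, 0, 0), (1, 1, 1), np.full((8, 8, 1), 2.00))
        ev = ref.with_values(np.full((8, 8, 1), 2.04))
        result = gamma_map(ref, ev, GammaCriteria(2, 2, normalization="local"))
        assert np.allclose(result.gamma[~result.excluded], 1.0, atol=1e-9)
        assert result.gp == 100.0  # boundary-inclusive pass rule

    def test_single_voxel_closed_form(self):
        ref = DoseGrid((0, 0, 0), (1, 1, 1), np.full((1, 1, 1), 1.00))
        ev = ref.with_values(np.full((1, 1, 1), 1.05))
        result = brute_force_gamma(ref, ev, GammaCriteria(3, 3, normalization="global"))
        assert result.gamma[0, 0, 0] == pytest.approx(0.05 / 0.03, abs=1e-12)

    def test_edge_shift_at_dta_gives_peak_gamma_one(self):
        # sigmoidal step edge displaced by exactly the DTA: the best match in
        # the steep region is the pure-distance candidate at 3 mm, gamma -> 1
        n = 80
        x = np.arange(n) * 1.0

        def edge(shift):
            return 2.0 / (1 + np.exp(-(x - 40.0 - shift) / 2.0)) + 0.2

        ref = DoseGrid((0, 0, 0), (1, 1, 1), edge(0).reshape(n, 1, 1))
        ev = ref.with_values(edge(3.0).reshape(n, 1, 1))
        result = gamma_map(ref, ev, GammaCriteria(3, 3, resample_step=0.25))
        peak = np.nanmax(result.gamma[30:50])
        assert peak == pytest.approx(1.0, abs=0.05)

    def test_geometry_mismatch_errors(self, small_grid_pair):
        ref, _ = small_grid_pair
        shifted = DoseGrid(ref.origin + 1, ref.spacing, ref.values, ref.frame_id)
        with pytest.raises(GridValidationError, match="co-registered"):
            gamma_map(ref, shifted, GammaCriteria(3, 3))

    def test_all_points_excluded_errors(self):
        # a zero reference under local normalization leaves nothing to evaluate
        ref = DoseGrid((0, 0, 0), (1, 1, 1), np.zeros((4, 4, 1)))
        ev = ref.with_values(np.ones((4, 4, 1)))
        with pytest.raises(GridValidationError, match="threshold"):
            gamma_map(ref, ev, GammaCriteria(3, 3, normalization="local"))

    def test_threshold_conservation(self, rng):
        values = rng.uniform(0, 2.0, (10, 10, 1))
        ref = DoseGrid((0, 0, 0), (3, 3, 3), values)
        ev = ref.with_values(values * 1.01)
        result = gamma_map(ref, ev, GammaCriteria(3, 3, low_dose_threshold=0.5))
        assert result.n_evaluated + result.n_excluded == ref.n_voxels
        assert result.n_excluded > 0

    def test_symmetric_shift_on_uniform_gradient(self):
        # gradient field: shifting evaluated by +s or -s gives the same gamma
        # map away from the boundary
        n = 40
        x = np.arange(n) * 1.0
        base = 1.0 + 0.05 * x
        ref = DoseGrid((0, 0, 0), (1, 1, 1), base.reshape(n, 1, 1))
        s = 2.0
        plus = ref.with_values((1.0 + 0.05 * (x - s)).reshape(n, 1, 1))
        minus = ref.with_values((1.0 + 0.05 * (x + s)).reshape(n, 1, 1))
        crit = GammaCriteria(3, 3)
        g_plus = gamma_map(ref, plus, crit).gamma
        g_minus = gamma_map(ref, minus, crit).gamma
        interior = slice(12, n - 12)
        assert np.allclose(g_plus[interior], g_minus[interior], atol=1e-9)

    def test_monotone_in_criteria(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            values = r.uniform(0.5, 2.0, (10, 10, 4))
            ref = DoseGrid((0, 0, 0), (3, 3, 3), values)
            ev = ref.with_values(values * (1 + r.normal(0, 0.02, values.shape)))
            gps = [
                gamma_map(ref, ev, GammaCriteria(t, d)).gp
                for t, d in [(1, 1), (2, 2), (3, 3)]
            ]
            assert gps[0] <= gps[1] <= gps[2]

    def test_2d_mode_stays_in_plane(self, rng):
        # out-of-plane agreement must not rescue an in-plane mismatch
        values = np.ones((8, 8, 3))
        values[:, :, 1] = 1.10  # middle plane 10% hot
        ref = DoseGrid((0, 0, 0), (3, 3, 3), np.ones((8, 8, 3)))
        ev = ref.with_values(values)
        r2d = gamma_map(ref, ev, GammaCriteria(3, 1), plane=("z", 1))
        assert r2d.gp == 0.0  # within the plane the 10% offset cannot pass
        r3d = gamma_map(ref, ev, GammaCriteria(3, 1))
        assert r3d.gp > 50.0  # in 3D the neighbouring planes match


class TestOracleEquivalence:
    @pytest.mark.parametrize("normalization", ["local", "global"])
    @pytest.mark.parametrize("dims", [(12, 12, 1), (6, 6, 5)])
    def test_matches_brute_force(self, dims, normalization):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = rng.uniform(0.5, 2.0, dims)
            ref = DoseGrid((0, 0, 0), (3, 3, 3), values)
            ev = ref.with_values(values * (1 + rng.normal(0, 0.03, dims)))
            crit = GammaCriteria(2, 2, normalization=normalization)
            fast = gamma_map(ref, ev, crit)
            slow = brute_force_gamma(ref, ev, crit)
            uncapped = ~fast.excluded & (slow.gamma < crit.search_radius_factor - 1e-9)
            assert uncapped.any()
            diff = np.abs(fast.gamma[uncapped] - slow.gamma[uncapped])
            assert diff.max() <= 1e-9
            # capped points report exactly the cap
            capped = ~fast.excluded & ~uncapped
            if capped.any():
                assert np.allclose(fast.gamma[capped], crit.search_radius_factor)

    def test_brute_force_refuses_oversized(self):
        big = DoseGrid((0, 0, 0), (3, 3, 3), np.ones((64, 64, 48)))
        with pytest.raises(ValueError, match="exceeds"):
            brute_force_gamma(big, big, GammaCriteria(3, 3))
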