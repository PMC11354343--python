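import numpy as np
import pytest

import lapthick as lt
from tests.conftest import radial_coordinates


@pytest.fixture(scope="module")
def slab_thickness(slab_grid, slab_solved):
    fieldU = lt.unit_gradient_field(slab_solved)
    return fieldU, lt.compute_thickness(fieldU)


class TestTracerConfig:
    def test_gamma_bounds(self):
        with pytest.raises(ValueError):
            lt.TracerConfig(gamma=1.5)
        with pytest.raises(ValueError):
            lt.TracerConfig(gamma=0.0)

    def test_default_max_steps_scales_with_diagonal(self):
        cfg = lt.TracerConfig()
        assert cfg.resolved_max_steps((30, 40)) == int(np.ceil(4 * 50 / 0.25))


class TestTracePath:
    def test_slab_path_lengths(self, slab_grid, slab_solved):
        fieldU = lt.unit_gradient_field(slab_solved)
        gamma_h = 0.25 * slab_grid.h
        # wall columns 3..17; positive path from col 10 exits past col 17.5
        length, status = lt.trace_path(fieldU, (20, 10), +1)
        assert status == lt.TraceStatus.OK
        assert length == pytest.approx((17.5 - 10) * 0.1, abs=gamma_h)
        length, status = lt.trace_path(fieldU, (20, 10), -1)
        assert status == lt.TraceStatus.OK
        assert length == pytest.approx((10 - 2.5) * 0.1, abs=gamma_h)

    def test_non_wall_start_rejected(self, slab_grid, slab_solved):
        fieldU = lt.unit_gradient_field(slab_solved)
        with pytest.raises(ValueError, match="WALL"):
            lt.trace_path(fieldU, (0, 0), +1)

    def test_invalid_start_gradient(self, slab_grid):
        fieldU = lt.UnitGradientField(
            n=np.zeros((2,) + slab_grid.shape),
            valid=np.zeros(slab_grid.shape, bool),
            grid=slab_grid,
        )
        length, status = lt.trace_path(fieldU, (20, 10), +1)
        assert status == lt.TraceStatus.INVALID_GRADIENT and length == 0.0

    def test_annulus_positive_path_is_radial_distance(self, ring20_thickness):
        grid, fieldU, _ = ring20_thickness
        r = radial_coordinates(grid)
        rng = np.random.default_rng(11)
        wall_idx = np.argwhere(grid.wall_mask())
        for k in rng.choice(len(wall_idx), 25, replace=False):
            idx = tuple(wall_idx[k])
            length, status = lt.trace_path(fieldU, idx, +1)
            assert status == lt.TraceStatus.OK
            assert abs(length - (3.0 - r[idx])) < 0.1


class TestComputeThickness:
    def test_slab_thickness_everywhere(self, slab_grid, slab_thickness):
        _, result = slab_thickness
        ok = result.ok_mask()
        assert ok.any()
        gamma_h = 0.25 * slab_grid.h
        dev = np.abs(result.T[ok] - 1.5)
        assert dev.max() <= 2 * gamma_h

    def test_identity_T_equals_sum_of_paths(self, ring20_thickness):
        _, _, result = ring20_thickness
        ok = result.ok_mask()
        np.testing.assert_array_equal(
            result.T[ok], (result.T_plus + result.T_minus)[ok]
        )
        assert (result.T_plus[ok] >= 0).all() and (result.T_minus[ok] >= 0).all()

    def test_ring_mean_thickness(self, ring20_thickness):
        _, _, result = ring20_thickness
        assert result.summary()["thickness_mean_mm"] == pytest.approx(1.5, abs=0.1)

    def test_streamline_consistency(self, ring20_thickness):
        # voxels on the same radial streamline measure the same thickness
        grid, _, result = ring20_thickness
        gamma_h = 0.25 * grid.h
        center = tuple(int(round(-o / grid.h)) for o in grid.origin)
        i0 = center[0]
        ok_row = [
            j for j in range(grid.shape[1])
            if result.flags[i0, j] == lt.TraceStatus.OK
        ]
        ts = result.T[i0, ok_row]
        # the +x ray through the center is one streamline
        right = [t for j, t in zip(ok_row, ts) if j > center[1]]
        assert max(right) - min(right) <= 2 * gamma_h

    def test_all_invalid_gradient_warns(self, slab_grid):
        fieldU = lt.UnitGradientField(
            n=np.zeros((2,) + slab_grid.shape),
            valid=np.zeros(slab_grid.shape, bool),
            grid=slab_grid,
        )
        with pytest.warns(UserWarning, match="traces failed"):
            result = lt.compute_thickness(fieldU)
        assert (result.flags[slab_grid.wall_mask()]
                == lt.TraceStatus.INVALID_GRADIENT).all()
        assert np.isnan(result.T[slab_grid.wall_mask()]).all()

    def test_nearest_fill_preserves_flags(self, slab_grid, slab_solved):
        fieldU = lt.unit_gradient_field(slab_solved)
        # poison one wall voxel's direction so its trace fails
        fieldU.n[:, 20, 10] = 0.0
        fieldU.valid[20, 10] = False
        result = lt.compute_thickness(fieldU)
        assert result.flags[20, 10] == lt.TraceStatus.INVALID_GRADIENT
        assert np.isfinite(result.T[20, 10])  # filled from nearest ok voxel

    def test_stride_subsampling_fills_gaps(self, slab_grid, slab_solved):
        fieldU = lt.unit_gradient_field(slab_solved)
        result = lt.compute_thickness(fieldU, lt.TracerConfig(stride=4))
        wall = slab_grid.wall_mask()
        assert np.isfinite(result.T[wall]).all()
        assert np.nanmax(np.abs(result.T[wall] - 1.5)) <= 2 * 0.25 * slab_grid.h

    def test_determinism_bit_identical(self, ring20_solved):
        _, fieldP = ring20_solved
        fieldU = lt.unit_gradient_field(fieldP)
        a = lt.compute_thickness(fieldU)
        b = lt.compute_thickness(fieldU)
        np.testing.assert_array_equal(a.T, b.T)
        np.testing.assert_array_equal(a.flags, b.flags)


class TestErrorMetrics:
    def make_result(self, grid, values):
        T = np.full(grid.shape, np.nan)
        flags = np.full(grid.shape, lt.TraceStatus.NOT_TRACED, dtype=np.uint8)
        wall = grid.wall_mask()
        T[wall] = values
        flags[wall] = lt.TraceStatus.OK
        return lt.ThicknessResult(T=T, T_plus=T / 2, T_minus=T / 2,
                                  flags=flags, grid=grid)

    def test_exact_truth_gives_zero(self, slab_grid):
        r = self.make_result(slab_grid, 1.5)
        em = lt.error_metrics(r, 1.5)
        assert em.bias == 0.0 and em.error == 0.0 and em.mad == 0.0

    def test_constant_offset(self, slab_grid):
        r = self.make_result(slab_grid, 1.6)
        em = lt.error_metrics(r, 1.5)
        assert em.bias == pytest.approx(0.1)
        assert em.error == pytest.approx(0.1)
        assert em.mad == pytest.approx(0.1)

    def test_no_ok_voxels_raises(self, slab_grid):
        r = self.make_result(slab_grid, 1.5)
        r.flags[:] = lt.TraceStatus.INVALID_GRADIENT
        with pytest.raises(ValueError, match="no successfully traced"):
            lt.error_metrics(r, 1.5)
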