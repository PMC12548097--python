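"""Sliding-window density maps, PCD, CDC, and areal foveal density."""

import numpy as np
import pytest

from fovea.cone_density import (
    ConeMosaic,
    DensityMap,
    areal_foveal_density,
    cdc,
    density_map,
    peak_cone_density,
)


def brute_force_density(mosaic, window_side_um, grid_step_um):
    """O(N·G) recount oracle: loop over nodes, count cones per window."""
    w, step = window_side_um, grid_step_um
    half = w / 2.0
    nx = int(np.floor((mosaic.roi_width_um - w) / step + 1e-9)) + 1
    ny = int(np.floor((mosaic.roi_height_um - w) / step + 1e-9)) + 1
    grid = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            cx, cy = half + j * step, half + i * step
            n = 0
            for x, y in mosaic.coords:
                if cx - half <= x < cx + half and cy - half <= y < cy + half:
                    n += 1
            grid[i, j] = n / (w / 1000.0) ** 2
    return grid


def regular_mosaic(pitch_um=5.0, roi=300.0):
    xs = np.arange(pitch_um / 2, roi, pitch_um)
    gx, gy = np.meshgrid(xs, xs)
    return ConeMosaic(np.column_stack([gx.ravel(), gy.ravel()]), roi, roi)


class TestDensityMap:
    def test_uniform_regular_grid_gives_exact_density(self):
        # window side (50) is a multiple of the pitch (5): every half-open
        # window holds exactly 10 x 10 cones regardless of phase
        mosaic = regular_mosaic(pitch_um=5.0)
        dmap = density_map(mosaic, window_side_um=50.0, grid_step_um=10.0)
        expected = 100 / 0.05**2
        assert np.allclose(dmap.grid, expected)

    def test_single_cone_counting(self):
        mosaic = ConeMosaic(np.array([[150.0, 150.0]]), 300.0, 300.0)
        dmap = density_map(mosaic, window_side_um=50.0, grid_step_um=10.0)
        covered = dmap.grid > 0
        assert np.all(dmap.grid[covered] == pytest.approx(1 / 0.05**2))
        # the cone is covered by the windows whose center is within w/2
        xs, ys = np.meshgrid(dmap.node_x_um, dmap.node_y_um)
        should = (np.abs(xs - 150.0) <= 25.0) & (np.abs(ys - 150.0) <= 25.0)
        # half-open: center exactly at +25 in x/y excludes, -25 includes
        should &= ~((xs - 150.0) == -25.0) & ~((ys - 150.0) == -25.0)
        assert covered.sum() > 0
        assert (covered == should).all()

    def test_matches_brute_force_recount(self, rng):
        for _ in range(3):
            coords = rng.random((150, 2)) * 100.0
            mosaic = ConeMosaic(coords, 100.0, 100.0)
            dmap = density_map(mosaic, window_side_um=30.0, grid_step_um=7.0)
            oracle = brute_force_density(mosaic, 30.0, 7.0)
            assert np.array_equal(dmap.grid, oracle)

    def test_count_conservation(self, rng):
        # sum over nodes of density x window area equals the total number of
        # (cone, covering window) incidences
        coords = rng.random((80, 2)) * 100.0
        mosaic = ConeMosaic(coords, 100.0, 100.0)
        dmap = density_map(mosaic, 30.0, 10.0)
        lhs = dmap.grid.sum() * 0.03**2
        incidences = 0
        for x, y in coords:
            for cx in dmap.node_x_um:
                for cy in dmap.node_y_um:
                    if cx - 15 <= x < cx + 15 and cy - 15 <= y < cy + 15:
                        incidences += 1
        assert lhs == pytest.approx(incidences)

    def test_window_larger_than_roi_rejected(self):
        mosaic = ConeMosaic(np.array([[5.0, 5.0]]), 10.0, 10.0)
        with pytest.raises(ValueError, match="window"):
            density_map(mosaic, window_side_um=10.0)

    def test_peak_recovery_against_generator(self, default_mosaic):
        mosaic, truth = default_mosaic
        dmap = density_map(mosaic)
        pcd, loc = peak_cone_density(dmap)
        assert pcd == pytest.approx(truth["peak_density"], rel=0.05)
        # peak node within one window side of the true density peak
        assert np.hypot(
            loc[0] - truth["peak_xy_um"][0], loc[1] - truth["peak_xy_um"][1]
        ) <= dmap.window_side_um


class TestMosaicValidation:
    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ConeMosaic(np.array([[1.0, 1.0], [1.0, 1.0]]), 10.0, 10.0)

    def test_near_duplicates_warn(self):
        with pytest.warns(UserWarning, match="closer than"):
            ConeMosaic(np.array([[1.0, 1.0], [1.0, 1.2]]), 10.0, 10.0)

    def test_out_of_roi_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ConeMosaic(np.array([[11.0, 1.0]]), 10.0, 10.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no cones"):
            ConeMosaic(np.empty((0, 2)), 10.0, 10.0)


class TestPeakAndCdc:
    def test_uniform_map_peak_at_center_tiebreak(self):
        dmap = DensityMap(np.full((21, 21), 5.0), 10.0, 50.0, (25.0, 25.0))
        pcd, loc = peak_cone_density(dmap)
        assert pcd == 5.0
        assert loc == (125.0, 125.0)  # node nearest the grid center

    def test_unique_maximum_location(self):
        grid = np.zeros((11, 11))
        grid[2, 8] = 7.0
        dmap = DensityMap(grid, 10.0, 50.0, (25.0, 25.0))
        _, loc = peak_cone_density(dmap)
        assert loc == (25.0 + 80.0, 25.0 + 20.0)

    def test_uniform_map_cdc_is_grid_centroid(self):
        dmap = DensityMap(np.full((11, 21), 3.0), 10.0, 50.0, (25.0, 25.0))
        met = cdc(dmap)
        assert met.contour_mask.all()
        assert met.cdc_location_um == pytest.approx((125.0, 75.0))
        assert met.cdc_density == pytest.approx(3.0)

    def test_symmetric_map_cdc_at_symmetry_center(self):
        n = 101
        x = np.arange(n) * 2.0
        gx, gy = np.meshgrid(x, x)
        grid = 1000.0 * np.exp(-((gx - 100) ** 2 + (gy - 100) ** 2) / (2 * 40.0**2))
        dmap = DensityMap(grid, 2.0, 50.0, (0.0, 0.0))
        met = cdc(dmap)
        assert met.cdc_location_um == pytest.approx((100.0, 100.0), abs=2.0)
        assert met.pcd >= met.cdc_density >= 0.8 * met.pcd - 1e-9

    def test_cdc_recovers_displaced_generator_peak(self, default_mosaic):
        mosaic, truth = default_mosaic
        met = cdc(density_map(mosaic))
        err = np.hypot(
            met.cdc_location_um[0] - truth["peak_xy_um"][0],
            met.cdc_location_um[1] - truth["peak_xy_um"][1],
        )
        assert err <= 5.0

    def test_contour_mask_contains_peak_and_is_connected(self, default_mosaic):
        from scipy import ndimage

        mosaic, _ = default_mosaic
        dmap = density_map(mosaic)
        met = cdc(dmap)
        _, ncomp = ndimage.label(met.contour_mask, structure=np.ones((3, 3)))
        assert ncomp == 1
        pj = int(round((met.pcd_location_um[0] - dmap.origin_um[0]) / dmap.grid_step_um))
        pi = int(round((met.pcd_location_um[1] - dmap.origin_um[1]) / dmap.grid_step_um))
        assert met.contour_mask[pi, pj]


class TestArealDensity:
    @staticmethod
    def _metrics_at(dmap, x, y):
        from fovea.cone_density import DensityMetrics

        return DensityMetrics(
            pcd=float(dmap.grid.max()),
            pcd_location_um=(x, y),
            cdc_location_um=(x, y),
            cdc_density=float(dmap.grid.max()),
            contour_mask=np.ones_like(dmap.grid, dtype=bool),
        )

    def test_uniform_map_with_central_cdc(self):
        dmap = DensityMap(np.full((251, 251), 7.0), 1.0, 50.0, (25.0, 25.0))
        met = self._metrics_at(dmap, 150.0, 150.0)
        width, dens = areal_foveal_density([(dmap, met)])
        assert width == pytest.approx(250.0)  # ROI extent minus window margin
        assert dens[0] == pytest.approx(7.0)

    def test_common_width_uses_minimum_margin(self):
        d1 = DensityMap(np.ones((251, 251)), 1.0, 50.0, (25.0, 25.0))
        d2 = DensityMap(np.ones((251, 251)), 1.0, 50.0, (25.0, 25.0))
        m1 = self._metrics_at(d1, 145.0, 150.0)  # margin 120 to the left edge
        m2 = self._metrics_at(d2, 125.0, 150.0)  # margin 100
        width, _ = areal_foveal_density([(d1, m1), (d2, m2)])
        assert width == pytest.approx(200.0)

    def test_cdc_on_edge_names_participant(self):
        dmap = DensityMap(np.ones((11, 11)), 1.0, 50.0, (25.0, 25.0))
        met = self._metrics_at(dmap, 25.0, 30.0)
        with pytest.raises(ValueError, match="edgy|edge"):
            areal_foveal_density([(dmap, met)], ["edgy"])

    def test_matches_generator_profile_mean(self, default_mosaic):
        """Areal density equals the analytic central-row window mean within 3%."""
        mosaic, truth = default_mosaic
        dmap = density_map(mosaic)
        met = cdc(dmap)
        width, dens = areal_foveal_density([(dmap, met)])
        h = width / 2.0
        cx, cy = met.cdc_location_um
        # oracle: the model density averaged over the sliding window footprint
        # along the CDC row (numeric integration of the generator profile)
        xs = np.linspace(cx - h, cx + h, 501)
        w = dmap.window_side_um
        off = np.linspace(-w / 2, w / 2, 41)
        vals = truth["density_fn"](
            xs[:, None, None] + off[None, :, None], cy + off[None, None, :]
        ).mean(axis=(1, 2))
        assert dens[0] == pytest.approx(float(vals.mean()), rel=0.03)
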