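"""D-OCT merging, boundary interpolation, and ONL thickness extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fovea.onl_profile import (
    BScanImage,
    BoundarySegmentation,
    ONLProfile,
    align_doct,
    extract_onl_profile,
    grader_average,
    interpolate_boundary,
    locate_foveal_center,
    merge_doct,
    onl_summaries,
    onl_thickness_profile,
)
from fovea.synthetic import LayerModel, synth_segmentation


def _scan(pixels):
    return BScanImage(pixels, axial_um_per_px=2.0, lateral_um_per_px=6.0)


class TestAlign:
    def test_identical_scans_zero_shift(self, rng):
        img = rng.random((120, 200))
        aligned, shifts, scores = align_doct([_scan(img), _scan(img.copy())])
        assert shifts == [(0, 0), (0, 0)]
        assert scores[1] == pytest.approx(1.0)

    def test_constructed_shift_recovered(self, rng):
        img = rng.random((120, 200))
        moved = np.zeros_like(img)
        moved[3:, :-2] = img[:-3, 2:]  # img shifted by (+3 rows, -2 cols)
        aligned, shifts, _ = align_doct([_scan(img), _scan(moved)])
        assert shifts[1] == (-3, 2)

    def test_noisy_triad_shifts_recovered(self, rng):
        base = rng.random((150, 300))
        # smooth structure so correlation has a well-defined peak
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(base, 3)
        def shifted(dy, dx):
            out = np.roll(np.roll(base, dy, axis=0), dx, axis=1)
            return out + 0.1 * base.std() * rng.standard_normal(base.shape)

        scans = [_scan(base), _scan(shifted(4, -6)), _scan(shifted(-5, 3))]
        _, shifts, scores = align_doct(scans)
        assert shifts[1] == (-4, 6)
        assert shifts[2] == (5, -3)
        assert min(scores) > 0.5

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            align_doct([_scan(rng.random((10, 10))), _scan(rng.random((10, 11)))])


class TestMerge:
    def test_idempotent(self, rng):
        img = rng.random((30, 40))
        assert np.array_equal(merge_doct([_scan(img), _scan(img.copy())]).pixels, img)

    @given(
        imgs=arrays(float, (3, 8, 9), elements=st.floats(0, 255, allow_nan=False))
    )
    def test_commutative_and_matches_elementwise_max(self, imgs):
        scans = [_scan(i) for i in imgs]
        out = merge_doct(scans).pixels
        assert np.array_equal(out, np.max(imgs, axis=0))
        assert np.array_equal(out, merge_doct(scans[::-1]).pixels)

    def test_monotone_in_scan_set(self, rng):
        a, b, c = (rng.random((20, 20)) for _ in range(3))
        two = merge_doct([_scan(a), _scan(b)]).pixels
        three = merge_doct([_scan(a), _scan(b), _scan(c)]).pixels
        assert (three >= two).all()

    def test_single_scan_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            merge_doct([_scan(rng.random((5, 5)))])


class TestInterpolation:
    def test_linear_between_knots_and_exact_at_knots(self):
        pts = np.array([[0.0, 10.0], [10.0, 20.0]])
        assert interpolate_boundary(pts, np.array([5.0]))[0] == 15.0
        assert interpolate_boundary(pts, np.array([10.0]))[0] == 20.0

    def test_reproduces_linear_function_exactly(self):
        x = np.linspace(0, 290, 30)
        pts = np.column_stack([x, 50 + 0.1 * x])
        q = np.linspace(0, 290, 777)
        assert np.max(np.abs(interpolate_boundary(pts, q) - (50 + 0.1 * q))) < 1e-9

    def test_no_extrapolation(self):
        pts = np.array([[0.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="outside"):
            interpolate_boundary(pts, np.array([1.5]))


def flat_segmentation(z_hfl=100.0, z_elm=130.0, axial=2.0):
    x = np.linspace(0, 1000, 30)
    b = {
        "ILM": np.column_stack([x, np.full(30, 10.0)]),
        "OPL_HFL": np.column_stack([x, np.full(30, 90.0)]),
        "HFL_ONL": np.column_stack([x, np.full(30, z_hfl)]),
        "ELM": np.column_stack([x, np.full(30, z_elm)]),
        "RPE": np.column_stack([x, np.full(30, 200.0)]),
    }
    return BoundarySegmentation(b, axial_um_per_px=axial, lateral_um_per_px=6.0)


class TestThicknessProfile:
    def test_flat_boundaries(self):
        seg = flat_segmentation()
        _, thick = onl_thickness_profile(seg)
        assert np.allclose(thick, 60.0)

    def test_common_axial_shift_invariance(self):
        seg = flat_segmentation()
        shifted = {k: v + [0.0, 1.0] for k, v in seg.boundaries.items()}
        seg2 = BoundarySegmentation(shifted, 2.0, 6.0)
        _, t1 = onl_thickness_profile(seg)
        _, t2 = onl_thickness_profile(seg2)
        assert np.allclose(t1, t2)

    def test_boundary_ordering_enforced(self):
        with pytest.raises(ValueError, match="ordering"):
            flat_segmentation(z_hfl=140.0, z_elm=130.0)

    def test_noise_free_analytic_recovery(self):
        """Reconstructed profile within 1 µm of the analytic ONL everywhere."""
        seg, truth = synth_segmentation(LayerModel(seed=0))
        x_um, thick = onl_thickness_profile(seg)
        analytic = truth["onl_fn_um"](x_um)
        sel = np.abs(x_um - truth["center_x_um"]) <= 1000
        assert np.max(np.abs(thick[sel] - analytic[sel])) < 1.0


class TestFovealCenter:
    def test_symmetric_pit_center_recovered(self):
        seg, truth = synth_segmentation(LayerModel(seed=0))
        assert locate_foveal_center(seg) == pytest.approx(truth["center_x_um"], abs=1.0)

    def test_offset_pit_center_recovered(self):
        seg, truth = synth_segmentation(LayerModel(center_offset_um=120.0, seed=2))
        assert locate_foveal_center(seg) == pytest.approx(truth["center_x_um"], abs=5.0)

    def test_monotone_thickness_warns_at_edge(self):
        x = np.linspace(0, 1000, 30)
        b = {
            "ILM": np.column_stack([x, 10.0 + 0.05 * x]),
            "RPE": np.column_stack([x, np.full(30, 200.0)]),
        }
        seg = BoundarySegmentation(b, 2.0, 6.0)
        with pytest.warns(UserWarning, match="edge"):
            locate_foveal_center(seg, search_halfwidth_um=2000.0)

    def test_noisy_center_recovery_rate(self):
        """With 1 px knot noise the center lands within 20 µm in >= 95%."""
        hits = 0
        for s in range(50):
            seg, truth = synth_segmentation(LayerModel(z_noise_px=1.0, seed=100 + s))
            c = locate_foveal_center(seg)
            hits += abs(c - truth["center_x_um"]) < 20.0
        assert hits >= 48  # 96%


class TestSummaries:
    def test_constant_profile(self):
        x = np.arange(-600.0, 601.0, 5.0)
        p = ONLProfile(x_um=x, thickness_um=np.full_like(x, 100.0), foveal_center_x_um=0)
        mx, mxx, cen = onl_summaries(p)
        assert mx == 100.0 and cen == pytest.approx(100.0)

    def test_analytic_gaussian_bump(self):
        seg, truth = synth_segmentation(LayerModel(seed=0))
        profile = extract_onl_profile(seg)
        mx, mxx, cen = onl_summaries(profile)
        assert mx == pytest.approx(truth["max_onl_um"], abs=1.0)
        assert abs(mxx) < 60.0
        assert cen == pytest.approx(truth["central_onl_mean_um"](113.5), rel=0.005)

    def test_displaced_peak_found_off_center(self):
        x = np.arange(-600.0, 601.0, 5.0)
        t = 80.0 + 20.0 * np.exp(-((x - 400.0) ** 2) / (2 * 50.0**2))
        p = ONLProfile(x_um=x, thickness_um=t, foveal_center_x_um=0)
        mx, mxx, _ = onl_summaries(p)
        assert mxx == pytest.approx(400.0, abs=5.0)
        assert mx == pytest.approx(100.0, abs=0.1)

    def test_insufficient_coverage_errors(self):
        x = np.arange(-100.0, 101.0, 5.0)
        p = ONLProfile(x_um=x, thickness_um=np.full_like(x, 50.0), foveal_center_x_um=0)
        with pytest.raises(ValueError, match="required"):
            onl_summaries(p)


class TestGraderAverage:
    def test_scalars_and_vectors(self):
        assert grader_average(100.0, 100.0) == 100.0
        assert grader_average(90.0, 110.0) == 100.0
        a = np.array([90.0, 80.0, 101.0])
        b = np.array([110.0, 90.0, 99.0])
        out = grader_average(a, b)
        assert np.array_equal(out, np.array([(x + y) / 2 for x, y in zip(a, b)]))

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            grader_average(np.ones(3), np.ones(4))
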