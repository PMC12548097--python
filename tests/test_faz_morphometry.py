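"""PICA labeling, FAZ assignment, and the fragmentation rule."""

import numpy as np
import pytest

from fovea.faz_morphometry import (
    VesselMask,
    assign_faz,
    average_angiograms,
    binarize_vessels,
    faz_area,
    label_picas,
)
from fovea.synthetic import VascModel, synth_vessel_mask


def ring_mask(n=100, r_in=10, r_out=12, center=None):
    c = (n - 1) / 2.0 if center is None else center
    x = np.arange(n)
    r = np.hypot(x[None, :] - c, x[:, None] - c)
    return (r >= r_in) & (r < r_out)


class TestAveraging:
    def test_identical_images(self, rng):
        img = rng.random((20, 20))
        assert np.allclose(average_angiograms([img, img.copy()]), img)

    def test_two_images_elementwise_mean(self, rng):
        a, b = rng.random((15, 15)), rng.random((15, 15))
        out = average_angiograms([a, b])
        oracle = np.array([[(a[i, j] + b[i, j]) / 2 for j in range(15)] for i in range(15)])
        assert np.allclose(out, oracle)

    def test_order_invariant(self, rng):
        imgs = [rng.random((10, 10)) for _ in range(4)]
        assert np.allclose(average_angiograms(imgs), average_angiograms(imgs[::-1]))

    def test_count_limits(self, rng):
        with pytest.raises(ValueError, match="2 to 10"):
            average_angiograms([rng.random((5, 5))])


class TestBinarize:
    def test_bimodal_image_recovers_mask(self, rng):
        truth = ring_mask()
        img = np.where(truth, 200.0, 20.0)
        vm = binarize_vessels(img, 10.0)
        assert np.array_equal(vm.mask, truth)

    def test_binary_passthrough(self):
        truth = ring_mask()
        vm = binarize_vessels(truth, 10.0)
        assert np.array_equal(vm.mask, truth)
        vm2 = binarize_vessels(truth.astype(np.uint8) * 255, 10.0)
        assert np.array_equal(vm2.mask, truth)

    def test_noisy_angiogram_high_agreement(self, rng):
        # capillary-bed-like vessel coverage (~35%) at SNR 5
        idx = np.arange(200)
        truth = ((idx % 5) == 0)[None, :] | ((idx % 7) == 0)[:, None]
        img = np.where(truth, 200.0, 20.0) + 36.0 * rng.standard_normal((200, 200))
        vm = binarize_vessels(img, 10.0)
        assert (vm.mask == truth).mean() >= 0.99

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="fixed"):
            binarize_vessels(np.full((10, 10), 7.0), 10.0)


class TestLabelPicas:
    def test_single_ring_interior_area(self):
        mask = ring_mask(100, 10, 12)
        k = int((~mask & (np.hypot(*np.meshgrid(np.arange(100) - 49.5,
                                                np.arange(100) - 49.5)) < 10)).sum())
        picas = label_picas(VesselMask(mask, 10.0))
        interior = [r for r in picas.regions if not r.touches_border]
        assert len(interior) == 1
        assert interior[0].area_mm2 == pytest.approx(k * (10.0 / 1000.0) ** 2)

    def test_two_disjoint_rings(self):
        m1 = ring_mask(120, 10, 12, center=30.0)
        m2 = ring_mask(120, 15, 17, center=85.0)
        picas = label_picas(VesselMask(m1 | m2, 10.0))
        interior = sorted(
            (r.area_mm2 for r in picas.regions if not r.touches_border)
        )
        a1 = np.pi * 0.1**2
        a2 = np.pi * 0.15**2
        assert interior[0] == pytest.approx(a1, rel=0.05)
        assert interior[1] == pytest.approx(a2, rel=0.05)

    def test_area_conservation(self):
        vmask, _ = synth_vessel_mask(VascModel(seed=5))
        picas = label_picas(vmask)
        px_mm2 = (vmask.um_per_px / 1000.0) ** 2
        total = sum(r.area_mm2 for r in picas.regions) + vmask.mask.sum() * px_mm2
        assert total == pytest.approx(vmask.mask.size * px_mm2, abs=1e-12)

    def test_no_enclosed_region_errors(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, :] = True  # one traversing vessel, all regions touch border
        with pytest.raises(ValueError, match="no candidate PICA"):
            label_picas(VesselMask(mask, 10.0))


def synthetic_picaset(areas_px, n=300, scale=10.0):
    """Mask with rectangular enclosed regions of the requested pixel areas."""
    mask = np.zeros((n, n), dtype=bool)
    slots = [(110, 100, 40), (155, 110, 20), (180, 140, 10)]
    for (r0, c0, h), a in zip(slots, areas_px):
        w = a // h
        assert h * w == a
        mask[r0 - 1 : r0 + h + 1, c0 - 1 : c0 + w + 1] = True
        mask[r0 : r0 + h, c0 : c0 + w] = False
    return VesselMask(mask, scale)


class TestAssignFaz:
    def test_single_central_pica(self):
        vm = VesselMask(ring_mask(300, 30, 33), 10.0)
        picas = assign_faz(label_picas(vm))
        assert not picas.fragmented
        assert picas.n_central == 1
        assert picas.faz_area_mm2 == pytest.approx(np.pi * 0.3**2, rel=0.02)

    def test_ratio_rule_fragmentation(self):
        """Central areas {0.20, 0.08, 0.01} mm²: ratios {1, 0.4, 0.05} -> fragmented."""
        vm = synthetic_picaset([2000, 800, 100])
        picas = assign_faz(label_picas(vm))
        ratios = sorted((r.ratio for r in picas.regions if r.central), reverse=True)
        assert ratios == pytest.approx([1.0, 0.4, 0.05])
        assert picas.fragmented
        assert picas.faz_area_mm2 == pytest.approx(0.20)

    def test_ratio_rule_single_faz(self):
        vm = synthetic_picaset([2000, 400, 100])  # ratios {1, 0.2, 0.05}
        picas = assign_faz(label_picas(vm))
        assert not picas.fragmented
        assert picas.faz_area_mm2 == pytest.approx(0.20)

    def test_empty_central_set_errors(self):
        vm = VesselMask(ring_mask(300, 10, 13, center=30.0), 10.0)
        with pytest.raises(ValueError, match="central"):
            assign_faz(label_picas(vm))


class TestFazArea:
    def test_circular_faz_area(self):
        """r = 300 µm circle at 10 µm/px: area within 2% of 0.2827 mm²."""
        vmask, truth = synth_vessel_mask(VascModel(faz_radius_um=300.0, seed=2))
        area, fragmented, n_central, _ = faz_area(vmask.mask, vmask.um_per_px)
        assert area == pytest.approx(np.pi * 0.3**2, rel=0.02)
        assert area == pytest.approx(truth["enclosed_area_mm2"], abs=1e-12)
        assert not fragmented

    def test_split_faz_classified_fragmented(self):
        vmask, truth = synth_vessel_mask(
            VascModel(faz_radius_um=350.0, split_proportions=(0.6, 0.4), seed=3)
        )
        area, fragmented, _, _ = faz_area(vmask.mask, vmask.um_per_px)
        assert fragmented
        assert area == pytest.approx(truth["largest_fragment_mm2"], abs=1e-12)
        fracs = np.array(truth["fragment_areas_mm2"][:2])
        fracs = fracs / fracs.sum()
        assert fracs[0] == pytest.approx(0.6, abs=0.03)

    def test_vessel_dilation_shrinks_faz(self):
        from scipy import ndimage

        vmask, _ = synth_vessel_mask(VascModel(seed=4))
        a1, *_ = faz_area(vmask.mask, vmask.um_per_px)
        dilated = ndimage.binary_dilation(vmask.mask)
        a2, *_ = faz_area(dilated, vmask.um_per_px)
        assert a2 < a1

    def test_rotation_and_reflection_invariance(self):
        vmask, _ = synth_vessel_mask(VascModel(seed=6))
        a0, *_ = faz_area(vmask.mask, vmask.um_per_px)
        for transformed in (
            np.rot90(vmask.mask).copy(),
            np.rot90(vmask.mask, 2).copy(),
            vmask.mask[::-1].copy(),
            vmask.mask[:, ::-1].copy(),
        ):
            a, *_ = faz_area(transformed, vmask.um_per_px)
            assert a == pytest.approx(a0, abs=1e-12)

    def test_classification_stable_away_from_threshold(self):
        # ratios {1, 0.4, 0.05}: dilating the second region's walls slightly
        # (perturbing its ratio by < 0.05) must not flip the flag
        vm = synthetic_picaset([2000, 800, 100])
        picas = assign_faz(label_picas(vm))
        assert picas.fragmented
        # shrink region 2 to 18 x 40 px (ratio 0.36, still above threshold)
        mask = vm.mask.copy()
        mask[155 + 18 : 155 + 20, 110:150] = True
        picas2 = assign_faz(label_picas(VesselMask(mask, 10.0)))
        assert picas2.fragmented
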