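"""FAZ assignment and fragmentation from OCTA vessel masks.

On OCT angiography the foveal avascular zone (FAZ) is the capillary-free
region at the foveal center.  Operationally it is found by labeling all
parafoveal intercapillary areas (PICAs, enclosed avascular regions between
capillaries) and assigning the largest central PICA as the FAZ.  Some eyes
show a "fragmented" FAZ — capillaries traversing what would otherwise be
one well-demarcated avascular area.  Fragmentation is classified by the
ratio of each central PICA's area to the largest central PICA: a single
ratio above 0.3 means a single FAZ; two or more ratios above 0.3 mean a
fragmented FAZ.  In either case the largest central PICA's area is
reported as the FAZ area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class VesselMask:
    """Binary capillary image (True = vessel) with isotropic pixel scale."""

    mask: np.ndarray
    um_per_px: float
    center_um: tuple[float, float] | None = None  # default: image center

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not self.mask.any() or self.mask.all():
            raise ValueError("mask must contain both vessel and non-vessel pixels")
        if self.center_um is None:
            ny, nx = self.mask.shape
            self.center_um = (
                (nx - 1) / 2.0 * self.um_per_px,
                (ny - 1) / 2.0 * self.um_per_px,
            )


@dataclass
class PicaRegion:
    """One labeled intercapillary region."""

    label: int
    area_mm2: float
    centroid_um: tuple[float, float]  # (x, y)
    touches_border: bool
    central: bool = False
    ratio: float | None = None


@dataclass
class PicaSet:
    """All PICAs of one image plus the FAZ assignment."""

    regions: list[PicaRegion]
    um_per_px: float
    center_um: tuple[float, float]
    labels: np.ndarray = field(repr=False)
    faz_label: int | None = None
    faz_area_mm2: float | None = None
    fragmented: bool | None = None

    @property
    def n_central(self) -> int:
        return sum(r.central for r in self.regions)


def average_angiograms(images: list[np.ndarray]) -> np.ndarray:
    """Pixelwise mean of 2–10 aligned angiogram repeats."""
    if not 2 <= len(images) <= 10:
        raise ValueError("expected 2 to 10 angiograms")
    arrs = [np.asarray(im, dtype=float) for im in images]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs[1:]):
        raise ValueError("angiogram dimension mismatch")
    return np.mean(arrs, axis=0)


def binarize_vessels(
    image: np.ndarray, um_per_px: float, method: str = "otsu",
    threshold: float | None = None,
    center_um: tuple[float, float] | None = None,
) -> VesselMask:
    """Vessel mask from a grayscale angiogram (Otsu or fixed threshold).

    Already-binary inputs (bool, or exactly two levels {0, max}) pass
    through unchanged.
    """
    img = np.asarray(image)
    if img.dtype == bool:
        return VesselMask(img, um_per_px, center_um)
    levels = np.unique(img)
    if len(levels) == 2 and levels[0] == 0:
        return VesselMask(img > 0, um_per_px, center_um)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    elif method == "otsu":
        if len(levels) < 2:
            raise ValueError(
                "constant image: Otsu undefined; use method='fixed' with a threshold"
            )
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(img.astype(float))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return VesselMask(img > thr, um_per_px, center_um)


def label_picas(vmask: VesselMask) -> PicaSet:
    """Label avascular regions (4-connected) and annotate area/centroid/border.

    Border-touching regions are retained but flagged; they are unbounded
    intercapillary space, never FAZ candidates.  Raises if no enclosed
    (non-border) region exists.
    """
    avasc = ~vmask.mask
    labels, n = ndimage.label(avasc, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        raise ValueError("no candidate PICA: mask has no avascular pixels")
    border_labels = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :])) | set(
        np.unique(labels[:, 0])
    ) | set(np.unique(labels[:, -1]))
    border_labels.discard(0)
    counts = np.bincount(labels.ravel())
    centroids = ndimage.center_of_mass(avasc, labels, np.arange(1, n + 1))
    px_mm2 = (vmask.um_per_px / 1000.0) ** 2
    regions = []
    for lab in range(1, n + 1):
        cy, cx = centroids[lab - 1]
        regions.append(
            PicaRegion(
                label=lab,
                area_mm2=float(counts[lab] * px_mm2),
                centroid_um=(cx * vmask.um_per_px, cy * vmask.um_per_px),
                touches_border=lab in border_labels,
            )
        )
    if all(r.touches_border for r in regions):
        raise ValueError("no candidate PICA: every avascular region touches the border")
    return PicaSet(
        regions=regions,
        um_per_px=vmask.um_per_px,
        center_um=vmask.center_um,
        labels=labels,
    )


def assign_faz(
    picas: PicaSet,
    central_radius_um: float = 500.0,
    ratio_threshold: float = 0.3,
) -> PicaSet:
    """Assign the FAZ and classify fragmentation by the PICA-ratio rule.

    Central PICAs are the non-border regions whose centroid lies within
    ``central_radius_um`` of the image center.  Ratios are each central
    area over the largest central area; the image is fragmented iff at
    least two ratios exceed ``ratio_threshold`` (strict), and the FAZ area
    is the largest central area regardless of fragmentation.
    """
    cx, cy = picas.center_um
    central = []
    for r in picas.regions:
        r.central = (not r.touches_border) and (
            (r.centroid_um[0] - cx) ** 2 + (r.centroid_um[1] - cy) ** 2
            <= central_radius_um**2
        )
        if r.central:
            central.append(r)
    if not central:
        raise ValueError(
            f"no central PICA within {central_radius_um} µm of the image center"
        )
    max_area = max(r.area_mm2 for r in central)
    n_above = 0
    faz = None
    for r in central:
        r.ratio = r.area_mm2 / max_area
        if r.ratio > ratio_threshold:
            n_above += 1
        if faz is None or r.area_mm2 > faz.area_mm2:
            faz = r
    picas.faz_label = faz.label
    picas.faz_area_mm2 = faz.area_mm2
    picas.fragmented = n_above >= 2
    return picas


def faz_area(
    mask_or_image: np.ndarray,
    um_per_px: float,
    central_radius_um: float = 500.0,
    ratio_threshold: float = 0.3,
    center_um: tuple[float, float] | None = None,
) -> tuple[float, bool, int, PicaSet]:
    """FAZ area (mm²) and fragmentation: binarize → label → assign.

    Returns ``(faz_area_mm2, fragmented, n_central_picas, picas)``.
    """
    vmask = binarize_vessels(mask_or_image, um_per_px, center_um=center_um)
    picas = assign_faz(label_picas(vmask), central_radius_um, ratio_threshold)
    return picas.faz_area_mm2, picas.fragmented, picas.n_central, picas
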