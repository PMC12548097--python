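"""Cone-mosaic density mapping and foveal density metrics.

From a table of cone photoreceptor coordinates inside a calibrated foveal
region of interest (ROI, nominally 300 x 300 µm from AOSLO montages), this
module computes:

* a sliding-window density map (cones/mm² on a regular grid of window
  centers);
* peak cone density (PCD) — the map maximum;
* the cone density centroid (CDC) — the centroid of the connected
  supra-threshold region enclosed by the isodensity contour at a fraction
  (default 80%) of PCD, a stabler foveal landmark than the PCD pixel;
* areal foveal cone density — the mean density along the horizontal row
  through the CDC over the largest square region common to a cohort of
  CDC-aligned maps.

Windows are half-open squares ``[c - w/2, c + w/2)`` so every cone is
counted by a well-defined set of windows, and only windows lying fully
inside the ROI are evaluated (no partial-window renormalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

DENSITY_CEILING = 400_000.0
"""Physical ceiling (cones/mm²) above which a density triggers a warning."""

MIN_CONE_SEPARATION_UM = 0.5
"""Cones closer than this raise a warning (likely duplicate detections)."""


@dataclass
class ConeMosaic:
    """Cone center coordinates (µm) within a rectangular ROI."""

    coords: np.ndarray  # (N, 2) array of (x, y) in µm
    roi_width_um: float = 300.0
    roi_height_um: float = 300.0
    participant_id: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (N, 2) array of (x, y) in µm")
        if len(self.coords) == 0:
            raise ValueError("mosaic contains no cones")
        x, y = self.coords[:, 0], self.coords[:, 1]
        if (x < 0).any() or (x > self.roi_width_um).any() or (y < 0).any() or (
            y > self.roi_height_um
        ).any():
            raise ValueError("cone coordinates outside the ROI bounds")
        # exact duplicates are rejected; near-duplicates only warned about
        uniq = np.unique(self.coords, axis=0)
        if len(uniq) != len(self.coords):
            raise ValueError("duplicate cone coordinates")
        if len(self.coords) > 1:
            from scipy.spatial import cKDTree

            d, _ = cKDTree(self.coords).query(self.coords, k=2)
            if (d[:, 1] < MIN_CONE_SEPARATION_UM).any():
                warnings.warn(
                    f"cone pairs closer than {MIN_CONE_SEPARATION_UM} µm detected",
                    stacklevel=2,
                )

    @property
    def n_cones(self) -> int:
        return len(self.coords)


@dataclass
class DensityMap:
    """Gridded cone density (cones/mm²) with its sampling geometry.

    Grid node ``(i, j)`` sits at physical position
    ``(origin_um[0] + j * grid_step_um, origin_um[1] + i * grid_step_um)``.
    """

    grid: np.ndarray
    grid_step_um: float
    window_side_um: float
    origin_um: tuple[float, float]

    @property
    def node_x_um(self) -> np.ndarray:
        return self.origin_um[0] + np.arange(self.grid.shape[1]) * self.grid_step_um

    @property
    def node_y_um(self) -> np.ndarray:
        return self.origin_um[1] + np.arange(self.grid.shape[0]) * self.grid_step_um

    def interpolate(self, x_um, y_um) -> np.ndarray:
        """Bilinear interpolation of the map at physical positions (µm)."""
        interp = RegularGridInterpolator(
            (self.node_y_um, self.node_x_um), self.grid, method="linear"
        )
        pts = np.column_stack([np.atleast_1d(y_um), np.atleast_1d(x_um)])
        return interp(pts)


@dataclass
class DensityMetrics:
    """PCD / CDC metrics derived from one density map."""

    pcd: float
    pcd_location_um: tuple[float, float]
    cdc_location_um: tuple[float, float]
    cdc_density: float
    contour_mask: np.ndarray = field(repr=False)


def density_map(
    mosaic: ConeMosaic, window_side_um: float = 50.0, grid_step_um: float = 1.0
) -> DensityMap:
    """Sliding-window cone density map.

    Each grid node is the center of a half-open square window
    ``[c - w/2, c + w/2)``; its value is the cone count in the window
    divided by the window area in mm².  Nodes are laid out so windows are
    fully interior to the ROI.
    """
    w = float(window_side_um)
    step = float(grid_step_um)
    if w >= min(mosaic.roi_width_um, mosaic.roi_height_um):
        raise ValueError(
            f"window_side_um={w} must be smaller than the ROI "
            f"({mosaic.roi_width_um} x {mosaic.roi_height_um} µm)"
        )
    if step > w:
        raise ValueError("grid_step_um must not exceed window_side_um")
    half = w / 2.0
    nx = int(np.floor((mosaic.roi_width_um - w) / step + 1e-9)) + 1
    ny = int(np.floor((mosaic.roi_height_um - w) / step + 1e-9)) + 1
    node_x = half + np.arange(nx) * step
    node_y = half + np.arange(ny) * step

    order = np.argsort(mosaic.coords[:, 1], kind="stable")
    xs_by_y = mosaic.coords[order, 0]
    ys_sorted = mosaic.coords[order, 1]

    area_mm2 = (w / 1000.0) ** 2
    grid = np.empty((ny, nx), dtype=float)
    x_lo = node_x - half
    x_hi = node_x + half
    for i, yc in enumerate(node_y):
        lo = np.searchsorted(ys_sorted, yc - half, side="left")
        hi = np.searchsorted(ys_sorted, yc + half, side="left")
        row_x = np.sort(xs_by_y[lo:hi])
        grid[i] = (
            np.searchsorted(row_x, x_hi, side="left")
            - np.searchsorted(row_x, x_lo, side="left")
        ) / area_mm2

    if (grid > DENSITY_CEILING).any():
        warnings.warn(
            f"density values exceed {DENSITY_CEILING:.0f} cones/mm² "
            "(physically implausible)",
            stacklevel=2,
        )
    return DensityMap(grid=grid, grid_step_um=step, window_side_um=w, origin_um=(half, half))


def peak_cone_density(dmap: DensityMap) -> tuple[float, tuple[float, float]]:
    """Map maximum (PCD) and its node position (µm).

    Plateau ties are broken by the node closest to the grid center (which
    coincides with the ROI center for a symmetric layout), then row-major.
    """
    grid = dmap.grid
    if grid.size == 0:
        raise ValueError("empty density map")
    pcd = float(grid.max())
    ii, jj = np.nonzero(grid == pcd)
    cx = dmap.origin_um[0] + (grid.shape[1] - 1) * dmap.grid_step_um / 2.0
    cy = dmap.origin_um[1] + (grid.shape[0] - 1) * dmap.grid_step_um / 2.0
    xs = dmap.origin_um[0] + jj * dmap.grid_step_um
    ys = dmap.origin_um[1] + ii * dmap.grid_step_um
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    # ties on distance resolved row-major: nonzero already yields row-major
    # order, and argmin returns the first minimum
    k = int(np.argmin(d2))
    return pcd, (float(xs[k]), float(ys[k]))


def cdc(dmap: DensityMap, fraction: float = 0.8, weighted: bool = True) -> DensityMetrics:
    """Cone density centroid from the isodensity contour at ``fraction * PCD``.

    The supra-threshold region is the 8-connected component of
    ``grid >= fraction * PCD`` that contains the PCD node; the CDC is its
    density-weighted centroid (unweighted when ``weighted=False``) and
    ``cdc_density`` is the map bilinearly interpolated at the CDC.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    pcd, pcd_loc = peak_cone_density(dmap)
    thresh = fraction * pcd
    above = dmap.grid >= thresh
    labels, _ = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    pj = int(round((pcd_loc[0] - dmap.origin_um[0]) / dmap.grid_step_um))
    pi = int(round((pcd_loc[1] - dmap.origin_um[1]) / dmap.grid_step_um))
    mask = labels == labels[pi, pj]
    if mask.sum() == 1:
        warnings.warn("degenerate supra-threshold region (single node)", stacklevel=2)
        cdc_xy = pcd_loc
        cdc_val = pcd
    else:
        ii, jj = np.nonzero(mask)
        wts = dmap.grid[ii, jj] if weighted else np.ones(len(ii))
        xs = dmap.origin_um[0] + jj * dmap.grid_step_um
        ys = dmap.origin_um[1] + ii * dmap.grid_step_um
        cdc_xy = (float(np.average(xs, weights=wts)), float(np.average(ys, weights=wts)))
        cdc_val = float(dmap.interpolate(cdc_xy[0], cdc_xy[1])[0])
    return DensityMetrics(
        pcd=pcd,
        pcd_location_um=pcd_loc,
        cdc_location_um=cdc_xy,
        cdc_density=cdc_val,
        contour_mask=mask,
    )


def areal_foveal_density(
    maps: list[tuple[DensityMap, DensityMetrics]],
    participant_ids: list[str] | None = None,
) -> tuple[float, np.ndarray]:
    """Cohort-common areal foveal cone density.

    All maps are notionally aligned at their CDC; the common half-width
    ``h`` is the smallest distance from any map's CDC to any of its grid
    edges.  For each map the horizontal row through the CDC is bilinearly
    sampled at the map's grid step over ``[CDC_x - h, CDC_x + h]`` and
    averaged.

    Returns
    -------
    (common_width_um, areal_densities)
        ``common_width_um = 2 h`` and one mean density per map.
    """
    if len(maps) == 0:
        raise ValueError("need at least one density map")
    ids = participant_ids or [f"map{i}" for i in range(len(maps))]
    margins = []
    for pid, (dmap, met) in zip(ids, maps):
        cx, cy = met.cdc_location_um
        x0, x1 = dmap.node_x_um[0], dmap.node_x_um[-1]
        y0, y1 = dmap.node_y_um[0], dmap.node_y_um[-1]
        m = min(cx - x0, x1 - cx, cy - y0, y1 - cy)
        if m <= 0:
            raise ValueError(f"CDC of participant {pid!r} lies on a grid edge")
        margins.append(m)
    h = float(min(margins))
    out = np.empty(len(maps))
    for k, (dmap, met) in enumerate(maps):
        cx, cy = met.cdc_location_um
        n = int(np.floor(h / dmap.grid_step_um))
        offs = np.arange(-n, n + 1) * dmap.grid_step_um
        out[k] = float(np.mean(dmap.interpolate(cx + offs, np.full_like(offs, cy))))
    return 2.0 * h, out
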