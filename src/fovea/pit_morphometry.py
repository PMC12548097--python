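"""Foveal pit diameter and volume from ILM–RPE thickness maps.

The foveal pit is the central depression of the inner retina.  Given a
gridded ILM–RPE retinal thickness map (nominally 512 x 128 samples over an
axial-length-corrected 6 x 6 mm macular cube), the pit is characterized by
a rim-based radial procedure:

1. the pit center is the (sub-pixel refined) thickness minimum near the
   map center;
2. thickness is resampled along radial spokes in physical µm coordinates
   (per-axis scales handle the 4x anisotropic Cirrus sampling);
3. on each spoke the rim is the first prominent local maximum moving
   outward (global maximum as fallback);
4. diameter is the mean rim-to-rim extent over opposed spoke pairs, and
   volume integrates the depth below a per-angle rim-height cap over all
   pixels inside the rim contour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks


@dataclass
class ThicknessMap:
    """Gridded ILM–RPE thickness (µm) with per-axis lateral sampling."""

    grid: np.ndarray
    x_um_per_px: float
    y_um_per_px: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if self.x_um_per_px <= 0 or self.y_um_per_px <= 0:
            raise ValueError("pixel scales must be positive")
        if (self.grid <= 0).any():
            raise ValueError("thickness must be positive everywhere")

    @property
    def x_um(self) -> np.ndarray:
        return np.arange(self.grid.shape[1]) * self.x_um_per_px

    @property
    def y_um(self) -> np.ndarray:
        return np.arange(self.grid.shape[0]) * self.y_um_per_px

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.y_um, self.x_um), self.grid, method="linear",
            bounds_error=False, fill_value=np.nan,
        )


@dataclass
class PitMetrics:
    """Rim-based pit morphometry for one thickness map."""

    center_um: tuple[float, float]
    angles_rad: np.ndarray
    rim_radius_um: np.ndarray
    rim_height_um: np.ndarray
    diameter_mm: float
    volume_mm3: float
    depth_um: float
    n_valid_pairs: int


def find_pit_center(
    tmap: ThicknessMap, search_radius_um: float = 750.0, smooth_um: float = 25.0
) -> tuple[float, float]:
    """Pit center (x, y in µm): refined thickness minimum near map center.

    Searches within ``search_radius_um`` of the geometric map center on a
    lightly Gaussian-smoothed copy of the map (``smooth_um``; thickness
    maps are physically smooth, so this suppresses pixel noise without
    moving the minimum of a symmetric pit).  Ties are broken by distance
    to the geometric center, then each axis is refined by a quadratic fit
    through the minimum and its two neighbors (clamped to ±1 pixel).
    """
    ny, nx = tmap.grid.shape
    gx = (nx - 1) / 2.0 * tmap.x_um_per_px
    gy = (ny - 1) / 2.0 * tmap.y_um_per_px
    work = tmap.grid
    if smooth_um > 0:
        from scipy.ndimage import gaussian_filter

        work = gaussian_filter(
            tmap.grid,
            sigma=(smooth_um / tmap.y_um_per_px, smooth_um / tmap.x_um_per_px),
            mode="nearest",
        )
    X, Y = np.meshgrid(tmap.x_um, tmap.y_um)
    d2 = (X - gx) ** 2 + (Y - gy) ** 2
    inside = d2 <= search_radius_um**2
    if not inside.any():
        raise ValueError("search region lies outside the map")
    vals = np.where(inside, work, np.inf)
    vmin = vals.min()
    ties = vals <= vmin + 1e-12
    if ties.sum() > 1:
        warnings.warn("tied thickness minima; taking the most central", stacklevel=2)
    k = int(np.argmin(np.where(ties, d2, np.inf)))
    i, j = np.unravel_index(k, vals.shape)
    # warn if the minimum hugs the search boundary
    if d2[i, j] > (search_radius_um - max(tmap.x_um_per_px, tmap.y_um_per_px)) ** 2:
        warnings.warn("pit minimum on the search boundary", stacklevel=2)

    def refine(idx: int, line: np.ndarray) -> float:
        if idx == 0 or idx == len(line) - 1:
            return 0.0
        f0, f1, f2 = line[idx - 1], line[idx], line[idx + 1]
        denom = f0 - 2 * f1 + f2
        if denom <= 0:
            return 0.0
        return float(np.clip(0.5 * (f0 - f2) / denom, -1.0, 1.0))

    dx = refine(j, work[i, :])
    dy = refine(i, work[:, j])
    return ((j + dx) * tmap.x_um_per_px, (i + dy) * tmap.y_um_per_px)


def radial_profiles(
    tmap: ThicknessMap,
    center_um: tuple[float, float],
    n_angles: int = 180,
    radial_step_um: float = 10.0,
    max_radius_um: float = 3000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thickness resampled along radial spokes from the pit center.

    Returns ``(angles, radii, profiles)`` with ``profiles[k, j]`` the
    bilinearly interpolated thickness at
    ``center + radii[j] * (cos angles[k], sin angles[k])``; samples outside
    the map are NaN.
    """
    if n_angles < 4 or n_angles % 2:
        raise ValueError("n_angles must be even and >= 4 for opposed pairs")
    angles = np.arange(n_angles) * (2 * np.pi / n_angles)
    radii = np.arange(0.0, max_radius_um + 1e-9, radial_step_um)
    interp = tmap.interpolator()
    cx, cy = center_um
    xs = cx + np.outer(np.cos(angles), radii)
    ys = cy + np.outer(np.sin(angles), radii)
    profiles = interp(np.stack([ys.ravel(), xs.ravel()], axis=-1)).reshape(xs.shape)
    return angles, radii, profiles


def detect_rim(
    profile: np.ndarray,
    radii: np.ndarray,
    smooth_halfwidth: int = 2,
    prominence_um: float = 2.0,
) -> tuple[float, float, bool]:
    """Rim radius and height (µm) on one radial profile.

    After moving-average smoothing (window ``2*smooth_halfwidth + 1``), the
    rim is the first local maximum with the required prominence moving
    outward; without one, the global maximum is used and flagged.  Radius
    and height are refined by a quadratic fit through the peak.

    Returns ``(rim_radius_um, rim_height_um, used_fallback)``.
    """
    valid = np.isfinite(profile)
    if valid.sum() < 5:
        raise ValueError("fewer than 5 valid samples on the radial profile")
    p = profile[valid]
    r = radii[valid]
    sm = uniform_filter1d(p, size=2 * smooth_halfwidth + 1, mode="nearest")
    peaks, _ = find_peaks(sm, prominence=prominence_um)
    fallback = len(peaks) == 0
    idx = int(np.argmax(sm)) if fallback else int(peaks[0])
    # quadratic sub-sample refinement on the smoothed profile
    if 0 < idx < len(sm) - 1:
        f0, f1, f2 = sm[idx - 1], sm[idx], sm[idx + 1]
        denom = f0 - 2 * f1 + f2
        d = 0.5 * (f0 - f2) / denom if denom < 0 else 0.0
        d = float(np.clip(d, -1.0, 1.0))
        rim_r = float(np.interp(idx + d, np.arange(len(r)), r))
        rim_h = float(f1 - 0.25 * (f0 - f2) * d)
    else:
        rim_r = float(r[idx])
        rim_h = float(sm[idx])
    return rim_r, rim_h, fallback


def pit_diameter(
    angles_rad: np.ndarray, rim_radius_um: np.ndarray
) -> tuple[float, int]:
    """Mean rim-to-rim extent (mm) over opposed spoke pairs.

    Pairs with any non-finite member are dropped (count reported); fewer
    than 2 valid pairs raise.
    """
    n = len(angles_rad)
    half = n // 2
    sums = rim_radius_um[:half] + rim_radius_um[half:]
    ok = np.isfinite(sums)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 valid opposed rim pairs")
    return float(np.mean(sums[ok]) / 1000.0), int(ok.sum())


def pit_volume(
    tmap: ThicknessMap,
    center_um: tuple[float, float],
    angles_rad: np.ndarray,
    rim_radius_um: np.ndarray,
    rim_height_um: np.ndarray,
) -> float:
    """Pit volume (mm³): depth below the per-angle rim cap, inside the rim.

    The rim radius and height are interpolated periodically in angle; every
    map pixel with ``r < rim_radius(theta)`` contributes
    ``max(0, rim_height(theta) - thickness) * pixel_area``.
    """
    ok = np.isfinite(rim_radius_um) & np.isfinite(rim_height_um)
    if ok.sum() < 2:
        raise ValueError("need >= 2 valid rim samples")
    ang = angles_rad[ok]
    rad = rim_radius_um[ok]
    hgt = rim_height_um[ok]
    # periodic extension for wraparound interpolation
    ang_ext = np.concatenate([ang, [ang[0] + 2 * np.pi]])
    rad_ext = np.concatenate([rad, [rad[0]]])
    hgt_ext = np.concatenate([hgt, [hgt[0]]])

    X, Y = np.meshgrid(tmap.x_um, tmap.y_um)
    dx = X - center_um[0]
    dy = Y - center_um[1]
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    # shift below ang[0] up by 2 pi into the extended span
    theta = np.where(theta < ang_ext[0], theta + 2 * np.pi, theta)
    rim_r = np.interp(theta, ang_ext, rad_ext)
    rim_h = np.interp(theta, ang_ext, hgt_ext)
    inside = r < rim_r
    depth = np.clip(rim_h - tmap.grid, 0.0, None)
    px_area_um2 = tmap.x_um_per_px * tmap.y_um_per_px
    return float((depth[inside]).sum() * px_area_um2 / 1e9)


def pit_metrics(
    tmap: ThicknessMap,
    search_radius_um: float = 750.0,
    n_angles: int = 180,
    radial_step_um: float = 10.0,
    max_radius_um: float = 3000.0,
    smooth_halfwidth: int = 2,
    prominence_um: float = 2.0,
) -> PitMetrics:
    """Full rim-based pit morphometry for one thickness map."""
    center = find_pit_center(tmap, search_radius_um)
    angles, radii, profiles = radial_profiles(
        tmap, center, n_angles, radial_step_um, max_radius_um
    )
    rim_r = np.full(n_angles, np.nan)
    rim_h = np.full(n_angles, np.nan)
    for k in range(n_angles):
        try:
            rim_r[k], rim_h[k], _ = detect_rim(
                profiles[k], radii, smooth_halfwidth, prominence_um
            )
        except ValueError:
            continue
    diameter, n_pairs = pit_diameter(angles, rim_r)
    volume = pit_volume(tmap, center, angles, rim_r, rim_h)
    t_center = float(tmap.interpolator()((center[1], center[0])))
    depth = float(np.nanmean(rim_h) - t_center)
    return PitMetrics(
        center_um=center,
        angles_rad=angles,
        rim_radius_um=rim_r,
        rim_height_um=rim_h,
        diameter_mm=diameter,
        volume_mm3=volume,
        depth_um=depth,
        n_valid_pairs=n_pairs,
    )
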