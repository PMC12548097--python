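"""Format readers and writers for every pipeline input/output class.

All formats are plain text or standard imaging formats:

* cone coordinates — CSV with header ``x_um,y_um``;
* boundary segmentations — CSV ``boundary,x_px,z_px`` plus a JSON sidecar
  with pixel scales (lateral scale is axial-length-corrected on read);
* thickness maps — 32-bit float TIFF or CSV grid plus JSON sidecar with
  per-axis scales;
* vessel masks — PNG/TIFF plus JSON sidecar with the isotropic scale;
* cohort tables and results — CSV / JSON.

Writers use fixed float formatting so repeated runs with identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .cone_density import ConeMosaic, DensityMap
from .faz_morphometry import VesselMask
from .onl_profile import BOUNDARY_NAMES, BoundarySegmentation
from .pit_morphometry import ThicknessMap

FLOAT_FMT = "%.6f"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_sidecar(path: Path, required: tuple[str, ...]) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"sidecar {sc} missing; provide the scale metadata "
            f"(required keys: {', '.join(required)})"
        )
    with open(sc) as fh:
        meta = json.load(fh)
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sc} missing keys: {missing}")
    return meta


# -- cone coordinates -------------------------------------------------------


def read_cone_coords(
    path: str | Path,
    roi_width_um: float = 300.0,
    roi_height_um: float = 300.0,
    participant_id: str | None = None,
) -> ConeMosaic:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns x_um,y_um")
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at line {bad[0] + 2}")
    return ConeMosaic(
        coords=df[["x_um", "y_um"]].to_numpy(dtype=float),
        roi_width_um=roi_width_um,
        roi_height_um=roi_height_um,
        participant_id=participant_id or path.stem,
    )


def write_cone_coords(mosaic: ConeMosaic, path: str | Path) -> None:
    df = pd.DataFrame(mosaic.coords, columns=["x_um", "y_um"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# -- boundary segmentations -------------------------------------------------


def read_segmentation(path: str | Path) -> BoundarySegmentation:
    """Read segmentation CSV + JSON sidecar; corrects the lateral scale.

    The sidecar must carry ``axial_um_per_px`` and ``lateral_um_per_px``
    (device-nominal); when ``axial_length_mm`` is present the lateral scale
    is multiplied by ``axial_length / device_assumed_axial``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("boundary", "x_px", "z_px"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns boundary,x_px,z_px")
    unknown = set(df["boundary"]) - set(BOUNDARY_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown boundary names {sorted(unknown)}")
    meta = _read_sidecar(path, ("axial_um_per_px", "lateral_um_per_px"))
    lateral = float(meta["lateral_um_per_px"])
    if "axial_length_mm" in meta:
        assumed = float(meta.get("device_assumed_axial_mm", geometry.DEVICE_ASSUMED_AXIAL_MM))
        nominal = float(meta.get("nominal_length_mm", 1.0))
        lateral *= (
            geometry.correct_lateral_scale(nominal, float(meta["axial_length_mm"]), assumed)
            / nominal
        )
    boundaries = {
        name: grp[["x_px", "z_px"]].to_numpy(dtype=float)
        for name, grp in df.groupby("boundary", sort=False)
    }
    return BoundarySegmentation(
        boundaries=boundaries,
        axial_um_per_px=float(meta["axial_um_per_px"]),
        lateral_um_per_px=lateral,
    )


def write_segmentation(
    seg: BoundarySegmentation, path: str | Path, sidecar_extra: dict | None = None
) -> None:
    path = Path(path)
    rows = []
    for name in BOUNDARY_NAMES:
        if name not in seg.boundaries:
            continue
        for x, z in seg.boundaries[name]:
            rows.append({"boundary": name, "x_px": x, "z_px": z})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {
        "axial_um_per_px": seg.axial_um_per_px,
        "lateral_um_per_px": seg.lateral_um_per_px,
    }
    meta.update(sidecar_extra or {})
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- thickness maps ---------------------------------------------------------


def read_thickness_map(path: str | Path) -> ThicknessMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        grid = tifffile.imread(path).astype(float)
    else:
        grid = np.loadtxt(path, delimiter=",")
    meta = _read_sidecar(path, ())
    if "x_um_per_px" in meta and "y_um_per_px" in meta:
        xs, ys = float(meta["x_um_per_px"]), float(meta["y_um_per_px"])
    elif "nominal_mm" in meta and "axial_length_mm" in meta:
        corr = geometry.correct_lateral_scale(
            float(meta["nominal_mm"]), float(meta["axial_length_mm"])
        )
        ys, xs = (
            geometry.um_per_pixel(corr, grid.shape[0]),
            geometry.um_per_pixel(corr, grid.shape[1]),
        )
    else:
        raise ValueError(
            f"sidecar for {path} needs x_um_per_px/y_um_per_px or "
            "nominal_mm/axial_length_mm"
        )
    return ThicknessMap(grid=grid, x_um_per_px=xs, y_um_per_px=ys)


def write_thickness_map(tmap: ThicknessMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, tmap.grid.astype(np.float32))
    else:
        np.savetxt(path, tmap.grid, delimiter=",", fmt=FLOAT_FMT)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {"x_um_per_px": tmap.x_um_per_px, "y_um_per_px": tmap.y_um_per_px},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


# -- vessel masks -----------------------------------------------------------


def read_vessel_mask(path: str | Path, um_per_px: float | None = None) -> VesselMask:
    path = Path(path)
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    if um_per_px is None:
        meta = _read_sidecar(path, ("um_per_px",))
        um_per_px = float(meta["um_per_px"])
    return VesselMask(mask=img > 0, um_per_px=um_per_px)


def write_vessel_mask(vmask: VesselMask, path: str | Path) -> None:
    path = Path(path)
    import imageio.v3 as iio

    iio.imwrite(path, (vmask.mask.astype(np.uint8) * 255))
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"um_per_px": vmask.um_per_px}, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- density maps -----------------------------------------------------------


def write_density_map(dmap: DensityMap, path: str | Path) -> None:
    """Density map as 32-bit float TIFF (cones/mm²) + geometry sidecar."""
    path = Path(path)
    import tifffile

    tifffile.imwrite(path, dmap.grid.astype(np.float32))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(
            {
                "grid_step_um": dmap.grid_step_um,
                "window_side_um": dmap.window_side_um,
                "origin_um": list(dmap.origin_um),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_density_map(path: str | Path) -> DensityMap:
    path = Path(path)
    import tifffile

    grid = tifffile.imread(path).astype(float)
    meta = _read_sidecar(path, ("grid_step_um", "window_side_um", "origin_um"))
    return DensityMap(
        grid=grid,
        grid_step_um=float(meta["grid_step_um"]),
        window_side_um=float(meta["window_side_um"]),
        origin_um=tuple(meta["origin_um"]),
    )


# -- cohort tables and results ----------------------------------------------


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_results_json(results: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
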