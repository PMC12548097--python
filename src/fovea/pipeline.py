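"""End-to-end cohort pipeline: per-participant morphometry to statistics.

``run_pipeline`` executes, for every participant in a manifest, whichever
stages have input files — cone-density metrics, ONL thickness summaries,
pit morphometry, FAZ morphometry — assembles the cohort table, appends the
cohort-level areal foveal density (which requires CDC alignment across all
maps), and runs the statistics layer.  Stage failures are logged and leave
the affected metrics missing; the pipeline never silently drops a
participant.

``simulate_cohort_files`` writes a fully synthetic cohort to disk in the
pipeline's own file formats, with generator parameters per participant
drawn from the copula cohort table, closing the generate → measure loop.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, cone_density, faz_morphometry, io, onl_profile, pit_morphometry
from .synthetic import CopulaCohort, LayerModel, MosaicModel, PitModel, VascModel
from .synthetic import synth_cohort, synth_mosaic, synth_segmentation
from .synthetic import synth_thickness_map, synth_vessel_mask

log = logging.getLogger("fovea")


@dataclass
class RunConfig:
    """All tunable pipeline parameters (µm unless noted)."""

    window_side_um: float = 50.0
    grid_step_um: float = 1.0
    cdc_fraction: float = 0.8
    cdc_weighted: bool = True
    onl_x_step_um: float = 5.0
    center_search_halfwidth_um: float = 750.0
    central_width_um: float = 227.0
    max_search_halfwidth_um: float = 500.0
    pit_search_radius_um: float = 750.0
    n_angles: int = 180
    radial_step_um: float = 10.0
    max_radius_um: float = 3000.0
    prominence_um: float = 2.0
    central_radius_um: float = 500.0
    ratio_threshold: float = 0.3
    icc_model: str = "two_way_random_absolute_single"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        positive = (
            "window_side_um", "grid_step_um", "onl_x_step_um",
            "center_search_halfwidth_um", "central_width_um",
            "max_search_halfwidth_um", "pit_search_radius_um",
            "radial_step_um", "max_radius_um", "central_radius_um",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.cdc_fraction < 1:
            raise ValueError("cdc_fraction must be in (0, 1)")
        if not 0 < self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ParticipantRecord:
    """Manifest entry: file paths per modality plus calibration data."""

    id: str
    axial_length_mm: float | None = None
    eye: str = "OD"
    coords_csv: Path | None = None
    seg_csv: Path | None = None
    thickness_csv: Path | None = None
    mask_png: Path | None = None
    derived: dict = field(default_factory=dict)


def read_manifest(path: str | Path) -> list[ParticipantRecord]:
    """Manifest CSV: ``id,axial_length_mm,eye,coords_csv,seg_csv,thickness_csv,mask_png``."""
    path = Path(path)
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: manifest needs an 'id' column")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate participant ids")
    base = path.parent
    records = []
    for _, row in df.iterrows():
        def _p(col):
            v = row.get(col)
            return base / str(v) if isinstance(v, str) and v else None

        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                axial_length_mm=float(row["axial_length_mm"])
                if "axial_length_mm" in row and pd.notna(row["axial_length_mm"])
                else None,
                eye=str(row.get("eye", "OD")),
                coords_csv=_p("coords_csv"),
                seg_csv=_p("seg_csv"),
                thickness_csv=_p("thickness_csv"),
                mask_png=_p("mask_png"),
            )
        )
    return records


def _participant_metrics(
    rec: ParticipantRecord, config: RunConfig, run_log: dict
) -> tuple[dict, tuple | None]:
    """All single-participant stages; returns (metrics, (map, cdc metrics))."""
    m: dict = {"participant_id": rec.id}
    plog = run_log["participants"].setdefault(rec.id, {"warnings": [], "errors": []})
    density_pair = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if rec.coords_csv is not None:
            try:
                mosaic = io.read_cone_coords(rec.coords_csv, participant_id=rec.id)
                dmap = cone_density.density_map(
                    mosaic, config.window_side_um, config.grid_step_um
                )
                met = cone_density.cdc(dmap, config.cdc_fraction, config.cdc_weighted)
                m["pcd"] = met.pcd
                m["cdc_density"] = met.cdc_density
                m["cdc_x_um"], m["cdc_y_um"] = met.cdc_location_um
                density_pair = (dmap, met)
            except Exception as exc:  # noqa: BLE001 - stage isolation
                plog["errors"].append(f"cone_density: {exc}")
                log.warning("participant %s cone_density failed: %s", rec.id, exc)
        if rec.seg_csv is not None:
            try:
                seg = io.read_segmentation(rec.seg_csv)
                profile = onl_profile.extract_onl_profile(
                    seg, config.onl_x_step_um, config.center_search_halfwidth_um
                )
                max_onl, max_x, central = onl_profile.onl_summaries(
                    profile, config.central_width_um, config.max_search_halfwidth_um
                )
                m["max_onl_um"] = max_onl
                m["central_onl_um"] = central
            except Exception as exc:  # noqa: BLE001
                plog["errors"].append(f"onl_profile: {exc}")
                log.warning("participant %s onl_profile failed: %s", rec.id, exc)
        if rec.thickness_csv is not None:
            try:
                tmap = io.read_thickness_map(rec.thickness_csv)
                pm = pit_morphometry.pit_metrics(
                    tmap,
                    config.pit_search_radius_um,
                    config.n_angles,
                    config.radial_step_um,
                    config.max_radius_um,
                    prominence_um=config.prominence_um,
                )
                m["pit_diameter_mm"] = pm.diameter_mm
                m["pit_volume_mm3"] = pm.volume_mm3
            except Exception as exc:  # noqa: BLE001
                plog["errors"].append(f"pit_morphometry: {exc}")
                log.warning("participant %s pit_morphometry failed: %s", rec.id, exc)
        if rec.mask_png is not None:
            try:
                vmask = io.read_vessel_mask(rec.mask_png)
                area, fragmented, n_central, _ = faz_morphometry.faz_area(
                    vmask.mask,
                    vmask.um_per_px,
                    config.central_radius_um,
                    config.ratio_threshold,
                )
                m["faz_area_mm2"] = area
                m["fragmented"] = fragmented
            except Exception as exc:  # noqa: BLE001
                plog["errors"].append(f"faz_morphometry: {exc}")
                log.warning("participant %s faz_morphometry failed: %s", rec.id, exc)
        plog["warnings"].extend(str(w.message) for w in caught)
    return m, density_pair


def run_pipeline(
    config: RunConfig,
    manifest: list[ParticipantRecord],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Execute all stages over a cohort manifest and write result tables.

    Writes ``cohort.csv``, ``summary.csv``, ``correlations.csv`` and
    ``run_log.json`` to ``out_dir``; returns the cohort table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    run_log: dict = {"config": config.to_dict(), "participants": {}}

    rows = []
    density_pairs: list[tuple] = []
    density_ids: list[str] = []
    for rec in manifest:
        m, pair = _participant_metrics(rec, config, run_log)
        rows.append(m)
        if pair is not None:
            density_pairs.append(pair)
            density_ids.append(rec.id)
    table = pd.DataFrame(rows)

    if density_pairs:
        try:
            common_width, areal = cone_density.areal_foveal_density(
                density_pairs, density_ids
            )
            areal_map = dict(zip(density_ids, areal))
            table["areal_density"] = table["participant_id"].map(areal_map)
            run_log["areal_common_width_um"] = common_width
        except Exception as exc:  # noqa: BLE001
            run_log.setdefault("cohort_errors", []).append(f"areal_density: {exc}")
            log.warning("areal density stage failed: %s", exc)

    io.write_cohort_table(table, out / "cohort.csv")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = cohort_stats.cohort_summary(table)
        io.write_cohort_table(summary, out / "summary.csv")
        pairs = [
            (a, b)
            for a, b in cohort_stats.DEFAULT_PAIRS
            if a in table.columns and b in table.columns
        ]
        corr_rows = []
        for a, b in pairs:
            try:
                res = cohort_stats.spearman(table[a], table[b])
                corr_rows.append(
                    {"metric_a": a, "metric_b": b, "r": res.r, "p_value": res.p_value,
                     "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n}
                )
            except ValueError as exc:
                run_log.setdefault("cohort_errors", []).append(f"{a}~{b}: {exc}")
        io.write_cohort_table(pd.DataFrame(corr_rows), out / "correlations.csv")

    io.write_results_json(run_log, out / "run_log.json")
    return table


# --------------------------------------------------------------------------
# synthetic cohort on disk
# --------------------------------------------------------------------------


def _pit_model_for(
    diameter_mm: float, volume_mm3: float, seed: int, noise_um: float = 0.0
) -> PitModel:
    """Pit model with the requested rim diameter and (approximate) volume."""
    rim_r = 500.0 * diameter_mm
    depth = 90.0
    model = None
    for _ in range(6):
        model = PitModel(
            t_rim_um=320.0,
            t_center_um=320.0 - depth,
            rim_radius_um=rim_r,
            seed=seed,
            noise_um=noise_um,
        )
        v = model.volume_truth_mm3()
        depth = float(np.clip(depth * volume_mm3 / v, 30.0, 220.0))
        if abs(v / volume_mm3 - 1.0) < 0.02:
            break
    return model


def simulate_cohort_files(
    n: int,
    seed: int,
    out_dir: str | Path,
    modalities: tuple[str, ...] = ("cones", "onl", "pit", "faz"),
) -> Path:
    """Write a synthetic cohort in pipeline formats; returns the manifest path.

    Per-participant generator parameters are taken from a copula cohort
    draw, so the on-disk cohort carries realistic metric ranges and
    cross-metric correlation structure.  A ``truth.json`` records every
    generator parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario, _ = synth_cohort(CopulaCohort(n=n, seed=seed))
    ss = np.random.SeedSequence([seed, 1])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 * n)]
    rows = []
    truth: dict = {"seed": seed, "n": n, "participants": {}}
    for i in range(n):
        pid = f"S{i:03d}"
        srow = scenario.iloc[i]
        rec: dict = {"id": pid, "axial_length_mm": 24.0, "eye": "OD"}
        ptruth: dict = {}
        if "cones" in modalities:
            model = MosaicModel(
                peak_density=float(srow["pcd"]),
                base_density=40_000.0,
                sigma_um=100.0,
                peak_offset_um=(0.0, 0.0),
                seed=seeds[4 * i],
            )
            mosaic, mtruth = synth_mosaic(model)
            io.write_cone_coords(mosaic, out / f"{pid}_cones.csv")
            rec["coords_csv"] = f"{pid}_cones.csv"
            ptruth["peak_density"] = mtruth["peak_density"]
            ptruth["peak_xy_um"] = list(mtruth["peak_xy_um"])
        if "onl" in modalities:
            lmodel = LayerModel(
                onl_peak_um=float(srow["max_onl_um"]),
                onl_base_um=float(srow["max_onl_um"]) - 40.0,
                seed=seeds[4 * i + 1],
            )
            seg, struth = synth_segmentation(lmodel)
            io.write_segmentation(seg, out / f"{pid}_seg.csv")
            rec["seg_csv"] = f"{pid}_seg.csv"
            ptruth["max_onl_um"] = struth["max_onl_um"]
            ptruth["center_x_um"] = struth["center_x_um"]
        if "pit" in modalities:
            pmodel = _pit_model_for(
                float(srow["pit_diameter_mm"]),
                float(srow["pit_volume_mm3"]),
                seed=seeds[4 * i + 2],
            )
            tmap, pt = synth_thickness_map(pmodel)
            io.write_thickness_map(tmap, out / f"{pid}_thickness.csv")
            rec["thickness_csv"] = f"{pid}_thickness.csv"
            ptruth["pit_diameter_mm"] = pt["diameter_mm"]
            ptruth["pit_volume_mm3"] = pt["volume_mm3"]
        if "faz" in modalities:
            radius_um = 1000.0 * math.sqrt(float(srow["faz_area_mm2"]) / math.pi)
            vmodel = VascModel(
                faz_radius_um=radius_um,
                split_proportions=(0.6, 0.4) if bool(srow["fragmented"]) else None,
                seed=seeds[4 * i + 3],
            )
            vmask, vt = synth_vessel_mask(vmodel)
            io.write_vessel_mask(vmask, out / f"{pid}_mask.png")
            rec["mask_png"] = f"{pid}_mask.png"
            ptruth["faz_area_mm2"] = vt["largest_fragment_mm2"]
            ptruth["fragmented"] = vt["fragmented"]
        rows.append(rec)
        truth["participants"][pid] = ptruth
    manifest_path = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    io.write_results_json(truth, out / "truth.json")
    return manifest_path
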