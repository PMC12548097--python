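# fovea-morph

Foveal specialization morphometry: a tested, reusable pipeline for the
image-derived metrics used to compare cone photoreceptor topography with
retinal anatomy in normal-vision cohorts.

The human fovea concentrates cones, thins the inner retina into a pit, and
excludes capillaries from an avascular zone — and how these specializations
covary across healthy eyes bears directly on whether clinically accessible
OCT measures (such as outer nuclear layer thickness) can stand in for cone
density. This package computes, from four imaging modalities:

* **Cone density metrics** from AOSLO cone coordinates in a ~300 × 300 µm
  foveal ROI: a sliding-window density map D(x, y) (cones/mm², half-open
  square windows, default side w = 50 µm on a 1 µm grid), **peak cone
  density** PCD = max D, the **cone density centroid** (CDC) — the
  density-weighted centroid of the 8-connected region enclosed by the
  isodensity contour at 0.8 · PCD — and the cohort-common **areal foveal
  density** (mean of the CDC row over the largest square common to all
  CDC-aligned maps).
* **True ONL thickness** from directional-OCT boundary segmentations
  (30 knots per boundary for ILM, OPL/HFL, HFL/ONL, ELM, RPE): triad
  alignment by translation, pixelwise-maximum merge, piecewise-linear
  boundary interpolation, ONL(x) = z_ELM(x) − z_HFL/ONL(x) in µm, with the
  **maximum foveal ONL** (within ±500 µm of the foveal center, located at
  the ILM–RPE thickness minimum) and the **central foveal ONL** (trapezoid
  mean over the 0.227 mm common width).
* **Foveal pit diameter and volume** from ILM–RPE thickness maps
  (anisotropic 512 × 128 grid over an axial-length-corrected 6 × 6 mm
  cube): radial rim detection (first prominent local maximum per spoke),
  diameter = mean opposed rim-to-rim extent, volume = ∫ max(0, rim(θ) − T) dA
  inside the rim contour.
* **FAZ area and fragmentation** from binarized OCTA vessel masks:
  4-connected parafoveal intercapillary areas (PICAs), the largest central
  PICA assigned as the FAZ, fragmentation when ≥ 2 central PICA/largest
  ratios exceed 0.3.
* **Cohort statistics**: Spearman rank correlations (t-approximation p,
  Fisher-z CI with SE = 1.03/√(n−3)), intergrader ICC(2,1) with F-based CI,
  paired t tests, and range/median/IQR summaries.

All lateral scales are corrected for ocular axial length:
`true length = nominal × axial_length / 24.46 mm` (the Cirrus schematic eye).

Because no public dataset carries all four modalities with ground truth,
the package includes first-class synthetic generators
(`fovea.synthetic`) for every input class — inhibition-sampled cone
mosaics with a prescribed Gaussian density surface, analytic layer
segmentations, parametric pits, Voronoi capillary beds around a known FAZ,
and Gaussian-copula cohort tables — so every stage is validated by
parameter recovery.

## Worked example

```python
from fovea.synthetic import MosaicModel, synth_mosaic
from fovea.cone_density import density_map, cdc

mosaic, truth = synth_mosaic(
    MosaicModel(peak_density=200_000, sigma_um=100, peak_offset_um=(30, -20), seed=1)
)
met = cdc(density_map(mosaic, window_side_um=50, grid_step_um=1))
print(f"PCD {met.pcd:.0f} cones/mm2 | CDC ({met.cdc_location_um[0]:.1f}, "
      f"{met.cdc_location_um[1]:.1f}) um | CDC density {met.cdc_density:.0f}")
```

prints

```
PCD 198000 cones/mm2 | CDC (179.0, 128.4) um | CDC density 193862
```

i.e. the recovered peak density is within 1% of the generator's
200 000 cones/mm² and the CDC lands within 2 µm of the true density peak at
(180, 130) µm — the CDC is a stabler foveal landmark than the PCD pixel
because it averages the whole supra-threshold region.

The cohort-level workflow lives in `analysis/`:

```bash
python analysis/01_simulate_cohort.py    # synthetic cohort -> scratch/cohort/
python analysis/02_extract_metrics.py    # full pipeline -> results/pipeline/
python analysis/03_cohort_statistics.py  # summaries, Spearman table, ICC
```

On the default 12-participant cohort, `02` reports worst-case recovery of
PCD within 3.1%, max ONL within 0.56 µm, pit diameter within 0.002 mm, pit
volume within 0.2%, and FAZ area exact to the pixel count; `03` prints the
Spearman correlation table over the designed metric pairs (e.g. pit
diameter vs. PCD r = −0.46 on this draw, target −0.54) and an intergrader
ICC(2,1) with its paired t test on a 68-participant two-grader simulation.

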