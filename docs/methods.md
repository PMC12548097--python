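# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `fovea` package. Conventions: image arrays are
(row, col) = (y, x), 0-based, pixel-center; physical coordinates are µm
from the top-left pixel center; depth (z) increases downward on B-scans.

## Lateral scale correction

OCT devices report scan lengths for a schematic eye (Cirrus: axial length
24.46 mm). True lateral extent scales as
`corrected = nominal × axial_length / 24.46`. The correction is applied to
every lateral measurement (B-scan µm/px, thickness-map extent); axial
(depth) sampling is treated as a device constant and not corrected — the
directional dependence of depth calibration is far smaller than the
lateral effect and the upstream segmentations are defined in device
pixels. Axial lengths outside 18–32 mm are rejected (configurable): the
window catches unit errors without excluding real eyes.

## Cone density mapping

Density at a grid node is the cone count in the half-open square window
[c − w/2, c + w/2) divided by the window area. Half-open membership makes
the count a partition: every cone belongs to a well-defined set of
windows, so window counts are conserved exactly (tested against a brute
force recount). Defaults: window side 50 µm, grid step 1 µm. The window is
an order of magnitude above foveal cone spacing (~2.5 µm), giving ~400–600
cones per window and stable counts, yet small against the 300 µm ROI.
Windows must lie fully inside the ROI — partial-window renormalization
would inflate edge variance, and the metrics of interest are central.

PCD is the map maximum; integer counts produce plateaus, so ties resolve
to the node nearest the grid center, then row-major — deterministic
output. The CDC threshold is 0.8 × PCD; the supra-threshold region is the
8-connected component containing the PCD node, and the CDC is its
density-weighted centroid (unweighted selectable). The phrasing "contour
at 80% of the top-percentile density" admits a second reading (a contour
derived from the top-20%-of-values set); this package implements the
fraction-of-PCD reading with the fraction configurable, and does not guess
further. CDC density is bilinear interpolation of the map at the CDC.

Areal foveal density aligns all maps at their CDCs; the common half-width
h is the minimum CDC-to-edge distance over all maps, and each map
contributes the mean of its CDC row over ±h. Whether a reported common
area of 0.227 mm is a half- or full width is ambiguous; the package treats
it as a full width (2h) and reports both.

## ONL thickness from directional OCT

Alignment is translation-only with integer pixel shifts, chosen to
maximize normalized cross-correlation (FFT cross-correlation of
standardized images restricted to ±40 px, with the exact overlap NCC
reported as the score; scores < 0.5 are flagged, mirroring grader
rejection of poorly aligned triads). Rotation/scaling are out of scope —
triad review in practice is a pass/fail visual check on RPE/ILM/choroid
contours. Merging is the pixelwise maximum (idempotent, commutative,
monotone).

Boundaries are piecewise-linear through their knots with no extrapolation:
manually placed points bound the trusted region. ONL(x) =
(z_ELM − z_HFL/ONL) × axial scale on the boundaries' common span,
evaluated every 5 µm (far below knot spacing; discretization negligible).
Negative thickness raises with the offending positions listed — it means
the segmentation violates anatomical ordering, which is also validated at
load.

The foveal center is the minimum of ILM–RPE thickness within ±750 µm of
the scan midpoint, evaluated on a 1 µm grid and refined by a least-squares
parabola over ±500 µm around the raw minimum. The refinement matters: with
~100 µm knot spacing the piecewise-linear minimum sits on a knot, so a
single noisy knot could displace the center by a full knot spacing,
whereas the parabola vertex pools all central knots (with 1 px knot noise,
center recovery is within 20 µm in ≥ 95% of simulations; the refinement is
exact for noise-free symmetric pits and can be disabled). Maximum foveal
ONL is searched within ±500 µm of the center — wide enough for real
displacement of the ONL peak, narrow enough to exclude parafoveal
artifacts; central ONL is the trapezoid mean over the full 0.227 mm
central width (±113.5 µm), mirroring the areal-density convention.

## Pit morphometry

The rim-based procedure operationalizes pit diameter/volume from a
thickness map: (1) pit center = smoothed thickness minimum within 750 µm
of the map center (Gaussian smoothing, 25 µm — thickness maps are
physically smooth, so this suppresses pixel noise without biasing a
symmetric pit — with quadratic sub-pixel refinement); (2) thickness
resampled along 180 radial spokes every 10 µm to 3 mm, bilinear in
physical µm so the 4× anisotropic sampling of the 512 × 128 cube is
handled exactly; (3) per-spoke rim = first local maximum with ≥ 2 µm
prominence after a 5-sample moving average (global maximum as a flagged
fallback on monotone profiles), quadratically refined; (4) diameter = mean
of opposed rim-to-rim sums; (5) volume = Σ max(0, rim(θ) − T) × pixel area
over pixels inside the periodically interpolated rim contour. A per-angle
rim cap (not a single plane) tolerates tilted maps. All thresholds are
configurable. Equivalence with any specific prior implementation cannot be
asserted — the procedure is validated by internal consistency: closed-form
cylinders (πR²d within 1%), fine quadrature of analytic pits (within 2%),
rotation invariance and scale equivariance.

## FAZ morphometry

Repeat angiograms are averaged pixelwise; grayscale images are binarized
by Otsu (fixed threshold selectable; binary inputs pass through). PICAs
are 4-connected components of the avascular complement — 4-connectivity
prevents diagonal leakage through 8-connected one-pixel capillary walls.
Border-touching regions are retained but flagged and never FAZ candidates:
they are unbounded intercapillary space. The central set comprises
non-border PICAs whose centroid lies within 500 µm of the image center
(the normal FAZ, ≤ ~0.5 mm², has an equivalent radius ≤ ~400 µm, so
500 µm comfortably contains it); centroid-based centrality is
deterministic and insensitive to finger-like protrusions. Ratios are each
central area over the largest; fragmentation requires ≥ 2 ratios strictly
above 0.3, and the FAZ area is always the largest central area.

## Statistics

Spearman r is the Pearson correlation of mid-ranks; p uses the
t-approximation t = r√((n−2)/(1−r²)) on n−2 df; the 95% CI is the Fisher z
interval with the Fieller-adjusted SE 1.03/√(n−3). The ICC defaults to
ICC(2,1) — two-way random effects, absolute agreement, single rater — so a
systematic grader offset (detectable by the paired t test) correctly
lowers agreement; the consistency variant ICC(3,1) is selectable. CIs use
the standard F-based intervals (both cross-checked against an independent
implementation). Missing data are deleted pairwise; ties get mid-ranks; p
values are reported raw by default (Holm adjustment available) with a
multiplicity warning.

## Synthetic data: what it emulates, and what it does not

Every generator returns its ground truth so the suite closes the
generate → measure → compare loop.

**Cone mosaics.** Variable-radius dart throwing: uniform candidates are
accepted if no prior cone lies within 0.8 × s(x, y), where
s = √(2/(√3 D)) is the triangular-lattice spacing at the local target
density D (Gaussian profile, defaults: peak 190 000, base 40 000 cones/mm²,
σ = 100 µm — chosen so densities at the ROI edge fall in the realistic
50–100 k range). Candidates continue until 200 × (expected count)
rejections. Sequential inhibition saturates near 0.94 of its proposal
intensity, so the generator self-calibrates a proposal multiplier until
the realized windowed density at the true peak matches the analytic window
mean within 2% (≤ 4 regenerations, deterministic per seed), and asserts
the result is within 10% of the target peak. The core loop is
numba-compiled. The mosaics have grader-like irregular packing but carry
no reflectance variation, detection misses, or montage seams.

**Layer segmentations.** Analytic boundaries: Gaussian ONL bump
(base + (peak−base)·exp(−x²/2σ²), σ = 300 µm), Gaussian pit in total
thickness (rim 330, center 210, σ = 450 µm — curvature representative of
normal pits), constant ELM–RPE offset (70 µm) and a Henle layer thinning
to 5 µm centrally. The 30 knots mimic grader placement: 14 uniform knots
across ±650 µm, 8 per side widening geometrically to ±2.5 mm —
concentrating points where curvature is high, as graders do; knot noise is
Gaussian in z with per-column re-sorting (graders never place crossing
boundaries). Real segmentations add structured errors (speckle-following,
boundary ambiguity) not modeled here.

**Pit maps.** T(r) = t_rim − (t_rim−t_center)·exp(−(r/r₀)²) −
s·max(0, r−r_k)², floored at 150 µm, with the Gaussian width r₀ solved
(on the u > 1 branch of u·e^(−u)) so the profile maximum sits exactly at
the requested rim radius (kink at 0.9 × rim radius). Reference volume by
radial quadrature of the analytic profile. Real maps add segmentation
artifacts and tilt; tilt tolerance is tested only via the per-angle rim
cap.

**Vessel masks.** A circular FAZ ring of known pixel-counted enclosed
area, surrounded by the Voronoi edges of Poisson seeds (spacing 150 µm,
2 px line width at 10 µm/px); fragmentation is a straight chord whose
offset is solved from the circular-segment area equation for the requested
split proportions. Real capillary beds are not Voronoi tessellations, but
the labeling/ratio logic only needs enclosed regions of known area.

**Copula cohorts.** Gaussian copula with target rank correlations
converted by ρ_pearson = 2 sin(π ρ_s / 6) (verified against brute-force
rank correlation of 10⁶ samples), nearest-PSD eigenvalue repair when the
assembled target matrix is indefinite, and scaled Beta margins
(concentration 6, shape solved so the distribution median matches the
scenario median) — Beta rather than Gaussian because the metrics are
bounded and skewed. Scenario defaults use the published normal-cohort
ranges and correlations as parameters; recovering them is a consistency
check of the generator + statistics loop, not a reproduction of human
data.

Passing tests therefore demonstrate correct computation under these
idealized conditions; they do not certify performance on real images with
acquisition artifacts, pathology, or grader disagreement beyond the
modeled noise.

## Problem sizes

Defaults throughout were chosen as the smallest sizes at which the
recovery criteria are statistically meaningful: 20 mosaics across the
density range for PCD/CDC recovery; 100 replicates for ONL noise bias; 50
for center-localization rates; 500 for the ICC and copula simulations
(SEs ≈ 0.005 and 1 percentage point); 3-participant cohorts for
byte-level determinism checks, and a 12-participant cohort in the analysis
scripts.

## Known limitations

* Cone detection, montaging and desinusoiding are out of scope: the
  pipeline consumes cone coordinates as given.
* D-OCT alignment is integer-translation only; no rotation/shear.
* The pit rim procedure is an operational definition; absolute agreement
  with other published pit algorithms is not claimed.
* OCTA binarization is global (Otsu); device-specific slab extraction and
  local-contrast methods are not modeled.
* The ICC/CI formulas assume the usual two-way normal ANOVA model.
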