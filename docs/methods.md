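# Methods

This note documents the models, conventions and design choices behind
`tismorph`, in the order the pipeline runs.

## Raw NLO corrections (`tismorph.preprocess`)

**Outlier removal.** Cosmic-ray and detector spikes are single-pixel
extremes. A pixel is replaced by its 3×3 neighbourhood median when it
deviates from that median by more than `z_thresh` (default 5) robust
standard deviations, where the scale is 1.4826 × the neighbourhood MAD
**floored at the image-wide median of local MADs**. The floor matters:
a nine-sample MAD collapses to zero by chance on pure noise, and the
unfloored rule would replace ~1 % of perfectly ordinary pixels. On a
globally flat raster the floor is zero, so an isolated spike (or a pair
of adjacent spikes, whose 3×3 medians are still the background level) is
always replaced. Known behaviour on synthetic data: hard-edged
structures painted at or below the pixel scale (droplet rims, speckles)
look like local extremes and are eroded by one pixel; measured droplet
areas are therefore slightly below the painted areas.

**Serpentine correction.** Bidirectional stage scanning shifts the
reverse-scan (even-indexed, 0-based) rows laterally. The integer shift
k̂ maximises the mean normalised cross-correlation between the
*lateral derivative* of each even row, circularly rolled by −k, and that
of the average of its adjacent odd rows, over |k| ≤ 10 (ties break
toward smaller |k|). Derivatives are used because the raw rows of a
smooth cell image produce a broad correlation peak that noise can move
by ±1 px; cell-edge derivatives are spiky and pin the peak (error-free
across the presets, exact for all |k| ≤ 10 on noise-free inputs —
circular differencing commutes with the circular shift, so the
round-trip is exact). One global k̂ per image is assumed, estimated on
the transmission channel and applied to all co-registered channels.

**Order of operations.** The pipeline aligns rows first and despikes
second. The reverse order would let the median filter interpret
misaligned cell edges as local extremes and partially smear them before
the shift could be measured, while single-pixel spikes barely perturb
the derivative-correlation estimate. Outliers are injected by the
generator before the row shift (as a detector would produce them), so
the round trip is exact either way on artifact-free data.

**SRG normalisation.** `normalize_srg` divides the lock-in ΔI raster
(V RMS) by the Stokes transmission I (V), pixelwise, to give
dimensionless ΔI/I. The result is invariant under a common gain; any
non-positive transmission pixel is an error, not a warning, because it
indicates a corrupted acquisition.

## NLO quantification (`tismorph.nlo`)

Cells appear dark in linear transmission. The footprint is the
below-Otsu region after closing (disk radius 2 px), hole filling and
removal of components < 50 px²; closing radius and minimum size are
package defaults exposed in the config. All per-FOV metrics are
computed over the union footprint of the FOV (the study design analyses
FOV-level populations of ~10 cells); per-component splitting is
available but not the default.

Thresholds: 0.25 a.u. for TPEF, 2.2 × 10⁻⁴ ΔI/I for SRS, applied with a
strict `>` to the preprocessed rasters as-is (no rescaling). The
top-decile maximum uses the ⌈0.1·N⌉ largest in-mask values — a maximum
estimate insensitive to residual spikes. The aggregation index is the
product of that maximum with the TPEF-positive area percentage; it
rises when a fixed amount of coenzyme fluorescence condenses into
bright puncta.

Droplet analysis labels in-mask above-threshold SRS pixels with
8-connectivity (configurable to 4). Components ≥ 5 px² are *clusters*;
*quasi-single* droplets additionally satisfy 0.3 ≤ 4πA/P² ≤ 1 with the
circularity clamped at 1.0 before the range test. The perimeter is the
**crack perimeter** — the total length of exposed pixel edges,
4A − 2·(adjacent pairs) — so a 1×20 px line has P = 42 and circularity
≈ 0.14, and a rasterised disk of radius 4 (49 px) has circularity
≈ 0.60, comfortably inside the quasi-single band. With this estimator
digital circularity cannot exceed π/4·(4A/P²-bound) > 1 in practice;
the clamp is kept for robustness to alternative perimeter definitions.
The mean quasi-single area is reported as missing (NaN), not zero, when
no component passes the filter.

## Colocalization (`tismorph.coloc`)

M1/M2 are the **pixel-frequency (count) quadrant** coefficients: with
crosshair thresholds (t1, t2) on the (ch1, ch2) scatter,
M1 = N_TR/(N_TR+N_BR) and M2 = N_TR/(N_TR+N_TL). They are invariant
under strictly monotone rescaling of either channel with its threshold.
The classical intensity-weighted Manders coefficients are provided
separately (`manders_intensity`) and are not used by the pipeline.
Thresholds for TPEF and SRS are the universal thresholds above; the
CARS channels carry an arbitrary nonresonant-background offset, so
their crosshairs default to Otsu on the in-mask pixels (override via
config). Analysis is restricted to the cell mask by default; a
whole-FOV mode exists for comparison with scatter plots that include
background.

The Costes control permutes the in-mask pixels of channel 2 while
channel 1 stays fixed, and reports the one-sided
p = (1 + #{PCC_rand ≥ PCC_obs})/(1 + n_rand). The default block size is
one pixel because the pixel pitch (350 nm) is at or above the optical
resolution, making adjacent pixels effectively independent; a block
mode (non-overlapping in-mask blocks) is available for oversampled
data. `n_rand < 20` is rejected as unstable. Under an independent-noise
null the p-values are uniform on {k/(n_rand+1)}; with n_rand = 199 an
identical structured pair yields the floor p = 0.005.

## QPI morphometrics (`tismorph.qpi`)

Cell voxels are those with RI above the medium (1.3342) by δn = 0.003
(configurable; the background RI alone does not define a margin), then
3-D closing (ball radius 1) and removal of 26-connected components
< 100 voxels. Volume is voxel count × voxel volume; mean thickness is
volume over the x-y footprint area (maximum column thickness is an
alternative output).

Dry mass uses Δn = α·c with α = 0.19 ml/g (cell) and 0.135 ml/g
(lipid). Two routes are implemented and agree to machine precision on
phantoms: the volumetric sum Σ Δn·dV/α and the phase-projection form
λ/(2πα)·∫φ dA with φ = (2π/λ)·∫Δn dz. Units compose so that
Δn = 0.019 over 1 µm³ at 0.19 ml/g is exactly 0.1 pg. Voxels inside the
mask with Δn < 0 (noise) contribute zero and are counted in a warning.
Lipid voxels are cell voxels with 1.40 ≤ n ≤ 1.46 **inclusive**; lipid
dry mass uses Δn relative to the *medium* (not the surrounding
cytoplasm) with the lipid α — the medium-relative convention is the
documented choice where both are defensible.

## Statistics (`tismorph.stats`)

Mann–Whitney U is exact (null enumerated) for untied pooled samples of
≤ 16 observations, otherwise the normal approximation with mid-ranks,
tie-corrected variance and continuity correction; the method used is
recorded per test. Both paths are delegated to `scipy.stats` and are
cross-checked in the tests against full enumeration of all rank splits
up to n = m = 6. The time-course report runs control-vs-TIS per time
point and each later time point against the 0 h baseline within each
condition (baseline pairing; the alternative consecutive-pair scheme is
not implemented). Groups with n < 3 are skipped with a recorded reason.
No multiple-testing correction is applied by default, matching the
single-comparison design; a Benjamini–Hochberg helper exists but is off.
With ~6 correlated metrics × 5 time points per modality, isolated
nominally-significant null contrasts are expected at roughly the α
rate and should be read accordingly.

## Synthetic phenotypes (`tismorph.synthetic`)

The generator is phenomenological: it paints the *features the metrics
respond to*, not the physics of coherent Raman imaging, phase retrieval
or optical sectioning. One seeded `numpy` generator drives everything,
so identical (params, seed) give bit-identical outputs.

NLO FOVs (default 300×300 px at 0.35 µm): cells are non-overlapping
jittered ellipses, dark in transmission (0.55–0.8 vs background 1.0)
with a radial gradient. The TPEF pattern is either a perinuclear
annulus (diffuse, plateau at half the peak) or hard parabolic-profile
puncta; smooth content is blurred with a Gaussian (σ 0.6 px) to mimic
the finite optical resolution, while puncta, droplets and speckles —
sub-resolution objects — stay pixel-sharp. SRS droplets are hard disks
at ΔI/I amplitudes well above threshold, echoed as bright F-CARS spots
over the intracellular nonresonant background and, where configured, in
E-CARS. Control-specific F-CARS speckles (bright spots without SRS)
keep the control CARS-vs-SRS M2 low, as expected when the nonresonant
background dominates. The E-CARS channel echoes a coherent fraction
(`ecars_overlap_frac`, jittered per FOV) of the TPEF pattern at a fixed
level plus an area-matched complement of E-CARS-only scatterers, so
that quadrant M1 ≈ M2 ≈ overlap in controls while a strong droplet
E-CARS term drives M1 down and the raised overlap drives M2 up in late
TIS. Gaussian noise is added per channel; Poisson photon statistics are
not modelled because every metric is threshold- or rank-based.
Outliers (random bright/dark spikes) are injected before the row shift.

Tomograms (default 212×212×64 voxels over 80.470 × 80.470 × 39.666 µm —
the instrument grid downscaled 4× laterally and ~3× axially to keep a
tomogram ~11 MB and its analysis ~1 s; the full grid is reachable via
`qpi_shape`/`qpi_voxel_um`): ellipsoidal cells at a constant RI drawn
from `cell_ri`, non-overlapping lipid spheres drawn from `lipid_ri`
fully inside the cell, optional RI noise. The ground truth records the
analytic volume (4/3·πabc), mean thickness (4c/3), pipeline-equivalent
dry mass and per-sphere lipid volume/mass, so voxel-counted estimates
can be checked against closed forms (≤ 5 % for radii ≥ 10 voxels).

**Presets.** `nlo_preset`/`qpi_preset` encode the emulated conditions
per time point. Controls are stationary: diffuse TPEF over ~15 % of the
cell area, ~1 small droplet per cell, 7.5 µm cell radius (NLO) and
9 µm radius × 9 µm thickness (QPI). TIS trajectories condense TPEF into
puncta of rising peak (1 → 16 a.u.) over falling area (15 → 4 %), and
raise droplet density/size so the SRS-positive area is ~0 % early,
~3 % at 72 h and ~15–20 % at day 7 with ~2–3× larger quasi-single
droplets; QPI cells grow (9 → 14 µm radius), flatten (9 → 6 µm) and
accumulate lipid spheres (2 → 12 per cell). Dispersion across FOVs
comes from placement randomness plus mild lognormal jitter (σ ≈ 0.1) on
fractions and amplitudes; no per-image variance was available to fit,
so these dispersions are chosen once as plausible biological
variability. Preset artifact levels are outlier rate 2×10⁻⁴ and a 3 px
serpentine shift.

**What passing tests show — and don't.** The synthetic data share the
metrics' *operating assumptions* (dark cells, thresholdable signals,
compact droplets, RI bands) but not real-image texture: no
photobleaching, no spatially correlated noise, no deformable cell
shapes, no partial-volume RI mixing, no droplet size distribution tails.
Green tests certify that the measurement chain is correct and that the
statistical machinery is calibrated; they do not certify segmentation
robustness on real micrographs.

## Problem sizes

Defaults were chosen so that the full test suite runs in a few minutes
and the acceptance script in ~2 min on one CPU: directional contrasts
use 10 FOVs/tomograms per condition at fixed seeds; the null
calibration of the control-vs-TIS test uses 500 repetitions of the full
generate → segment → measure → test path on reduced 144 px, 3-cell FOVs
(the reduction changes only compute cost, not the null distribution of
the test); Costes calibration uses 500 trials at n_rand = 99 on 16×16
masks, and 199 randomizations for the structured-pair floor.

## Known limitations

* The outlier filter erodes one-pixel rims of hard-edged
  sub-resolution objects; droplet areas are measured post-erosion.
* The serpentine estimate is global per image; per-row-pair drift is
  not modelled or corrected.
* The quadrant M1/M2 depend on the CARS Otsu crosshairs when no fixed
  threshold is configured; on bimodally-distributed CARS content the
  Otsu split can move between modes across FOVs.
* QPI metrics are per-tomogram (one cell per tomogram in the presets);
  multi-cell tomograms are analysed as a union unless segmented
  components are handled by the caller.
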