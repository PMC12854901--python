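# Methods

## The measurement model

A nucleus expressing a condensate-forming scaffold is treated as a two-phase
system at each instant: a dilute phase (nucleoplasm) at concentration C_dil
and a dense phase (the condensates) at C_den, occupying a volume fraction φ
of the nucleus. Fluorescence is assumed proportional to scaffold
concentration, so the compartment means of the background-corrected voxel
intensities estimate relative concentrations, and mass balance ties the three
quantities together:

    C_tot = φ·C_den + (1 − φ)·C_dil.

The discriminating physics lives in how (C_dil, C_den, φ) move as C_tot
varies across nuclei. Simple binary coexistence pins C_dil at the saturation
concentration C_sat and C_den at the dense binodal — only φ grows (the lever
rule). In a multicomponent system (scaffold plus clients and other
interactors) the effective tie-lines shift with composition, and both phase
concentrations climb with C_tot.

## Image processing

Each stack passes through: a 5 × 5 × 3 (y, x, z) median filter with edge
replication (the 3-tap axis is z because confocal axial sampling is coarse);
subtraction of the intensity mode of the full 3D stack; an intensity-weighted
histogram (128 bins by default); bounded least-squares fits of 2-, 3- and
4-component Gaussian sums to that histogram; adjusted-R² model selection; and
mean + 3·SD thresholds from the first two components to segment nucleus and
condensates. Design choices a user should know about:

**Mode estimation.** Float images have no exact mode, so intensities are
quantised into 256 equal-width bins. The background is defined as the
*lowest-intensity* prominent population: among local maxima of the lightly
smoothed count histogram reaching at least half the global maximum, the
lowest one is chosen, and the reported mode is the mean intensity of the
voxels in that bin. In dim fields of view the nucleoplasm peak can rival the
background peak in raw counts; subtracting the global mode there would delete
the dilute phase. Exact ties likewise resolve to the lowest mode.

**Histogram weighting.** Each voxel contributes weight proportional to its
own intensity ("counts weighted by intensity"). This up-weights the rare
bright dense phase — a condensate occupying 5 % of the nucleus at a 10-fold
partition coefficient carries roughly a third of the total weight — which is
what makes a small dense-phase peak fittable at all. A `count` weighting
option exists for the alternative reading.

**Fit parameterisation and bounds.** The fitted curve is
f(x) = Σᵢ aᵢ·exp(−(x−μᵢ)²/2σᵢ²) — a curve fit to the histogram, not EM over
voxels, because the selection statistic (adjusted R²) is a curve-fit
quantity. Bounds keep component identity stable: the first component is the
background, with mean and SD confined below a background ceiling estimated
as 1.5 × the 0.6 count-quantile of the corrected image (background dominates
voxel counts in a single-nucleus field of view, so this tracks the upper
edge of the background residual at any expression level); signal components'
means lie above the ceiling, SDs within [bin width, range/2], amplitudes
within [0, 1.5 × max weight]. Without the ceiling, the intensity-weighted
histogram's tiny background weight lets fits drop or misplace the background
component, and the "component 1 = background, component 2 = nucleoplasm"
threshold rule breaks. Fits are multi-started (5 starts by default) from
quantile-spaced means, one start anchored at the low end, with seeded jitter;
a non-converging k returns a flagged fit that model selection skips.

**Model selection.** Highest adjusted R² with p = 3k parameters; adjusted-R²
differences below `selection_tol` (default 6e-3) count as ties and resolve to
the smaller k. The tolerance is calibrated on synthetic condensate-free
nuclei: a spurious extra component (absorbing bin noise or the mild skew the
intensity weighting imprints on the nucleoplasm peak) gains at most ~5e-3
adjusted R², while a real dense-phase peak gains ≥ ~1.5e-2, so the default
cleanly separates the regimes. With k = 4 selected, the condensate threshold
still uses component 2 — the two brightest components jointly describe an
asymmetric dense phase.

**Segmentation.** Nucleus = voxels above μ₁ + 3σ₁, reduced to the largest
26-connected component with internal holes filled (interior voxels that dip
below threshold — dim nucleoplasm texture — are thereby recovered);
condensates = nucleus voxels above μ₂ + 3σ₂. Inverted thresholds (overlapping
components) raise a named error and count as a per-image failure in series
runs. An image entirely below the nucleus threshold yields empty masks and
NaN-flagged metrics. C_den pools all condensate voxels (one compartment);
objects are 26-connected components, filtered by a `min_size` (default 4
voxels) that replaces the interactive per-image size cutoff of manual 3D
object counting; volumes use the anisotropic voxel size.

## Series analysis and the regime verdict

For each of {φ, mean condensate volume, C_den, C_dil} against C_tot the
package reports Pearson r and its two-sided p (NaN rows excluded pairwise),
plus a robust effect size: the Theil–Sen slope times the observed C_tot range
divided by the metric's median — the fitted relative change across the
series. The verdict is

* **multicomponent-like** if C_dil and C_den both increase significantly
  (r > 0, p < 0.05) *and* by more than `rel_change_threshold` (default 10 %)
  across the range;
* **binary-like** if both are flat (relative change below threshold, or
  |r| < 0.2 and not significant) while φ increases significantly;
* **indeterminate** otherwise.

The effect-size guard is essential, not cosmetic: when the truth is constant
(binary regime), the measured series is constant plus independent estimation
noise, and the *sample* correlation of n = 40 such values against C_tot is
null-distributed with SD ≈ 1/√(n−1) ≈ 0.16 — a significance-only rule would
misclassify a large fraction of genuinely binary series no matter how precise
the per-image estimates are. The robust slope also keeps one or two badly
segmented images from manufacturing an apparent trend. Setting
`rel_change_threshold = 0` recovers the significance-only rule. Binned
profiles report mean ± SEM (SD/√n) per equal-width C_tot bin; single-point
bins report SEM 0 with an explicit flag.

## The synthetic-scene generator

Scenes emulate agroinfiltrated-nucleus stacks: an ellipsoidal nucleus
(default semi-axes 2.0 × 4.2 × 4.2 μm) in a 24 × 128 × 128 grid of
0.2 × 0.08 × 0.08 μm voxels; non-overlapping spherical condensates placed by
largest-first rejection sampling (capped at 10⁴ attempts, with a one-voxel
separation margin so ground-truth labels stay distinct 26-connected
objects); phase intensities set by mass balance from (C_tot, pc, φ); a
detector offset (default 20 a.u.) added everywhere; smooth multiplicative
texture fields (Gaussian random fields, 0.3 μm correlation length) at 10 %
relative amplitude on signal and 40 % on the background offset; optional
isotropic Gaussian PSF; Gaussian (default σ = 4 a.u.) or Poisson noise.
Identical parameters and seed give bit-identical scenes. Ground truth records
the pre-blur, pre-noise masks and the *nominal* mass-balance concentrations;
the realized texture fluctuates ±~1 % around them, which is folded into
recovery tolerances.

Why texture: piecewise-constant phases collapse to single-bin delta peaks
after median filtering, which would make the histogram-fitting stage
degenerate; real nuclei have within-phase intensity structure, and the broad
background component seen in real intensity histograms requires background
spread (uneven autofluorescence). The background offset is additive
everywhere — that is what detector dark counts and stray light do, and it is
the model under which mode subtraction is an unbiased correction.

Series are generated under two thermodynamic laws over C_tot ∈ [70, 200] a.u.
(defaults): binary — C_dil ≡ C_sat = 60, C_den ≡ 800, φ from the lever rule
(images below C_sat get no condensates); multicomponent — C_dil = 20 +
0.3·C_tot, C_den = 300 + 2.5·C_tot, φ from mass balance (≈ 0.067 → 0.166).
Droplet number and mean size both grow with φ (per-droplet volume
∝ √(φ/0.06) around a 1 μm reference radius, count from φ·V_nucleus), so
the generator reproduces the qualitative growth of both condensate count and
size with expression level while keeping droplets several kernel widths
across.

**PSF default is 0 (off).** Ground truth refers to pre-blur geometry; with
blur enabled, the low condensate threshold (μ₂ + 3σ₂ sits just above the
nucleoplasm) picks up the blur halo, inflating apparent droplet volumes by
tens of percent — a genuine limitation of threshold segmentation on blurred
data that users should calibrate against their optics before interpreting
absolute φ. Blur is available per-scene (`psf_sigma`, μm).

**Droplet size matters.** The 5 × 5 × 3 median filter erodes spheres. Measured
on voxelized spheres with a threshold just above the dilute level, the
segmented-volume bias is ≈ −5 % at radii of (5 z, 12 xy) voxels, −9 % at
(4, 10), and −20 % or worse below (3, 7). Phase *concentrations* are nearly
immune (eroded boundary voxels flip to dilute-like values and leave both
compartment means unbiased), but φ and per-object volumes are not. Generator
defaults therefore keep droplet radii ≈ 0.7–1.1 μm; the replicate studies'
reduced geometry keeps the same ratio, and its series start at C_tot = 110 to
avoid the binary near-saturation regime where droplet volumes fall below the
filter's resolution limit in a small nucleus and acquire a size-dependent
C_den bias.

## What passing the validation studies does and does not show

The studies (tests and `scripts/acceptance.py`) show the pipeline recovers
known phase parameters, selects the right component count and discriminates
the two thermodynamic regimes *under the generator's assumptions*: spherical
droplets well above the resolution limit, flat within-phase concentrations
with mild smooth texture, additive offset, Gaussian noise, no optical blur.
They do not validate performance on real data with anisotropic PSFs,
sub-resolution droplets, intranuclear structures (nucleoli), depth-dependent
attenuation or chromatic mis-registration; on real images the recovered
quantities are *relative* concentrations and the φ bias analysis above
applies.

## Problem sizes and runtime

Full-size studies (recovery: 40 images; model selection: 50 + 50 scenes) run
on 24 × 128 × 128 stacks in ~1–2 minutes each on one CPU. The
regime-discrimination study repeats 40-image series 100× per mode, so it
uses reduced 12 × 48 × 48 stacks with k ∈ {2, 3} and 2 fit starts (k = 4
refines dense-phase substructure but cannot move the component-2 threshold
the verdict depends on), finishing in ~7 minutes; `scripts/acceptance.py`
runs 30 replicates per mode (~4 minutes total). Fits use analytic Jacobians
with `scipy.optimize.least_squares` (trf).

## Auxiliary quantifications

FRAP traces are affine-normalised (max → 1, min → 0); traces whose signal
dropped by less than 50 % of the pre-bleach mean at the bleach frame are
flagged excluded rather than rejected; the normalised plateau estimates the
mobile fraction. Co-localisation is pixelwise Pearson r inside a mask
(default: union of per-channel Otsu foregrounds, since whole-image
correlations are inflated by shared dark background; whole-image and custom
masks available). Transects sample both channels along a discretised line in
one z-plane with nearest-voxel stepping (interpolation optional). Integrated
intensity sums a z sum-projection after subtracting the mean of a 10 × 10
pixel background ROI (default: the dimmest image corner) and divides by the
slice count, so stacks of different depth are comparable. Group comparisons
use the two-sided Mann–Whitney U with tie correction and the conventional
star mapping (*** < 0.001, ** < 0.01, * < 0.05).
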