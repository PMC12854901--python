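# condensate-quant

Quantitative confocal analysis of synthetic biomolecular condensates in plant
cell nuclei. Engineered scaffold proteins (e.g. RGG-domain fusions expressed
in *Nicotiana benthamiana*) demix into bright droplet-like condensates; this
package turns 3D fluorescence stacks of such nuclei into phase-separation
physics: the scaffold concentration in the dilute phase (nucleoplasm, C_dil)
and dense phase (condensates, C_den), the condensate volume fraction φ, and —
across many nuclei spanning a range of expression levels — a classification of
whether the system behaves like simple binary phase separation (both phase
concentrations pinned at the binodal, only φ growing with total concentration
C_tot) or like a multicomponent system (tie-lines shifting, so C_dil and C_den
themselves climb with C_tot).

It is aimed at plant synthetic-biology and condensate-biophysics labs who
image nuclei as z-stacks and want the full pipeline — segmentation,
per-compartment concentrations, object statistics, cross-image thermodynamic
analysis — reproducible from the command line or from Python, plus a
ground-truth simulator to validate every stage.

## The pipeline

Per image (all tunables in `RunConfig`):

1. 3D median filter, 5 × 5 × 3 (y, x, z) kernel, edge replication.
2. Background subtraction using the mode of the full 3D intensity
   distribution (256-bin quantisation; the lowest prominent count mode).
3. Intensity-weighted histogram (each voxel contributes weight ∝ its own
   intensity, which makes the rare bright dense phase fittable).
4. Least-squares fits of k = 2, 3, 4 component Gaussian sums
   f(x) = Σᵢ aᵢ·exp(−(x−μᵢ)²/2σᵢ²) with constrained per-component bounds;
   the model with the highest adjusted R² (= 1 − (RSS/(n−p−1))/(TSS/(n−1)),
   p = 3k) is selected, ties resolving to the smaller k.
5. Thresholds at μ + 3σ: the first (background) component's threshold
   segments the nucleus (largest 26-connected component, holes filled), the
   second (nucleoplasm) component's threshold segments the condensates.
6. Metrics: C_tot/C_dil/C_den as mean voxel intensities over
   nucleus / nucleoplasm / pooled condensates, φ as a voxel-count ratio,
   per-object volumes from 26-connected components (min_size filter).

Per series: Pearson correlation of each metric against C_tot, binned
mean ± SEM profiles, and a regime verdict (binary-like / multicomponent-like /
indeterminate) that combines correlation significance with a robust
effect-size guard. Auxiliary analyses: FRAP trace normalisation (max → 1,
min → 0, with the ≥ 50 % bleach-depth inclusion rule), pixelwise Pearson
co-localisation, line transects, sum-projection integrated intensity as a
semi-quantitative protein level, and Mann–Whitney U group comparisons.

The synthetic-scene generator produces ellipsoidal nuclei with non-overlapping
spherical condensates whose intensities obey mass balance
(C_tot = φ·C_den + (1−φ)·C_dil, C_den = pc·C_dil), plus detector offset,
smooth within-phase texture, optional Gaussian PSF and Gaussian/Poisson noise
— with exact ground truth for every stage.

## Worked example

```python
from condensate_quant import SceneParams, generate_scene, analyze_image

img, truth = generate_scene(SceneParams(rng_seed=42))
report = analyze_image(img)
m = report.metrics
print(f"k = {report.fit.k}, adjusted R^2 = {report.fit.adjusted_r_square:.4f}")
print(f"C_dil  {m.c_dil:6.1f} a.u.  (truth {truth.true_c_dil:6.1f})")
print(f"C_den  {m.c_den:6.1f} a.u.  (truth {truth.true_c_den:6.1f})")
print(f"phi    {m.volume_fraction:.4f}   (truth {truth.true_volume_fraction:.4f})")
print(f"{m.n_condensates} condensates, mean volume {m.mean_condensate_volume:.2f} um^3")
```

prints

```
k = 3, adjusted R^2 = 0.9981
C_dil    66.7 a.u.  (truth   69.0)
C_den   648.1 a.u.  (truth  689.7)
phi    0.0459   (truth 0.0498)
6 condensates, mean volume 1.13 um^3
```

i.e. the fit identified background, nucleoplasm and dense phase (k = 3) and
recovered both phase concentrations within a few percent of the generating
values; dense-phase estimates on this scene's small droplets (r ≈ 0.75 μm)
are biased a few percent low because the median filter erodes droplet
boundaries (see `docs/methods.md`).

The same workflow from the shell:

```bash
condensate-sim series --mode multicomponent --n-images 42 --seed 1 --out scenes/
condensate-quant series scenes/multicomponent_*.tif --out results/  # skips *_labels
condensate-quant image scenes/multicomponent_000.tif
```

`analysis/01…04_*.py` run the complete study narrative (simulate both
thermodynamic regimes, characterise every image, classify the regimes,
auxiliary quantifications) and write their tables under `results/`.

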