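# Methods

`mmphantom` builds annotated, inherently co-registered multimodal abdominal
volumes from a digital phantom and uses them to validate image-quality
metrics and deformable-registration settings. This note records the models,
the defaults and their rationale, the numerical choices, and the limits of
what the desk-scale validation demonstrates.

## Procedural phantom

The anatomy is a 3D integer label map. Organs are parameterized
superellipsoids and axial tubes composited back-to-front with fixed
precedence (vessels over liver over body), which guarantees a partition of
the volume: every voxel carries exactly one organ id. The mandatory set is
body, two lungs, liver with interior vessel tubes, two kidneys, spleen,
stomach, spine and aorta; arms are optional because only the MRI protocol
images them. Per-organ radii are jittered by `Uniform(1 - j, 1 + j)` with
`j = 0.05` by default so each seed is an individual. The default grid is
96³ voxels at 2 mm isotropic spacing (a 19.2 cm abdominal cube) — large
enough for realistic organ topology, small enough that the complete
pipeline, including B-spline registration, runs in minutes on one CPU.

This phantom is a geometric stand-in: it has no anatomically accurate
vascular tree, no bowel/bladder variability, no couch, and its organ shapes
are smooth. All downstream machinery consumes only the label map and so is
indifferent to these simplifications, but quantitative results on this
phantom do not transfer numerically to clinical anatomy.

### Respiration model

Two amplitudes drive the exhaled-to-inhaled displacement field, because
those are the physiologically dominant degrees of freedom: peak diaphragm
excursion (superior–inferior, default 15 mm — a typical free-breathing
excursion) and chest expansion (anterior, default 6 mm). The diaphragm
component is an axial Gaussian window centered on the diaphragm plane; the
chest component is weighted by a quadratic anterior–posterior window. Both
are Gaussian-smoothed (12 mm), forced to zero at the inferior and posterior
volume boundaries, and rescaled so the per-component peak equals the
requested amplitude exactly.

The inhaled phantom is *defined* as the exhaled labels warped through this
field (pull-back, nearest-neighbor), so the stored field is exact ground
truth by construction rather than an approximation of one. Field inversion
for round-trip checks uses fixed-point iteration
`d_inv(x) = -d(x + d_inv(x))` (25 iterations), accurate for smooth
respiratory-scale deformations; the liver round-trip Dice is ≈ 0.995 at the
default amplitudes, which is the practical ceiling registration can aim for.

## Modality simulation

* **CT/CBCT**: per-organ linear attenuation µ(E) on a 90–120 keV grid in
  5 keV steps (no interpolation off-grid), converted to Hounsfield units via
  `HU = 1000 (µ - µ_water)/µ_water`. The built-in attenuation table uses
  broad tissue classes with a mild downward energy trend; lung is pinned at
  0.24 × water so simulated lung reads −760 HU, matching the value the
  full-scale torso model assigns. The table (and µ_water per energy) is a
  CSV-editable fixture, not a measurement.
* **CBCT field of view**: a cylinder (axial disk × z-extent) centered on the
  liver centroid, default radius 60 mm; voxels outside are set to the window
  floor. The cylinder models a C-arm's narrow reconstruction volume.
* **MRI**: the steady-state spoiled gradient-echo (VIBE) signal
  `SI = ρ sin α (1 − E1)/(1 − cos α · E1) · exp(−TE/T2)`, `E1 = exp(−TR/T1)`,
  with protocol defaults TR = 7.25 ms, TE = 4.54 ms, α = 10°. T1/T2 (3 T) and
  relative proton density are literature-typical per-tissue defaults. Each
  organ's (T1, T2, ρ) is independently scaled by `Uniform(0.95, 1.05)`
  per volume (drawn per organ, not once per volume) to emulate
  inter-subject variability; the random stream iterates the catalog in id
  order so it is independent of which organs happen to be present.
* **Windowing**: CT [−1024, 1500] HU, CBCT [−1024, 2000] HU fixed; MRI uses
  the 10th/90th percentile of the whole 3D array, background included, since
  MR intensities have no absolute scale. Values are clipped then mapped
  affinely onto [−1, 1] (order-preserving inside the window).
* **Textured noise**: white Gaussian noise shaped slice-wise in the 2D
  Fourier domain by a radial magnitude profile |H(f)| and scaled so the
  liver-region standard deviation equals the requested magnitude. This
  produces "patient-style" volumes with controllable noise texture so the
  realism metrics and the registration harness can be validated without a
  trained network or clinical data. It does not emulate streaks, metal
  artifacts, bias fields, or spatially varying noise.

Because every modality is painted onto the same label map, the volumes are
co-registered voxel-for-voxel before FOV masking — the property that makes
the dataset a registration ground truth.

## Translation networks

The style-transfer stage is an unpaired two-domain translation (CycleGAN):
ResNet generators (encoder, n residual blocks, decoder, tanh output) and
70 × 70-receptive-field least-squares PatchGAN discriminators. The generator
objective adds two terms to the usual adversarial + cycle losses: an
intensity L1 loss `|G(x) − x| + |F(y) − y|` (meaningful because the phantom
is initialized in the target modality's intensity scale, making the
translation monomodal) and a gradient-difference loss that compares absolute
forward-difference gradients, counteracting blur. Weight presets
λ_cyc/λ_int/λ_gdl are 10/10/5 for CT and CBCT and 10/0.4/0.4 for MRI.
Pushing λ_int/λ_gdl much higher over-regularizes the objective and drives
the generator toward an identity mapping — a regime the reduced-scale tests
exploit as a convergence check.

Loss conventions: all image losses default to the per-pixel mean so the λ's
are resolution-independent; the raw-sum variant is exposed for exact
small-grid arithmetic. The gradient-difference loss omits the boundary
row/column (sums over valid i−1, j−1). The adversarial term sums both
generators' least-squares terms. Optimizer: Adam (β₁ = 0.5), constant
learning rate 2 × 10⁻⁴, batch 4, one random patch per axial slice
(reflect-padded when a slice is smaller than the patch).

The networks run on a small in-package numpy layer framework (im2col
convolution, instance normalization, manual backprop) whose gradients are
verified against central finite differences in float64. Default training
scale is desk-size — 64 × 64 patches, width 16, two residual blocks,
hundreds of steps — chosen so a training run finishes in minutes on one
CPU core; the full-scale recipe (256 × 256, width 64, nine blocks, 150 000
steps) is reachable through the same arguments but is not exercised by the
tests. Consequently the tests validate the objective's mechanics
(component logging, determinism, the identity regime, loss algebra), not
photorealistic synthesis.

## Image-quality metrics

*Fidelity vs. phantom* (one-to-one correspondence exists): MAE excluding
background; SSIM and FSIM computed per axial slice and averaged (volumes are
compared slice-wise); EPR/EGR from Canny edge maps (σ = 2 by default,
identical parameters on both images): EPR = |E_ref ∧ E_test|/|E_ref|,
EGR = |E_test ∧ ¬E_ref|/|E_ref|, so EGR may exceed 1 when synthesis
introduces texture. FSIM is implemented in-package (log-Gabor phase
congruency, 4 scales × 4 orientations, without noise-floor compensation,
combined with Scharr gradient magnitude and the standard stabilization
constants on a [0, 255] scale); identical images score exactly 1.

*Realism vs. reference* (no correspondence): the radial noise power
spectrum is estimated from 2D axial patches (default 16², stride 8) lying
entirely inside the liver ROI — second-order polynomial detrending, Hann
window, averaged periodograms, annular binning over in-plane frequency in
cycles/mm, normalized so white noise of variance σ² gives a flat level of
σ²·Δx·Δy. Two spectra are compared by Pearson correlation on a common grid
(NCC). Noise magnitude is the sample standard deviation of liver voxels;
HistCC is the Pearson correlation of density-normalized intensity
histograms (the background peak can optionally be dropped; by default it is
kept, and cropping it is treated as a display choice).

The Gaussian anchor `E|X|/sd(X) = sqrt(2/π) ≈ 0.80` gives MAE/NM ratios an
interpretation: a measured ratio near 0.8 is compatible with pure Gaussian
noise, while the published full-scale ratios (2.1/1.3/1.5 for CBCT/CT/MRI)
indicate structured change beyond noise. The package bundles that published
per-modality summary purely as reference numbers for this bookkeeping.

## Registration benchmark

Inhaled CT/CBCT/MRI are registered to exhaled CT with a B-spline free-form
deformation (SimpleITK backend): gradient descent, learning rate 1, up to
300 iterations, full-image metric sampling by default (deterministic;
seeded random sampling optional). Metrics: Mattes mutual information with
50 bins, normalized correlation, and mean squares (monomodal CT–CT only —
requesting MS across modalities is an error). Control-point spacing sweeps
50–150 mm in 20 mm steps, giving 18 monomodal and 12 multimodal settings.
Liver masks are closed with a 3-voxel ball (both fixed and moving masks)
after merging interior vessel labels, then propagated with nearest-neighbor
resampling; scoring is the Dice coefficient, aggregated as mean and
10th/90th percentiles per setting. B-spline order is SimpleITK's default
(cubic); no multi-resolution schedule is used at desk scale.

Degenerate inputs are errors, not silent defaults: empty liver masks,
both-empty Dice operands, off-grid tube energies, constant volumes under
percentile windowing, and constant spectra under Pearson correlation all
raise.

## What the desk-scale validation shows — and does not

The suite demonstrates that (i) the ground-truth displacement machinery is
self-consistent to Dice ≈ 0.995, (ii) registration at the
best-reported setting (MMI, 50 mm) improves liver overlap on synthetic
pairs, (iii) the NPS estimator recovers known spectral shapes (r > 0.95),
(iv) the loss algebra matches brute-force arithmetic exactly, and (v) the
training loop is deterministic and converges to identity under extreme
regularization. It does not — and cannot, without clinical data and
full-scale training — validate photorealism of synthesized images or
reproduce full-scale image-quality tables; those quantities depend on the
target-domain data distribution.
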