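# Methods

This note documents the models, parameter choices and numerical conventions
behind `mesomap`, and what the synthetic data do and do not establish.

## Coordinate and data conventions

Images are 0-based, row-major, origin top-left; x = column; the atlas
midline is a vertical column (midline_col = (width−1)/2, so even-width
grids have a half-pixel midline and the brain mask is exactly mirror
symmetric). Movies are time-first arrays (T, H, W); reflectance stacks are
(wavelength, T, H, W). All time windows are half-open [t0, t1).
Concentrations are molar changes from baseline; ΔHbT ≡ ΔHbO + ΔHbR is
asserted after every transform.

The default atlas is 128×128 px at 0.078 mm/px (a 512×512 sensor binned
4×4, ~1 cm² field of view); desk-scale experiments use 64×64 at
0.156 mm/px, which preserves the field of view while keeping movies small.
The three registration landmarks (anterior coronal-vessel junction,
sagittal-suture point, lambda) all lie on the midline and are therefore
collinear; `fit_affine` rejects collinear triples, so synthetic studies are
generated directly in atlas space and the affine path is validated with
non-collinear fixtures. Real camera-space data would need an off-midline
landmark or a lower-order (similarity) fit.

## Optics and spectroscopy

The forward model is R_λ(t) = exp(−[ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·L(λ))
with baseline reflectance 1 by convention; the inversion solves the
pathlength-weighted extinction system by orthogonal least squares
(pseudoinverse), so any ≥2 wavelengths are handled uniformly and the
4-LED system is solved consistently (condition number ≈ 3.7, logged).
Extinction coefficients are a bundled, coarse-grid compilation after the
standard OMLC tabulation of human hemoglobin (see
`src/mesomap/data/hb_extinction.csv`); values are smooth interpolants, not
bit-exact copies, with the isosbestic point planted at 586 nm. Pathlength
factors are synthetic working values with the correct qualitative
wavelength dependence (longer paths in the red); both files are versioned
and overridable through `OpticsModel`. No claim of numerical agreement
with any specific instrument calibration is made — the same optics model
is used forward and inverse, which is what the round-trip and recovery
guarantees require.

## Synthetic cortex generator

The generator defines the study conditions; its defaults are fixed and the
tests measure recovery under them.

**Resting networks.** Ten Gaussian nodes (five homotopic pairs: motor M1,
forepaw S1FP, hindlimb HL, retrosplenial RS, visual V1; footprint
σ = 0.03·width) carry zero-mean unit-SD time courses drawn with an exact
matrix square root of the target correlation matrix (homotopic r 0.5–0.7,
anterior–posterior anticorrelation −0.4 between M1 and V1; PSD verified at
construction). Pixel HbT = Σ footprints × time courses × 1 µM + white pixel
noise (relative SD 0.1) + an optional shared global fluctuation (relative
SD 0.3 in the study runner, 0 otherwise) that gives global signal
regression something to remove. Node fluctuations are white at the
analysis sampling rate, so empirical Fisher-z correlations converge to the
targets with the textbook SE ≈ 1/√(n−3).

**Hemodynamic coupling.** ΔHbR = −0.4·ΔHbO by default (activation raises
HbT and lowers HbR); exposed as a parameter since the ratio is
preparation-dependent.

**Evoked responses.** The stimulus boxcar is convolved with a
gamma-variate impulse response (peak 2 s, FWHM 3 s — chosen to reproduce
the several-second spread of photostimulus-evoked activity) and normalized
to unit peak, so the planted amplitude (default 5 µM HbT) is the exact
peak concentration change at the node center. Paradigms: electrical
forepaw 5 s rest / 10 s stim (3 Hz) / 35 s rest × 18 blocks;
optogenetic 10 s stim (10 Hz pulses) / 50 s rest × 30 blocks. Desk-scale
runs use 6 blocks and 2 Hz sampling; block counts and rates are paradigm
parameters, not analysis constants.

**Lesion and remapping.** A lesion disc attenuates the amplitude of every
node whose center it covers (evoked and resting) from week 1 onward; a
remap site switches on at a configurable session with a configurable
fraction of the original amplitude (study defaults: 0.9 for the
unstimulated group, 0.3 for the stimulated group, emulating strong vs
suppressed remapping).

**Photostimulation sessions.** The driven site's time course propagates
through a spatial coupling map: the target footprint, plus a broad
positive background spread (amplitude 0.15, σ = 0.31·width), plus a
Gaussian annulus (radius 0.19·width, σ = 0.047·width) scaled by the
surround weight. Negative weights create an anticorrelated ring whose area
grows smoothly and monotonically with |weight|; with weight 0 and no noise
the coupling map is strictly positive and the inhibition index is exactly
0.

**Ancillary tables.** Paw-use asymmetry scores are drawn per group from
Normal(mean, SD) and converted to contact times with a fixed 40 s
single-paw total; qPCR Ct values are reference-gene Ct (~18) plus
per-gene baselines minus planted log2 effects plus Normal(0, sd) noise, so
the comparative-Ct method recovers fold changes of exactly 2^effect in
expectation.

All generators are pure functions of (parameters, seed); the study runner
derives per-task seeds from the master seed with a keyed hash.

## Analysis conventions and numerical choices

* **Filtering:** 5th-order Butterworth, applied forward–backward
  (zero-phase `sosfiltfilt`); band edges 0.009–0.08 Hz (resting) and
  0.009–0.5 Hz (task). Downsampling is non-overlapping block averaging
  (anti-aliasing by integration).
* **QC:** a run is rejected when its global-trace variance exceeds 5× the
  median across runs or its maximum frame-to-frame jump exceeds 10× the
  median (defaults, configurable).
* **GSR:** OLS projection of every pixel trace onto [global trace,
  constant]; a relative guard skips the projection when the global trace
  is at round-off level, which also makes GSR exactly idempotent.
* **Evoked metrics:** threshold comparisons are inclusive (≥); the peak
  window is ±2 s around stimulus offset; activation magnitude is the
  maximum within the group's established response region (defined from
  baseline and week-4 group maps at the 75% threshold), so attenuated
  responses remain measurable; activation area counts suprathreshold
  pixels and contributes 0 when empty while a missing magnitude (empty
  region) propagates as NaN, excluded from group means by default.
* **RSFC:** Fisher z with |r| clipped to 1−10⁻⁷; self-pairs excluded
  everywhere; node degree counts positive exceedances of z ≥ 0.4 only.
  Pixelwise matrices are computed on a 2× spatial downsample by default
  (logged) to bound memory.
* **Spatial PCA:** eigendecomposition of the symmetric group difference
  matrix after symmetric double mean-centering (row + column − grand mean),
  which removes each unit's mean connectivity offset while preserving
  symmetry and the trace identity Σλ = tr(centered). Variance fractions
  are signed, λ/Σ|λ| — equal to λ/trace for PSD inputs and bounded for
  difference matrices whose spectrum straddles zero. The permutation test
  shuffles group labels (3000 iterations at full scale; 200 in desk-scale
  runs), compares the first two observed eigenvalues to the null's 90th
  percentile, and warns when fewer distinct permutations exist than
  iterations. Raw eigenvalues are the default statistic; a
  variance-fraction mode is available.
* **ROI derivation:** symmetrize about the midline, Gaussian smooth
  (σ = 2 px default, unconstrained by any stated value), threshold at 85%
  of the positive maximum and negative minimum, split 8-connected
  components at the midline.
* **Inhibition index:** strict r < 0 pixel count (area reading); a
  magnitude-weighted Σ|r| mode is provided because the wording "summing
  anticorrelated pixels" admits both readings. No band-pass is applied to
  block-averaged photostim traces — averaging 30 blocks is the denoiser.
* **Behavior:** percent paw use is computed from single-paw contact times
  only (both-paw time excluded from numerator and denominator).
* **Expression:** fold changes are reported on the relative (2^−ΔΔCt)
  scale while t-tests run on the log (ΔΔCt) scale, which is
  variance-stabilizing; clustering uses average linkage on Euclidean
  distances of row-normalized profiles with a canonical child order
  (subtree containing the lexicographically smallest row label first), so
  the leaf order is a function of the tree alone.
* **Statistics:** Welch t with Welch–Satterthwaite dof wraps scipy;
  BH-FDR wraps statsmodels; Cohen's d uses the two-group pooled SD with
  n−1 weights. Repeated-measures ANOVA / mixed models are deliberately not
  reimplemented; the pipeline consumes p-value tables from standard
  routines (paired/Welch t here).

## Validation experiments and their scope

The validation suite (`mesomap.experiments`, asserted in
`tests/test_acceptance.py`, recomputed by `scripts/acceptance.py`) checks:
machine-precision forward/inverse spectroscopy; recovery of all 45 node-pair
correlations within the 2/√(n−3) sampling band (pooled over 20 seeds of
300 samples — note that this experiment deliberately omits the narrow
resting-state band-pass, because filtering white planted dynamics would
shrink the effective sample size and invalidate the 1/√(n−3) yardstick;
the filter's own behavior is tested separately on sinusoids); read-out of
an 80% lesion attenuation as ~20% normalized magnitude and ≥70% area loss;
exact agreement of node degree with a brute-force count; exact recovery of
planted PCA variance fractions (0.52/0.18 atop a spread of small
components) and the trace identity; calibration of the permutation
criterion's null firing rate (~10%; a 200-run estimate has Monte-Carlo SD
≈ 2.2 percentage points); strict monotonicity of the inhibition index in
the surround weight; and bit-identical study tables across repeated
fixed-seed CLI runs.

Problem sizes are deliberately desk-scale (64×64 or 48×48 grids, 3–5 mice
per group, 6 blocks, 200 permutation iterations); every size is a
parameter, and the same code paths run at full scale.

**What passing does not show.** The generator emulates the structure of
real widefield data — planted correlations, block responses, lesion
geometry, group effects — not its physics. There is no photon-transport
model, no vascular anatomy, no motion or physiological (pulse/respiration)
artifacts, and noise is white and Gaussian. Recovery of planted parameters
therefore validates the analysis code, not the biological interpretation
of any particular dataset; headline effect sizes from real studies are not
reproduction targets here.

## Known limitations

* The permutation test with very small groups (3 vs 3) has only 20
  distinct label partitions; the implementation warns and proceeds, but
  significance at the 90th percentile is then rarely attainable — the
  study runner reports it honestly.
* `variance_explained` is signed; consumers ranking components should use
  its absolute value when the spectrum straddles zero.
* Registration assumes three non-collinear landmark pairs; midline-only
  landmark sets require an external third point.
* The QC thresholds, smoothing σ, and pathlength factors are working
  defaults, configurable but not calibrated to any instrument.
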