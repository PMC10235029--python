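# Methods

This note documents the models, numerical choices and limitations of the
package in its own right: what each stage computes, which knobs matter,
what the synthetic generators do and do not emulate, and where the design
was genuinely open.

## Spectral model and conventions

All spectral quantities use natural logarithms internally; decibels
(10·log₁₀ for power quantities) appear only at reporting boundaries, which
keeps the block-wise model exactly linear in its three parameters.
Attenuation is carried in Np·cm⁻¹·MHz⁻¹ (1 Np = 8.686 dB; a dB/cm/MHz
view is a reporting option only).  Frequencies are in MHz on explicit
grids; the default analysis band is 4–18 MHz, and `usable_bandwidth`
trims it to the largest contiguous run of the ROI-mean spectrum above
−20 dB relative to its peak.

The log spectral ratio per block is

    Y(f, z) = ln Δb(z) + Δn(z)·ln f − 4 f·Δa(z),

with `Δa` the cumulative attenuation in Np/MHz.  The integration origin is
not dictated by the physics alone, so the package fixes it: depth 0 at the
transducer-proximal edge of the analysis region, midpoint rule per block
row (row *i* integrates full steps over rows 0..i−1 plus half a step of
row *i*).  A consequence worth knowing: the forward finite difference of a
midpoint-rule integral returns the average of adjacent rows, so a sharp
Δα edge recovered via `attenuation_from_cumulative` is smeared across
exactly one block row even on noiseless data.

### Block geometry

Blocks span 20λ × 20λ (λ = 0.14 mm at 11 MHz and 1540 m/s, the same
wavelength the envelope-SNR map uses) with 80 % overlap.  Because 80 %
overlap is rarely integral in pixels, rounding is fixed as: block side =
`round(20λ/spacing)`, step = `floor(0.2·side)` clamped to ≥ 1 px.
Coordinates are 0-based, half-open; the axial index grows with depth.
Each block's spectrum averages Tukey(0.25)-windowed, zero-padded
periodograms of its lateral lines (Welch-style across lines, no axial
sub-segmentation), then interpolates onto the analysis frequency grid.

### Envelope SNR and ROI choice

The envelope is the analytic-signal magnitude (Hilbert transform per
lateral line).  SNR = mean/population-sd per block; a constant block has
undefined SNR and is marked NaN and excluded from ROI search rather than
raising, so edge blocks cannot kill a run on real data.  The ROI is the
sub-window (default: half the fixed region per axis — the source protocol
does not state its subsection size) whose mean SNR is nearest
√(π/(4−π)) ≈ 1.9131; ties break toward the smallest (axial, lateral)
origin, and when every window sits below the target the argmin is still
returned with a logged warning.

## RPL-TV inversion

The three maps are estimated jointly by minimising the squared data
misfit plus weighted isotropic total variation per map, optimising over
β = ln Δb so positivity of Δb is automatic.  The TV weights are
dimensionless on the natural-log-scale maps with defaults
μ_b = 1, μ_n = 10³, μ_a = 10³.

**Solver.** Lagged-diffusivity IRLS (majorize–minimize) on the
ε-smoothed isotropic TV objective (ε = 10⁻⁶).  Each iteration solves one
sparse symmetric system coupling the three maps through the 3×3 spectral
normal matrix and each map to its spatial neighbours through the
reweighted Neumann-boundary Laplacian; the solve is exact (sparse direct),
so the smoothed objective is guaranteed non-increasing across iterations —
the property the tests assert.  This solver was chosen over
ADMM-with-splitting precisely because ADMM does not guarantee a monotone
objective; both share the μ→0 limit, which is the per-block OLS fit on
regressors [1, ln f, −4f] (`per_block_ols`, kept as the test oracle).
Stopping: relative objective change < 10⁻⁶ or 500 iterations, whichever
first; running out of iterations sets a `converged=False` flag instead of
raising.  Initialisation is the unregularized (OLS) solution, making the
solver fully deterministic.

A subtlety of TV on the *cumulative* attenuation: the TV of a monotone
axial ramp equals its total rise regardless of how the rise is
distributed, so the penalty removes non-monotone noise wiggles (sign
flips in Δα) and smooths laterally without flattening genuine attenuation
— unless μ_a is large enough that trading total rise against data misfit
pays, which is why "exact recovery of constant truth under any μ" holds
only when Δα = 0.

Δα is the forward finite difference of Δa divided by the axial block step
(cm), last row replicated so the map keeps the grid shape.
ΔBSC(f) = Δb·f^Δn is evaluated pointwise on the block maps (the
subject-level ΔBSC feature is the median of that map, not the formula
applied to median Δb and Δn — medians do not commute with the product).

**Features.**  Per frame, the ROI median of Δb (dB), Δn, Δα, ΔBSC@11 MHz
and SNR; per subject, the arithmetic mean of those medians over the frame
sequence (20 frames in the emulated protocol).

## Synthetic data

The generators exist so that every downstream stage has testable ground
truth; they emulate the *statistical* structure of an in-vivo steatosis study,
not the acoustics of a particular scanner.

**Spectra** (`simulate_spectra`): exact forward evaluation of the model
above plus i.i.d. Gaussian noise on Y — the idealised regime in which the
inversion is identifiable, used for oracle-equivalence and
noise-advantage tests.

**RF speckle** (`simulate_rf`): white Gaussian scatterer field scaled by
√Δb, filtered in overlapping axial segments (Hann analysis windows,
50 % overlap, zero-padded FFTs so the convolution is linear, edge margins
cropped) by a Gaussian-modulated pulse spectrum times the depth-cumulative
attenuation e^(−2a(z)f) and the backscatter weighting f^(Δn/2) — amplitude
filters, so block power spectra follow the power-law model.  Linear
filtering preserves Gaussianity, hence the envelope of a homogeneous
region is Rayleigh and its SNR converges to 1.9131 (verified to ±0.01 on
millions of samples).  Not emulated: diffraction, elevational focusing,
nonlinear propagation, electronic noise, or any scanner transfer function
beyond the Gaussian pulse — so passing tests certify the processing
chain, not robustness to real-probe artefacts.

**Histology** (`make_histology_image`): eosin-pink background (luminance
≈ 130) with bright non-overlapping discs (luminance ≈ 235, radii 5–15 px)
placed until the disc-area fraction hits the target within ±0.5
percentage points; when blind rejection sampling jams, free sites are
located from the Euclidean distance transform of the unoccupied space,
the inter-disc gap relaxing from 3 px (which guarantees the radius-5
opening downstream cannot bridge neighbours) toward 1 px, and the
fill-in radius down to 3 px as a last resort.  Elongated bright
distractors (aspect ≥ 3, vessel-like) are drawn but excluded from the true
mask — a constructive stand-in for the manual removal step of the
original protocol.  Not emulated: staining variability, nuclei,
out-of-focus blur, uneven illumination.

**Cohort** (`make_cohort`): group sizes 24/15/16 for grades 0/1/2.  Each
subject draws its fat fraction from the grade's truncated normal
(1.28±1.26 %, 20.36±7.36 %, 45.23±9.74 %, truncated to the Brunt
interval).  Feature locations follow a piecewise-linear interpolation of
the per-grade feature medians against the grade-mean fat fractions, with
the end segments extended linearly (acoustic parameters keep rising with
fat content beyond the grade-2 mean), plus Gaussian noise.  The noise sd
is 0.6·IQR/1.349 of the grade's configured IQR: roughly 60 % of the
configured spread is attributed to fat-independent variation, the rest
arising from the within-grade fat-fraction variation itself.  Δn is
generated grade-independent (its group differences are not significant in
the emulated study).  A single `noise_scale` multiplies every random
spread, so zero collapses each subject onto its grade's medians.  Tables
are bitwise reproducible under the seed.

## Histology quantification

Grayscale (luminance) → global threshold (default 180, Otsu optional;
bright, unstained vacuoles lie above it) → erosion then dilation with a
radius-5 disk (the original non-flat ball element's offset height is
irrelevant on binary data) → 8-connected labeling → deterministic shape
filter: keep components with circularity 4πA/P² ≥ 0.4 and aspect ratio
≤ 3 (replacing manual removal of vessels, sinusoids and cracks) → fat
fraction = retained area / image area.  Multiple sections of one subject
average their fractions.  Grade intervals: 5 and 33 inclusive to grade 1,
66 inclusive to grade 2, matching "<5, 5–33, >33–66, >66".

## Regression and statistics

`FatFractionGPR` wraps a Gaussian process with kernel
σ_f²·exp(−‖x−x′‖/ℓ) (a single shared length scale over the z-scored
4-feature space) plus white noise, zero mean function, hyperparameters by
multi-start (5 restarts) maximisation of the log marginal likelihood with
a fixed seed.  Features entering the model: Δb (dB), Δα, ΔBSC@11 MHz,
SNR; Δn stays in summaries but out of the model (no steatosis trend).
Leave-one-out cross-validation refits the scaler and the GP on each n−1
training fold — the held-out subject never contributes to the
standardization statistics (asserted structurally in tests) — and the
held-out prediction is clamped at zero.  R² and RMSE pool all n held-out
predictions; classification grades those pooled predictions via the Brunt
intervals, with the binary task merging grades ≥ 1.  Train-side
accuracies average the per-fold training predictions over the LOO models.

Group screening uses the Kruskal-Wallis test (tie-corrected H, chi-square
p with groups−1 df) at the 0.01 significance level; cohort summaries
report median(IQR) per grade with linear-interpolation (type-7) quartiles
and fat fraction as mean±sd.

## Pipeline

`pipeline.run` executes the stages in dependency order under one global
seed; each random stage derives its seed from the global seed and the
stage name, the manifest records inputs, outputs, SHA-256 content hashes,
seeds and durations, and re-runs skip stages whose recorded hashes still
match.  Output bundles are CSV/JSON/HDF5/PNG only; no plotting dependency
is required.

## Problem sizes and defaults used in the checks

The solver and property checks run on deliberately compact synthetic
problems chosen to exercise the mathematics at desk scale: 16×16 or
20×20-block grids with 30 frequencies for the inversion checks, 512×512
histology images, a 55-subject cohort for the end-to-end regression, a
~6.8-million-sample speckle volume for the Rayleigh-SNR limit, and 2000
replicates for the Kruskal-Wallis null calibration.

## Known limitations

* The speckle simulator's nearest-neighbour map lookup quantises
  coefficient boundaries to RF pixels; sub-pixel boundary placement is
  not modelled.
* TV regularization is applied per 2-D frame; no elevational (3-D)
  coupling.
* The Δα map inherits the one-row edge smear of differencing a
  midpoint-rule integral (see above).
* The reference phantom's absolute parameters are synthetic declarations;
  only relative (sample-minus-reference) quantities are meaningful
  anywhere in the pipeline.
* Grade-3 livers are absent from the emulated cohort; the regression extrapolates there only through the
  monotone trend of its features.
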