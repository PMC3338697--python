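# Methods

## Physical model

The sample is an effectively two-dimensional membrane carrying fluorescent
entities ("n-mers": n subunits co-localized below the PSF width). Entities
are placed by a homogeneous spatial Poisson process; entity brightness is
`per_subunit_brightness × (number of labeled subunits)`, with each subunit
labeled independently with probability `label_fraction`. The microscope's
illumination/detection profile is a 2D Gaussian `g(r) = exp(-2 r²/ω₀²)` with
e⁻² radius ω₀; the confocal axial dimension is collapsed because the
membrane is thin compared to the axial PSF extent. A pixel samples the field
at its center (no within-pixel integration — pixel size is required to be
smaller than ω₀, making the difference negligible).

Densities are expressed per **beam area** `BA = ∫g dA = πω₀²/2`. With that
convention the mean pixel intensity is exactly `⟨I⟩ = Σᵢ Nᵢ εᵢ` and, by
Campbell's theorem for shot-noise fields, all spatial cumulants of the
noise-free image are

```
κ_n = γ_n Σᵢ Nᵢ εᵢⁿ ,   γ_n = (∫gⁿ dA)/(∫g dA) = 1/n .
```

The quantal brightness ε is defined as the peak pixel intensity one
fluorophore contributes when it sits exactly at a pixel center, per pixel
dwell, in detector intensity units (iu). No cross-scan-speed normalization
is applied: calibrations made under different acquisition settings are
keyed by an `acquisition_tag` and never mixed.

Assumptions the model makes: no quenching between subunits (a dimer is
exactly twice as bright as a monomer), no diffusion during the scan (fixed
samples), no FRET, no blinking, spatially uniform illumination and
background.

## Detector model

Analog PMTs convert photocurrent to an intensity with noise whose variance
grows linearly with the signal. The package models the measured value as
`M = I + η` with `η | I ~ Normal(0, c + s·I)` (c = intercept, dark-noise
variance in iu²; s = slope in iu), valid up to `linear_max`, clamped at
`saturation`, and rounded to integer intensity units.

`fit_detector_noise` calibrates (s, c) from uniform-illumination
(mean, variance) pairs. Because real detectors leave the linear regime at
high signal, only the initial part of the curve is fitted: starting from the
three lowest means, the range is extended while R² ≥ 0.99 and the next
point lies within 3 residual SDs of the current line; `linear_max` records
where extension stopped. The intercept is a free parameter (dark noise);
an origin line is recovered as intercept ≈ 0.

### Cumulant correction

From the conditional-Gaussian law, the cumulant generating function of M is
`K_M(t) = c t²/2 + K_I(t + s t²/2)`, which gives the exact contamination
chain

```
κ₂(M) = κ₂ + c + s κ₁
κ₃(M) = κ₃ + 3 s κ₂
κ₄(M) = κ₄ + 6 s κ₃ + 3 s² κ₂
```

inverted top-down by `correct_moments`. When the analyzed pixels have had a
background offset b subtracted, the noise level is evaluated at κ₁ + b
(noise follows the raw signal). Rounding to integer bins adds a further
1/12 iu² to κ₂ that is left uncorrected — negligible against any real
signal, and accounted for in the validation tolerances.

## Moment analysis

Raw central moments are plain averages (no small-sample bias correction;
analysis regions are ≥ 64 pixels and typically ≥ 1.6·10⁴, where the bias is
negligible). Heterogeneous images are handled by a tiling strategy: ROIs at
least twice the tile size are cut into 50%-overlapping 128×128 tiles,
moments are computed about each tile's own mean (suppressing slow
gradients), tiles whose mean deviates more than 50% from the median tile
mean are discarded, and the surviving estimates averaged.

- **One population**: `ε = κ₂/(γ₂⟨I⟩)`, `N = ⟨I⟩/ε` (closed form).
- **Two populations, free α**: damped least squares on the four relative
  residuals `(γ_n(N₁ε₁ⁿ + N₂ε₂ⁿ) − κ_n)/|κ_n|` in log-parameter space
  (positivity by construction), multi-started from α ∈ {1.5, 2, 4, 8}
  crossed with monomer-heavy/oligomer-heavy intensity splits; lowest
  residual wins; output ordered ε₁ ≤ ε₂. The solver falls back to the
  one-population solution when the two-population fit is not at least twice
  as good, or when the data are algebraically one-population.
- **Fixed α**: the tie ε₂ = α·ε₁ removes one unknown. Three cumulants would
  then determine the system, but the κ₁..κ₃ subsystem is a cubic in ε₁ with
  (generically) *two* positive roots; all four cumulants are therefore
  always used, κ₄ being the discriminator.

### Identifiability limitation, and the calibrated pipeline

The κ₄ discriminator is weak in practice: for a 50/50 monomer–dimer mixture
at α = 2 the two roots differ in κ₄ by only ~6%, while the sampling error
of κ̂₄ on a single 512² image at moderate density is ~40%. Uncalibrated
two-population inversion of measured cumulants is therefore root-unstable —
an intrinsic property of fourth-order moment analysis, not of this
implementation. The practical remedy is the same one the experimental
workflow uses anyway: measure the monomeric brightness first. With
`fix_eps1` (the monomeric control) and `fix_alpha` both given, κ₁ and κ₂
are *linear* in (N₁, N₂) and the solve is exact and well conditioned; κ₃,
κ₄ only enter the reported residual. This calibrated mode is the
recommended production pipeline and the one exercised by the mixture
validation.

Model selection follows the standard rule: fit one population first; if the
recovered ε exceeds the monomeric control by more than 2 combined standard
errors, the sample contains oligomers and the two-population (or
monomer–dimer) model is indicated.

## SpIDA

The single-particle intensity distribution ρ(k) — the intensity a particle
at a uniformly random position within a cutoff disc of radius 3ω₀
contributes to the observed pixel — is computed in closed form: the mass in
an intensity bin is the area between the corresponding Gaussian-profile
contours divided by the disc area (a slow Cartesian-grid estimator is kept
as a cross-check). Beyond 3ω₀ a particle contributes an e⁻¹⁸ fraction of
its intensity; the expected particle count in the disc is
λ = N·(πR²)/BA = 18 N.

The compound (super-Poissonian) histogram `H = Σ_n Poisson(n; λ) ρ*ⁿ` is
evaluated two ways, asserted to agree to 10⁻⁸: direct Poisson-weighted
convolution (used for λ ≤ 30; the Poisson sum is truncated at cumulative
mass 1 − 10⁻⁹) and characteristic-function multiplication
`Ĥ = exp(λ(ρ̂ − 1))` on an FFT grid (used above). Detector broadening has
an exact CF form under the linear variance law,
`E e^{-iξM} = e^{-cξ²/2} · G_I(-iξ - sξ²/2)`, so the fitting path folds
compounding and broadening into a single pass. The standalone
histogram-smearing operation (each bin replaced by a discretized Gaussian
of variance c + s·k, sub-zero mass folded into bin 0) is also provided and
agrees with the joint path.

Numerical resolution choices, validated against the simulator oracle:

- ρ is built on a fine grid of 0.25 iu cells when ε < 16 iu (quantization
  would otherwise be coarse relative to the particle brightness) or when
  the compound distribution is narrow (SD < 40 iu, so sub-bin structure
  survives into the output); 1 iu otherwise, where quantization smears
  out; intensities are aggregated to the 1-iu output bins only after
  compounding, by proportional interval overlap (an unbiased
  coarse-graining — nearest-integer assignment of fine cells is biased when
  cells straddle bin boundaries).
- Quantizing ρ sheds a small deterministic amount of each particle's mean
  intensity (the sub-cell PSF tail). It is restored by shifting ρ by its
  closed-form mean deficit, per particle, so a pixel's correction scales
  with its local particle count and empty pixels stay at exactly zero.
  After these two measures the model mean equals N·ε to < 0.1%.

`fit_histogram` performs unweighted least squares of the broadened model
against the normalized observed histogram over a window ending at the
99.9th observed percentile (a Poisson-weighted objective is available but
off by default — the unweighted form is the simplest defensible choice and
what the residual diagnostics assume). The k = 0 bin is included: at low
density it carries most of the information, which also means background
ROIs must be chosen conservatively, since clamped negative
background-subtracted pixels inflate it. Models: `one_pop` (N, ε),
`two_pop_free` (N₁, ε₁, N₂, ε₂), `monomer_dimer` (ε₂ = 2ε₁ exactly — no
quenching; ε₁ fixed to the monomeric control or fitted jointly).
Initialization comes from the one-population moment solution of the
histogram itself; fits are deterministic given the data and init. If more
than 1% of pixels are saturated the top bin is excluded and the result
flagged.

## Simulator

`simulate` is the ground-truth oracle: spatial Poisson placement with a
guard band of 3ω₀ beyond the image edges (so edge pixels see unbiased
statistics), exact Gaussian-PSF rendering at pixel centers (per-particle
patches truncated at 3ω₀), conditionally Gaussian detector noise
(matching the analog-PMT treatment above — not Poisson photon counting),
clamping and integer rounding. Identical specs and seeds produce
bit-identical images. Photobleaching series thin fluorophores (not
entities) independently each frame with the given survival probability,
keeping positions fixed.

What the simulator does *not* emulate — and hence what passing tests do
not certify about real data: axial structure and defocus, cell-shaped
masks and intensity gradients (the tiling strategy is exercised only on
constructed heterogeneous fixtures), autofluorescence texture,
non-uniform illumination, detector nonlinearity below saturation,
fluorophore blinking/quenching, and labeling stoichiometry errors beyond
the binomial `label_fraction` model.

## Validation conditions and tolerances

Standard study conditions: ω₀ = 0.2 µm, pixel 0.046 µm, detector
σ² = 2 + 0.5·I (16-bit saturation), monomeric ε = 44 iu. The density
ladder (125–4000 µm⁻², 10 seeds × 512² each) uses ε = 25 iu so the mean
intensity at the top density stays inside the detector's range. The
dimer/monomer MEU ratio uses 20 images of 512² per condition at 2 entities
per BA. Smaller properties (detector-correction identity, bleaching) use
256² images sized so Monte-Carlo error stays well below the asserted
tolerances.

Model-vs-simulation histogram agreement is measured as total-variation
distance at matched resolution: both histograms are rebinned to cells of
width ⌈SD/24⌉ iu (never finer than the 1-iu output grid). At 10⁶ pixels
the per-integer-bin sampling noise of a wide distribution (SD of hundreds
of iu) alone would exceed any useful tolerance; rebinning proportional to
the distribution's scale keeps the statistic sensitive to model error
rather than to bin-level shot noise. The model mean is asserted separately
at 0.5%.

## Degenerate inputs and tie-breaks

Empty ROIs, < 64-pixel regions, non-positive κ₂ (no signal, or
over-correction — flagged, indicating the mean left the calibrated linear
range), all-identical calibration means, < 3 calibration cells and
acquisition-tag mismatches raise typed errors. SEM of a single cell is
reported as missing, not zero. Significance stars use strict inequalities
(p = 0.05 is "ns"). The Mann–Whitney test is exact for groups ≤ 20 without
ties, normal-approximated with tie correction otherwise. Monomer-control
outliers are flagged by a median/MAD criterion (3 robust SDs) so a bright
aggregate cannot mask itself.
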