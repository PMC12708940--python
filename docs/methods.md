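# Methods

This note records the models, numerical choices, and open design decisions
behind `flimfret`, and what the synthetic-data tests do and do not
demonstrate about real measurements.

## Steady-state photophysics

Spectra are wavelength-indexed curves on strictly increasing nm grids.
All cross-spectrum arithmetic happens on a shared grid built by linear
interpolation over the *intersection* of the input ranges (default step
0.5 nm, configurable); values are never extrapolated. The overlap integral
J = ∫ I_D(λ) ε_A(λ) λ⁴ dλ area-normalizes the donor emission on that common
grid before a composite-trapezoid integration, which makes J independent of
the donor curve's scale and keeps its units at M⁻¹cm⁻¹nm⁴ — the convention
required by the 0.2108 prefactor of R₀ = 0.2108·(κ²Φ_D η⁻⁴J)^(1/6) with R₀
in Å. Peak-normalizing the donor instead would silently change J's units;
it is not offered. κ² defaults to 2/3 (fast isotropic reorientation) and is
overridable.

pK_a values are fitted with the Henderson–Hasselbalch sigmoid
I(pH) = I_min + (I_max − I_min)/(1 + 10^(n·(pK_a − pH))), with the Hill
coefficient n fitted by default (fixable at 1). The fit refuses series whose
relative intensity span is below 10⁻³ (no transition present) and
initializes pK_a at the half-height crossing, which makes the noiseless case
converge to machine precision.

## TCSPC forward model

A decay with fractional amplitudes Aᵢ and lifetimes τᵢ observed through a
Gaussian IRF (FWHM, center shift) on a laser of repetition period T has the
per-bin expectation

    E[c_b] = scale · Σᵢ Aᵢ Σ_k [F(t_{b+1} + kT) − F(t_b + kT)] + background,

where F is the analytic CDF of the exponentially-modified Gaussian and the
pulse sum k = −1, 0, 1, … folds fluorescence that outlives one period back
into the window (the k = −1 term catches the IRF's leading edge). Bin masses
are exact integrals, not center-point evaluations, so coarse bins and
narrow IRFs introduce no discretization bias; the σ → 0 limit reduces to the
pure-exponential bin integral, verified against the closed form to 10⁻¹⁰.
The pulse sum is truncated where exp(−kT/τ) < 10⁻¹⁵, preserving total counts
to better than 0.1 %. An analytic Gaussian IRF was chosen over measured IRF
traces because the instrument class being emulated only bounds the IRF width
(< 150 ps FWHM); the shift is fitted by default, the width held fixed.

## Fitting, χ²ν, and the runs test

Parameters are one positive amplitude (expected photons) and one lifetime
per component, a constant background, and optionally the IRF shift.
Lifetimes and amplitudes are log-parameterized (positivity without active
bounds) and optimized by trust-region least squares; lifetime initial values
are log-spaced over [2·bin width, T/2], amplitudes equal, background taken
from the pre-rise bins. Components are returned sorted by descending
lifetime with fractional amplitudes; adjacent lifetimes within ratio 1.2 are
flagged as degenerate rather than silently merged.

The default objective is the Poisson maximum-likelihood deviance. Classic
Neyman-weighted least squares (variance = max(counts, 1)) is available, but
simulation at the package's own study conditions (the 37/46/16 % //
3.0/2.0/0.6 ns triple, 10⁶ counts, 1024 bins over 50 ns) showed it biases
the middle lifetime by up to 30 % through the sparse tail, while the MLE
tracks the Cramér–Rao bound; counting data with near-empty bins is exactly
where Neyman weights fail.

Goodness of fit is reported as the Neyman reduced χ²ν together with a
two-sided Wald–Wolfowitz runs test on the signs of the weighted residuals.
Both are evaluated from the 1 %-of-peak point on the rising edge to the last
bin where the locally smoothed counts reach 10 (configurable, including
full-window evaluation): the Neyman statistic has unit expectation only on
appreciably populated bins, and including a long empty tail deflates it to
~0.65 even for the *true* model, which would defeat its purpose as an
accept/reject criterion (fits are considered acceptable below χ²ν ≈ 1.5 with
sign-random residuals). Estimation itself always uses the full window.

Parameter uncertainty at these conditions is worth stating: the CRLB for the
triexponential mixture at 10⁶ counts gives σ(A₁) ≈ 0.063, σ(A₂) ≈ 0.057 and
σ(τ₂)/τ₂ ≈ 4.5 % even with background and shift known, because a 1.5
lifetime ratio makes the components nearly collinear. Single-realization
recoveries therefore scatter at that scale — amplitude deviations of ~0.06
on one seed are expected statistics, not fit failures. Recovery tightens
rapidly with separation: well-separated pairs (ratio ≥ 2) round-trip
noiselessly to 0.1 %.

## Model selection

Model order is chosen by fitting k = 1, 2, … components in sequence,
warm-starting each extension from the accepted lifetimes plus one faster
guess. A (k+1)-component fit replaces the k-component one only if it lowers
χ²ν by more than 0.05, every fractional amplitude is at least 1 %, and no
adjacent lifetime pair is degenerate (ratio < 1.2). The Δχ²ν gate is sized
so that improvements like 1.05 → 1.04 do not promote a model. The
degeneracy gate sits at the identifiability limit deliberately: mixtures
with a true ratio of exactly 1.5 (3 ns vs 2 ns) produce fitted ratios that
straddle 1.5, so a gate at 1.5 would reject half of all correct
three-component fits; at 1.2 the calibration runs select the true order in
100/100 mono-generated and 100/100 tri-generated realizations at 10⁶ counts.

## Imaging

Streak images hold counts on a time × wavelength grid (row-major, time
increasing downward, half-open intervals everywhere). Spectrum extraction
sums rows over a time window; decay extraction sums columns over a
wavelength band (a column belongs to a band if its *center* does). Both are
plain sums — linear and count-conserving by construction. Default detection
bands are 500–550 nm (donor; free of acceptor emission) and 580–630 nm
(acceptor); note the acceptor band also collects the donor's red emission
tail, so its decay is a mixture and is best analyzed through the
model-selection ladder.

FLIM images store one arrival-time histogram per pixel on a shared grid.
Cells are segmented from the integrated-intensity image by Otsu threshold,
connected components, and a minimum-area filter (default 200 px). The
primary analysis mode pools each cell's photons into one decay (per-cell
statistics are what the downstream population comparison consumes), fits it
through the model-selection ladder, and colors the lifetime map with the
accepted model's amplitude-weighted mean lifetime; ROIs under 1000 photons
are skipped with a warning. A secondary per-pixel mode bins 3×3
neighborhoods until a 500-photon floor is reached and fits
mono-exponentials; pixels that never reach the floor are masked invalid.

## FRET inference

Efficiencies are computed from amplitude-weighted mean lifetimes; integer
percentages round half away from zero, the convention that reproduces every
printed value in the source tables from their lifetime pairs. Negative
efficiencies (τ_DA > τ_D) are returned with a warning rather than clipped,
so environmental lifetime shifts stay visible. Distances are attached only
for E strictly inside (0, 1). Per-component analysis labels a component
"unquenched" when its lifetime is within 10 % (configurable) of the
donor-only lifetime, and otherwise splits at E = 0.5 into low- and high-FRET
with the boundary assigned to high-FRET. The significance rule is strict:
τ̄_m < mean − 3·s.d. of the donor-only control distribution, where the s.d.
is across per-sample mean lifetimes; when only a standard error is
available it is reconstructed as SEM·√n.

## Synthetic data

Generators are pure functions of (parameters, seed) — identical calls are
bit-identical — and every generator returns its ground truth for
transcription-free recovery tests. Spectra are Gaussian mixtures
parameterized by the published band maxima (mNeonGreen 506/476/520 nm,
mCherry 587 nm at ε = 72,000 M⁻¹cm⁻¹, 610 nm); band widths are package
choices since only maxima are published, which is adequate because no
downstream check depends on exact band shapes. Decay histograms draw
per-bin Poisson counts around the reconvolution expectation. Streak images
draw Poisson counts around sums of outer products (emission spectrum ×
decay profile). FLIM scenes place non-overlapping elliptical cells (seeded
rejection sampling with a bounded retry budget, so generation either
succeeds deterministically or fails loudly) and draw per-photon arrival
times from the population's IRF-convolved mixture.

Default instrument constants: IRF 150 ps FWHM centered 2 ns into the
window, 20 MHz repetition (50 ns window) for FLIM-style decays, 1024 bins
(≈ 49 ps) for cuvette-style decays and 256 bins for imaging scenes, 10⁵
photons per cell, 512×512 native image convention with 256×256 scenes used
in tests to keep memory and runtime modest. Detector pile-up is not
simulated by default (the emulated acquisitions keep count rates below 1 %
of the repetition rate, where pile-up is negligible); a classical pile-up
distortion can be enabled for robustness studies by post-processing the
expected counts.

What the synthetic tests show: correctness of the estimation chain
(generation → extraction → fitting → inference) under the package's own
noise model. What they cannot show: robustness to measured-IRF asymmetry,
detector afterpulsing, autofluorescence with short lifetimes, spectral
bleed-through beyond the band definitions, or cell-segmentation difficulty
in low-contrast images — real data adds all of these.

## Problem sizes

The test suite runs the full statistical calibrations at the sizes the
analyses use: 100-seed model-selection calibration and a 20-cell, 2×10⁶
photon scene, about four minutes total on one core. The acceptance script
fits two 10⁶-count decays and evaluates one closed-form radius, well under a
minute.

## Known limitations

Global (linked-lifetime) fitting across decays, phasor analysis,
time-resolved anisotropy, κ² orientation distributions,
distance-distribution FRET models, dark-state/photobleaching kinetics, and
vendor container formats (streak-camera or TTTR files) are out of scope;
data enter through the package's open CSV/NPZ/TIFF formats.
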