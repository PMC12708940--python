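# flimfret

Analysis toolkit for lifetime-based FRET measurements on fluorescent-protein
pairs, built around the mNeonGreen (donor) / mCherry (acceptor) system:
steady-state photophysics, time-correlated single photon counting (TCSPC)
decay analysis, streak-camera image decomposition, fluorescence lifetime
imaging (FLIM), and FRET inference, together with seeded synthetic-data
generators that emulate the whole measurement chain.

## The science in brief

Förster resonance energy transfer quenches the donor's excited state, so the
donor lifetime drops from τ_D (no acceptor) to τ_DA (acceptor present). The
package implements the standard chain of quantities:

- **Relative quantum yield** against a reference standard:
  Φ = Φ_ref · (η²/η_ref²) · (I/A) · (A_ref/I_ref).
- **Spectral overlap integral** J = ∫ I_D(λ) ε_A(λ) λ⁴ dλ with the donor
  emission I_D area-normalized (λ in nm, ε in M⁻¹cm⁻¹, J in M⁻¹cm⁻¹nm⁴).
- **Förster radius** R₀ = 0.2108 · (κ² Φ_D η⁻⁴ J)^(1/6) in Å.
- **Amplitude-weighted mean lifetime** τ̄_m = Σᵢ Aᵢ τᵢ of a multi-exponential
  decay with fractional amplitudes Aᵢ.
- **FRET efficiency** E = 1 − τ_DA/τ_D = R₀⁶/(R₀⁶ + r⁶), inverted to the
  donor-acceptor distance r = R₀·((1−E)/E)^(1/6).
- **Significance call**: a sample shows FRET only if
  τ̄_m(sample) < τ̄_m(control) − 3·s.d. of the donor-only control
  distribution.

Decays are modeled as exponential mixtures convolved with a Gaussian
instrument response function (IRF) and wrapped on the laser repetition
period; expected counts are exact analytic bin integrals. Fits minimize the
Poisson maximum-likelihood deviance; goodness of fit is reported as the
conventional Neyman reduced χ²ν plus a Wald–Wolfowitz runs test on the
residual signs, and the model order (mono/bi/tri/tetra) is chosen by a
nested-fit ladder that only accepts an extra component for a substantial χ²ν
improvement (Δχ²ν > 0.05), non-negligible amplitude (≥ 1 %), and
non-degenerate lifetimes.

## Layout

- `src/flimfret/` — the library: `photophysics` (spectra, J, R₀, Φ, pK_a),
  `decay` (forward model, reconvolution fitting, model selection), `fret`
  (efficiency/distance/significance), `imaging` (streak and FLIM
  processing, segmentation), `synthetic` (seeded generators),
  `io`/`config`/`pipeline`/`cli` (formats, validated configs, orchestration).
- `analysis/01…04_*.py` — numbered narrative drivers that exercise the
  pipeline end to end and write their tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers (below).

## Worked example

Running the end-to-end FLIM driver on the demo scene (10 donor-only cells
at 3.02 ns against 10 tandem-construct cells mixing 37/46/16 % of
3.0/2.0/0.6 ns components, 10⁵ photons per cell):

```bash
python analysis/04_flim_fret.py
```

prints

```
 construct    system  n  mean_lifetime_ns   sem_ns  efficiency_percent  n_significant
donor-only synthetic 10          3.017544 0.003252                   0              0
    tandem synthetic 10          2.139492 0.002487                  29             10

donor-only control: mean 3.018 ns, sd 0.0103 ns, n = 10; 3-s.d. threshold 2.987 ns
cells called FRET-positive: 10 of 20 (expected: the 10 tandem cells)
```

The tandem population's mean lifetime (2.139 ns, ground truth 2.142 ns)
gives a 29 % transfer efficiency against the donor-only control, and every
tandem cell — and no control cell — falls below the 3-s.d. threshold.
A quick interactive equivalent:

```bash
flimfret fret --tau-da 2.67 --tau-d 3.20     # efficiency: 0.1656 (17%)
flimfret forster --j 2.4e15                  # R0: 57.3 A
```

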