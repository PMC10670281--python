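# Methods

## Measurement model

A computational (single-pixel) spectrometer disperses NIR light onto a DMD;
each DMD frame reflects a binary subset of the 64 spectral channels onto one
InGaAs photodiode. A spectral measurement is a series of readings

    y_i = m_i · x + ε_i,    ε_i ~ N(0, σ²) i.i.d.,

where `m_i ∈ {0,1}^N` is the i-th mask and `x` the channel intensities. The
noise is *additive and reading-independent* (detector dark/readout noise
dominates at 1270 nm luminescence levels); this assumption is what makes
multiplexing profitable and it is the package default. An optional Poisson
(shot-noise) term exists for sensitivity studies but the multiplex-advantage
claims do not hold in a shot-noise-limited regime.

### Mask schemes and decoders

| scheme | readings | decoder | per-channel error SD |
|---|---|---|---|
| identity (scan) | N | passthrough | σ |
| S-matrix, n = 2^k−1 | n | S⁻¹ = 2/(n+1)·(2Sᵀ−J) | 2σ√n/(n+1) |
| complementary pairs, n = 2^k | 2n | x̂ = Hᵀd/n on pair differences | σ√(2/n) |

All decoders are exact closed forms (O(n²) matrix application); noiseless
round trips are identities to machine precision. The error SDs follow from
σ² times the decoder's row sum of squares and are verified against
Monte-Carlo in the test suite.

The SNR gain over an N-reading scan at equal per-reading noise is
`(n+1)/(2√n)` for the S-matrix and `√(N/2)` for complementary pairs — 5.66
(“5.7×”) at N = 64. Note the convention: the pair scheme uses 2N readings.
If the scan were granted the same 2N-reading budget (two averaged sweeps)
the gain would be `√N/2` = 4.0 at N = 64; the benchmark reports both so the
bookkeeping is explicit. S-matrix orders are 2^k−1, so a 64-channel
instrument using it drops to 63 channels (warned, configurable upstream).

### Acquisition timing

One reading per DMD frame: `t = n_readings / frame_rate`. Default frame
rate 10 Hz; 64 readings → 6.4 s, 128 → 12.8 s. No overhead term is modeled.

## Synthetic phantom

The phantom emulates a PS solution (or tissue) emitting:

- a **cubic PS-fluorescence background** in the centered wavelength
  `u = λ − 1270 nm`, default coefficients `(100, −0.25, −10⁻³, 5·10⁻⁶)`
  (arbitrary intensity units) — a smooth, gently curving band across
  1150–1402 nm, peak-to-background ratio ≈ 0.15 like the real spectra;
- a **Gaussian ¹O₂ line** at 1270 nm, default FWHM 20 nm, amplitude 20;
- optional **additive per-channel noise** and an optional non-cubic
  Gaussian "bump" for model-mismatch studies.

Both components scale linearly with `excitation_intensity`, and
`oxygenated=False` (the nitrogen-purge control) zeroes the peak while
leaving the background untouched.

**Instrument line shape.** The emission is blurred by a Gaussian of FWHM
14 nm (the instrument's measured resolution). The blur is evaluated in
closed form rather than by numerical convolution: a Gaussian blur of SD `s`
maps a cubic `p(u)` to the cubic `p(u) + s²(c₂ + 3c₃u)` and a Gaussian line
to a Gaussian with variance increased by `s²` and area conserved. This is
exact — no oversampling grid, no discretization bias — and keeps the
blurred baseline exactly cubic, so the pipeline's baseline stage is
well-specified against ground truth.

**Grid.** Default 64 channels over 1150–1402 nm (4 nm pitch): wide enough
to contain both baseline windows and the peak at the instrument's 64-point
sampling. The true spectral span of the hardware is not critical to any
result here and is configurable.

**What the phantom does not emulate:** PS photobleaching, ¹O₂ lifetime
kinetics, tissue optics, wavelength-dependent excitation chemistry, drifts,
or structured (non-white) detector noise. Passing tests therefore validate
the *processing chain* under its stated assumptions, not instrument
performance on real tissue.

## Quantification pipeline

1. **Baseline:** least-squares cubic over the channels inside 1220–1235 and
   1305–1320 nm only, in centered wavelength for conditioning. Cubic inputs
   are absorbed exactly (residual ≡ 0).
2. **Subtraction:** residual = raw − baseline, allowed negative.
3. **Peak fit:** unconstrained Gaussian by nonlinear least squares over
   1240–1300 nm (window configurable). No parameter is predetermined; the
   optimizer starts at the residual maximum, its wavelength, and the
   second-moment width, with σ bounded to [1, 100] nm for numerical sanity.
   A non-positive residual maximum or non-convergence yields "no peak".
4. **Integration:** the fitted Gaussian is integrated over 1260–1280 nm via
   the error function (matches adaptive quadrature to ~1e−9). A
   raw-residual trapezoid mode (with edge interpolation) exists for
   sensitivity analysis.
5. **PS metric:** integral of the fitted baseline over 1220–1320 nm. This
   is a package convention — the only PS quantity the NIR pipeline
   possesses; whether a real instrument would report this or a
   visible-camera fluorescence value is instrument-specific.
6. **Detection rule:** a peak is "present" iff fitted amplitude
   > k·(residual noise SD) with k = 3 by default, center ∈ [1255, 1285] nm,
   FWHM ∈ [5, 60] nm. The noise SD is pooled from the out-of-band residuals
   (df-corrected for the 4 baseline parameters) and the fit-window
   residuals after peak removal (df-corrected for the 3 peak parameters);
   the out-of-band windows alone hold only ~8 channels and give too
   unstable an estimate.

### Known biases and numerical notes

- **Tail leakage:** with the default 20 nm peak FWHM plus 14 nm blur, the
  effective line (FWHM 24.4 nm) has a ~0.2%-of-amplitude tail inside the
  nearest baseline-window channels. The baseline absorbs it, biasing the
  ¹O₂ value low by ~0.5%. This is a property of the sequential
  baseline-then-peak procedure itself, not of the implementation; with
  narrower lines (e.g. 14 nm emission FWHM, unblurred or blurred) the
  end-to-end recovery is 0.03% or better.
- **Detection false positives:** the k·σ amplitude rule is a scan statistic
  (the fit searches over center and width) and is scale-invariant, so on
  pure noise it fires at a few percent rate regardless of noise level
  (~4% measured at k = 3). Purge controls without noise are always
  negative; users needing a tighter false-positive rate should raise `k`.
- **Baseline extrapolation:** outside 1220–1320 nm the fitted cubic is an
  extrapolation with large leverage amplification under noise; the pipeline
  never evaluates it there, and neither should users.
- Wavelengths are centered at 1270 nm before polynomial fitting; negative
  fitted peak amplitudes are reported as "no peak" rather than negative
  ¹O₂; R² of the peak fit is computed over the fitting window.

## Dose-response and efficacy analysis

Ordinary least squares (unweighted), R² = 1 − SS_res/SS_tot over included
points, sample (n−1) SDs for error bars. Outlier exclusion is **manual by
default** — mirroring knowledge-based exclusion of artifacts such as
subject motion — with an opt-in leave-one-out studentized-residual rule
(threshold 3). The efficacy-cohort generator draws tumor-reduction values
as a seeded linear response in ¹O₂ dose plus Gaussian noise; cohort size is
a parameter (the in-vivo experiments this emulates used 6–8 animals).

## Radiometric calibration

Relative only: response_i = measured_i / B(λ_i, T) against a blackbody
emitter of known temperature, normalized to unit mean, then divided out of
subsequent spectra. `B` is the Planck spectral radiance up to a constant
(λ⁻⁵/(exp(hc/λkT)−1)); no absolute scale is established, matching the
instrument's relative ¹O₂ units.

## Problem sizes

Simulation sizes used throughout (tests and the acceptance script) are
2000-trial Monte-Carlo runs at 64 channels, 100-repeat fit-recovery sweeps,
and 200-realization detection-rate estimates — enough for ≤10% Monte-Carlo
tolerance on the quantities asserted, and all run in seconds on one core.

## Seeding

All randomness flows through `numpy.random.Generator`. Multi-draw
generators (dose series) spawn independent child streams from one root
`SeedSequence`, so per-level draws are independent of list order; identical
seeds give bit-identical outputs.
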