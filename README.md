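# o2spec

Simulation and analysis toolkit for **Hadamard-multiplexed single-pixel NIR
spectroscopy of singlet-oxygen (¹O₂) luminescence**, the measurement at the
heart of photodynamic-therapy (PDT) dosimetry.

During PDT, a light-activated photosensitizer (PS) transfers energy to
dissolved oxygen, producing cytotoxic ¹O₂ whose weak luminescence peaks at
1270 nm — buried under broadband PS fluorescence. A cost-effective way to
measure it is a *computational spectrometer*: a digital micromirror device
(DMD) selects binary combinations of spectral channels, a single InGaAs
photodiode records one reading per mask, and the spectrum is recovered by a
Hadamard transform. Because the photodiode's dark/readout noise is additive
and independent of light level, multiplexing yields the Fellgett SNR
advantage over scanning one wavelength at a time.

`o2spec` is for instrument builders and dosimetry researchers who want to
simulate, validate, or reuse this processing chain without hardware.

## The model

**Encoding.** For `N` spectral channels `x`, each DMD mask is a 0/1 row `m`,
and a reading is `y = m·x + ε`, `ε ~ N(0, σ²)`. Supported mask sets:

- *identity* — sequential wavelength scanning (`N` readings);
- *S-matrix* — Hadamard weighing design of order `n = 2^k − 1`, row weight
  `(n+1)/2`, closed-form inverse `S⁻¹ = 2/(n+1) · (2Sᵀ − J)`;
- *complementary pairs* — each ±1 Hadamard row realized as two masks
  `(1±h)/2` (`2N` readings); pair differences `d` decode as `x̂ = Hᵀd/N`.

**Multiplex advantage.** Against an `N`-reading scan with equal per-reading
noise, the complementary-pair scheme achieves an SNR gain of `√(N/2)` —
**5.66 ≈ 5.7× at N = 64** — and the S-matrix `(n+1)/(2√n)` (≈4.0 at n = 63).

**Quantification.** For each spectrum: fit a 3rd-order polynomial PS
baseline to the out-of-band windows 1220–1235 and 1305–1320 nm; subtract
it; fit an unconstrained Gaussian to the residual; integrate the fit over
1260–1280 nm → relative ¹O₂ value. A nitrogen-purged control (no dissolved
O₂) must, and does, report no peak.

## Worked example

```python
import numpy as np
from o2spec import *

grid = default_grid()                     # 64 channels, 1150-1402 nm
params = PhantomParams()                  # PS baseline + 1270 nm peak, 14 nm blur
truth = generate_phantom_spectrum(params, grid)

masks = build_masks("complementary_hadamard", 64)
series = forward_measure(truth, masks, NoiseModel(detector_sigma=1.0, seed=1))
recon = reconstruct_spectrum(series)
result = quantify_spectrum(recon)

levels = np.linspace(0.5, 3.0, 6)
specs = generate_dose_series(params, grid, intensities=levels, noise_sigma=1.0, seed=2)
fit = linear_fit(levels, [quantify_spectrum(s).o2_value for s in specs])

gains = benchmark_cs_vs_scan(truth.intensities, 64, detector_sigma=1.0,
                             n_trials=2000, seed=3)
```

prints (via the obvious `print` statements):

```text
acquisition: 128 readings at 10 Hz -> 12.8 s
o2_value = 280.0  (ground truth 283.3)
ps_value = 9922
peak: center 1270.2 nm, FWHM 24.4 nm, R^2 = 0.998
peak_present = True
dose-response: slope 260.3, R^2 = 0.998
s_matrix: empirical 4.02x, theoretical 4.03x
complementary_hadamard: empirical 5.64x, theoretical 5.66x
```

The quantified ¹O₂ value (280) recovers the phantom's analytic in-window
peak integral (283.3) through detector noise; the dose-response fit shows
the expected linearity of ¹O₂ with excitation intensity; the Monte-Carlo
benchmark reproduces both closed-form multiplex gains. A 64-reading scan at
10 Hz takes 6.4 s; the 128-reading complementary-pair acquisition, 12.8 s.

The same pipeline is scriptable from a shell:

```sh
o2spec simulate --seed 1 --out run1
o2spec quantify run1/reconstructed.csv --out run1
o2spec benchmark-snr --channels 64 --trials 2000 --seed 7 --out run1
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults, what
the synthetic phantoms do and do not emulate, and known limitations.
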