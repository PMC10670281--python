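"""Synthetic PS + singlet-oxygen spectra with known ground truth.

The phantom emulates what a NIR single-point spectrometer sees from a
photosensitizer (PS) solution or tissue: a smooth broadband PS fluorescence
background across 1150-1400 nm, plus -- when dissolved oxygen is present --
the weak singlet-oxygen (1O2) luminescence peak centered at 1270 nm.  Both
components scale linearly with excitation intensity, and the whole emission
is blurred by the instrument line shape (~14 nm FWHM Gaussian).

The background is modeled as a cubic polynomial in the centered wavelength
(lambda - 1270 nm), matching the functional form the downstream baseline fit
assumes, so exact recovery is testable.  An optional "bump" term injects
controlled model mismatch for robustness studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CENTER_NM",
    "WavelengthGrid",
    "PhantomParams",
    "Spectrum",
    "make_grid",
    "default_grid",
    "fwhm_to_sigma",
    "generate_phantom_spectrum",
    "generate_dose_series",
    "generate_efficacy_cohort",
    "planck_radiance",
]

#: Wavelength (nm) about which polynomials are centered; the 1O2 emission peak.
CENTER_NM = 1270.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return fwhm * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling grid.

    Channel centers run from ``start_nm`` to ``end_nm`` inclusive, uniformly
    spaced, one per spectral channel.
    """

    start_nm: float
    end_nm: float
    n_channels: int

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError(
                f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})"
            )
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.end_nm, self.n_channels)

    @property
    def pitch_nm(self) -> float:
        return (self.end_nm - self.start_nm) / (self.n_channels - 1)

    def window_mask(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of channels whose centers lie in [lo_nm, hi_nm]."""
        c = self.centers
        return (c >= lo_nm) & (c <= hi_nm)


def make_grid(start_nm: float, end_nm: float, n_channels: int) -> WavelengthGrid:
    """Build a uniform wavelength grid with inclusive endpoints."""
    return WavelengthGrid(start_nm, end_nm, n_channels)


def default_grid() -> WavelengthGrid:
    """64 channels over 1150-1402 nm (4 nm pitch).

    Wide enough to contain both out-of-band baseline windows
    (1220-1235 and 1305-1320 nm) and the 1270 nm peak, at the 64-point
    sampling the instrument uses.
    """
    return WavelengthGrid(1150.0, 1402.0, 64)


@dataclass(frozen=True)
class PhantomParams:
    """Ground-truth parameters of the synthetic PS + 1O2 emission.

    Parameters
    ----------
    baseline_coeffs
        Cubic PS-background coefficients ``(c0, c1, c2, c3)`` in ascending
        powers of the centered wavelength ``u = lambda - 1270 nm``
        (intensity units; arbitrary).
    peak_amplitude
        Height of the (pre-blur) 1O2 Gaussian peak, same units.
    peak_center_nm, peak_fwhm_nm
        Location and width of the 1O2 emission line.
    excitation_intensity
        Relative excitation scalar; both PS background and peak scale
        linearly with it.
    oxygenated
        ``False`` models the nitrogen-purged control: dissolved oxygen is
        removed, so the 1270 nm peak vanishes while the PS background stays.
    line_shape_fwhm_nm
        Instrument spectral resolution (Gaussian blur FWHM).  0 disables
        blurring.
    bump_amplitude, bump_center_nm, bump_fwhm_nm
        Optional non-cubic background bump (model-mismatch hook); off by
        default.
    """

    baseline_coeffs: tuple[float, float, float, float] = (100.0, -0.25, -1e-3, 5e-6)
    peak_amplitude: float = 20.0
    peak_center_nm: float = CENTER_NM
    peak_fwhm_nm: float = 20.0
    excitation_intensity: float = 1.0
    oxygenated: bool = True
    line_shape_fwhm_nm: float = 14.0
    bump_amplitude: float = 0.0
    bump_center_nm: float = 1200.0
    bump_fwhm_nm: float = 40.0

    def __post_init__(self) -> None:
        if len(self.baseline_coeffs) != 4:
            raise ValueError("baseline_coeffs must have exactly 4 entries")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.peak_fwhm_nm <= 0:
            raise ValueError("peak_fwhm_nm must be > 0")
        if self.excitation_intensity < 0:
            raise ValueError("excitation_intensity must be >= 0")
        if self.line_shape_fwhm_nm < 0:
            raise ValueError("line_shape_fwhm_nm must be >= 0")

    @property
    def effective_peak_amplitude(self) -> float:
        """Peak amplitude actually emitted: zero when deoxygenated."""
        return self.peak_amplitude if self.oxygenated else 0.0

    def true_peak_integral(self, lo_nm: float = 1260.0, hi_nm: float = 1280.0) -> float:
        """Analytic integral of the blurred, excitation-scaled 1O2 peak over
        ``[lo_nm, hi_nm]`` -- the ground truth the quantification pipeline
        estimates.

        Gaussian blur widens the line (variances add) but conserves its area,
        so this is the integral of a Gaussian of the blurred width whose full
        area equals the emitted one.
        """
        amp = self.effective_peak_amplitude * self.excitation_intensity
        if amp == 0.0:
            return 0.0
        sig0 = fwhm_to_sigma(self.peak_fwhm_nm)
        sig = math.hypot(sig0, fwhm_to_sigma(self.line_shape_fwhm_nm))
        area = amp * sig0 * math.sqrt(2.0 * math.pi)
        from scipy.special import erf  # local import keeps module import light

        z_lo = (lo_nm - self.peak_center_nm) / (sig * math.sqrt(2.0))
        z_hi = (hi_nm - self.peak_center_nm) / (sig * math.sqrt(2.0))
        return float(area * 0.5 * (erf(z_hi) - erf(z_lo)))


@dataclass
class Spectrum:
    """Intensities on a wavelength grid -- the central exchange object."""

    grid: WavelengthGrid
    intensities: np.ndarray
    label: str = ""
    excitation_intensity: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_channels,):
            raise ValueError(
                f"intensities length {self.intensities.shape} does not match "
                f"grid n_channels {self.grid.n_channels}"
            )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.centers


def _gaussian(x: np.ndarray, amplitude: float, center: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _blurred_components(
    params: PhantomParams, wavelengths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (baseline, peak) after instrument blurring, per unit excitation.

    A Gaussian blur of sd ``s`` maps a cubic p(u) to p(u) + s^2 (c2 + 3 c3 u)
    -- still a cubic -- and maps a Gaussian line to a Gaussian with variance
    increased by s^2 and area conserved.  Both blurs are therefore evaluated
    in closed form; the optional bump term is blurred the same analytic way
    (it is itself Gaussian).
    """
    u = wavelengths - CENTER_NM
    c0, c1, c2, c3 = params.baseline_coeffs
    s = fwhm_to_sigma(params.line_shape_fwhm_nm)
    baseline = c0 + c1 * u + c2 * u**2 + c3 * u**3 + s**2 * (c2 + 3.0 * c3 * u)

    if params.bump_amplitude != 0.0:
        bsig0 = fwhm_to_sigma(params.bump_fwhm_nm)
        bsig = math.hypot(bsig0, s)
        baseline = baseline + _gaussian(
            wavelengths,
            params.bump_amplitude * bsig0 / bsig,
            params.bump_center_nm,
            bsig,
        )

    amp = params.effective_peak_amplitude
    if amp > 0.0:
        psig0 = fwhm_to_sigma(params.peak_fwhm_nm)
        psig = math.hypot(psig0, s)
        peak = _gaussian(wavelengths, amp * psig0 / psig, params.peak_center_nm, psig)
    else:
        peak = np.zeros_like(wavelengths)
    return baseline, peak


def generate_phantom_spectrum(
    params: PhantomParams,
    grid: WavelengthGrid | None = None,
    seed: int | np.random.Generator | None = None,
    sampling_noise_sigma: float = 0.0,
) -> Spectrum:
    """Generate one instrument-blurred phantom spectrum.

    The emitted spectrum is ``excitation_intensity x [cubic PS baseline +
    1O2 Gaussian peak (if oxygenated)]`` convolved with the Gaussian
    instrument line shape and sampled at the channel centers.  Optional
    additive Gaussian sampling noise (``sampling_noise_sigma``) is seeded
    and off by default; without it the output is deterministic.
    """
    if grid is None:
        grid = default_grid()
    baseline, peak = _blurred_components(params, grid.centers)
    intensities = params.excitation_intensity * (baseline + peak)
    if sampling_noise_sigma < 0:
        raise ValueError("sampling_noise_sigma must be >= 0")
    if sampling_noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, sampling_noise_sigma, grid.n_channels)
    label = "oxygenated" if params.oxygenated else "nitrogen-purged"
    return Spectrum(
        grid=grid,
        intensities=intensities,
        label=label,
        excitation_intensity=params.excitation_intensity,
        metadata={"peak_center_nm": params.peak_center_nm},
    )


def generate_dose_series(
    params: PhantomParams,
    grid: WavelengthGrid | None = None,
    intensities: list[float] | np.ndarray = (1.0,),
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> list[Spectrum]:
    """One phantom spectrum per excitation level, with independent seeded noise.

    Models a dose-response acquisition: the same sample measured at several
    excitation intensities, each measurement carrying its own additive
    detector noise realization.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size == 0:
        raise ValueError("intensity list must be non-empty")
    if np.any(intensities < 0):
        raise ValueError("excitation intensities must be non-negative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(intensities.size)
    out = []
    for level, ss in zip(intensities, streams):
        p = replace(params, excitation_intensity=float(level))
        spec = generate_phantom_spectrum(
            p,
            grid,
            seed=np.random.default_rng(ss),
            sampling_noise_sigma=noise_sigma,
        )
        spec.label = f"dose level {level:g}"
        out.append(spec)
    return out


def generate_efficacy_cohort(
    n_subjects: int,
    o2_range: tuple[float, float],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int | None = None,
) -> np.ndarray:
    """Paired (o2_value, tumor_reduction) table for an efficacy correlation.

    Subjects receive 1O2 doses uniformly spaced over ``o2_range``; tumor
    reduction responds linearly (``intercept + slope * o2``) plus Gaussian
    biological noise.  Returns an (n_subjects, 2) array with columns
    (o2_value, tumor_reduction).
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = o2_range
    if hi < lo:
        raise ValueError("o2_range must satisfy lo <= hi")
    if hi == lo and n_subjects > 1:
        import warnings

        warnings.warn(
            "degenerate o2_range (zero width): all subjects share one dose",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    o2 = np.linspace(lo, hi, n_subjects)
    reduction = intercept + slope * o2 + rng.normal(0.0, noise_sd, n_subjects)
    return np.column_stack([o2, reduction])


# Planck constants in nm-friendly units: h*c/k = 1.4388e7 nm*K
_HC_OVER_K_NM_K = 1.43877687750393e7


def planck_radiance(wavelength_nm, temperature_K):
    """Relative blackbody spectral radiance, proportional to
    lambda^-5 / (exp(hc / lambda k T) - 1).

    Used only for *relative* radiometric response calibration, so the overall
    radiometric constant is omitted; units are arbitrary.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be > 0")
    if temperature_K <= 0:
        raise ValueError("temperature must be > 0")
    x = _HC_OVER_K_NM_K / (wl * temperature_K)
    out = wl**-5 / np.expm1(x)
    return out if out.ndim else float(out)
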