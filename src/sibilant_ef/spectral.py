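"""Multitaper spectral estimation and the spectral centroid.

The articulation measure is the first spectral moment (centroid) of a 40 ms
slice taken from the middle of each sibilant token.  The power spectrum of
that slice is estimated with Thomson's multitaper method: the slice is
multiplied by K orthonormal discrete prolate spheroidal sequences (DPSS),
the K eigenspectra are averaged, and the result is scaled to a one-sided
density whose integral over [0, Nyquist] equals the slice variance.

The centroid is the power-weighted mean frequency over an analysis band,
by default [550 Hz, Nyquist] to keep voicing remnants and low-frequency
room noise out of the fricative moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss as _scipy_dpss

from .audio_io import Waveform


@dataclass(frozen=True)
class TaperSet:
    """DPSS tapers with their concentration eigenvalues.

    ``tapers`` has shape (K, n_samples); rows are unit-norm and mutually
    orthogonal.  ``eigenvalues`` are the in-band energy concentrations,
    sorted descending and all in (0, 1].
    """

    n_samples: int
    time_bandwidth_nw: float
    tapers: np.ndarray
    eigenvalues: np.ndarray

    @property
    def k_tapers(self) -> int:
        return self.tapers.shape[0]


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided power spectral density on a DFT frequency grid."""

    frequencies_hz: np.ndarray
    power: np.ndarray  # amplitude^2 / Hz, >= 0

    def __post_init__(self) -> None:
        if self.frequencies_hz.shape != self.power.shape:
            raise ValueError("frequency grid and power must have equal length")


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the centroid extraction.

    window_ms : analysis slice length centred on the token midpoint.
    nw        : DPSS time-bandwidth product.
    k_tapers  : number of tapers averaged (standard choice 2*NW - 1).
    band_low_hz / band_high_hz : centroid integration band; ``None`` for the
        high edge means Nyquist.
    weighting : 'power' weights the centroid by S(f); 'amplitude' by sqrt(S).
    """

    window_ms: float = 40.0
    nw: float = 4.0
    k_tapers: int = 7
    band_low_hz: float = 550.0
    band_high_hz: float | None = None
    weighting: str = "power"

    def __post_init__(self) -> None:
        if self.weighting not in ("power", "amplitude"):
            raise ValueError("weighting must be 'power' or 'amplitude'")


def mid_window(segment: Waveform, window_ms: float = 40.0) -> tuple[Waveform, bool]:
    """Return the ``window_ms`` span centred on the segment midpoint.

    Segments shorter than the window are analysed whole rather than dropped;
    the returned flag is True when that fallback fired.
    """
    n = segment.samples.size
    n_win = int(round(window_ms * 1e-3 * segment.sample_rate_hz))
    if n <= n_win:
        return segment, n < n_win
    mid = n / 2.0
    i0 = int(round(mid - n_win / 2.0))
    i0 = max(0, min(i0, n - n_win))
    return (
        Waveform(samples=segment.samples[i0 : i0 + n_win], sample_rate_hz=segment.sample_rate_hz),
        False,
    )


def dpss_tapers(n_samples: int, time_bandwidth_nw: float = 4.0, k_tapers: int = 7) -> TaperSet:
    """Compute K unit-norm DPSS tapers of length ``n_samples``.

    The sequences solve the symmetric tridiagonal eigenproblem that
    maximises spectral concentration in [-NW/n, NW/n] cycles/sample.  Sign
    convention: symmetric (even-order) tapers have nonnegative mean, the
    others a nonnegative first lobe.
    """
    if k_tapers < 1:
        raise ValueError(f"k_tapers must be >= 1, got {k_tapers}")
    if n_samples < 8:
        raise ValueError(f"n_samples must be >= 8, got {n_samples}")
    k_max = int(2 * time_bandwidth_nw - 1)
    if k_tapers > k_max:
        warnings.warn(
            f"k_tapers={k_tapers} exceeds 2*NW-1={k_max}; higher-order tapers "
            "have poor concentration",
            stacklevel=2,
        )
    tapers, ratios = _scipy_dpss(
        n_samples, time_bandwidth_nw, Kmax=k_tapers, sym=True, norm=2, return_ratios=True
    )
    tapers = np.atleast_2d(tapers)
    return TaperSet(
        n_samples=n_samples,
        time_bandwidth_nw=time_bandwidth_nw,
        tapers=tapers,
        eigenvalues=ratios,
    )


def multitaper_psd(window: Waveform, tapers: TaperSet) -> SpectrumEstimate:
    """Multitaper PSD of one analysis window.

    The K eigenspectra |DFT(v_k * x)|^2 are averaged with equal weights and
    scaled so that the trapezoidal integral of the one-sided density over
    [0, Nyquist] equals the sample variance of the window (Parseval
    contract).  The frequency grid is the rFFT grid of the window length —
    no zero padding, so the estimate is a pure function of the input.
    """
    x = window.samples
    if x.size != tapers.n_samples:
        raise ValueError(
            f"taper length {tapers.n_samples} != window length {x.size}"
        )
    fs = window.sample_rate_hz
    x = x - x.mean()
    spectra = np.abs(np.fft.rfft(tapers.tapers * x[np.newaxis, :], axis=1)) ** 2
    psd = spectra.mean(axis=0)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    variance = float(np.mean(x**2))
    if variance > 0:
        raw_integral = float(np.trapezoid(psd, freqs))
        if raw_integral > 0:
            psd = psd * (variance / raw_integral)
    else:
        psd = np.zeros_like(psd)
    return SpectrumEstimate(frequencies_hz=freqs, power=psd)


def spectral_centroid(
    spectrum: SpectrumEstimate,
    band_hz: tuple[float, float],
    weighting: str = "power",
) -> float:
    """Weighted mean frequency of the spectrum over ``band_hz``.

    The default weights each grid frequency by its power density S(f); the
    'amplitude' mode weights by sqrt(S(f)) instead.
    """
    low, high = band_hz
    nyquist = spectrum.frequencies_hz[-1]
    if not (0.0 <= low < high <= nyquist + 1e-9):
        raise ValueError(f"band [{low}, {high}] outside [0, {nyquist}] Hz")
    mask = (spectrum.frequencies_hz >= low) & (spectrum.frequencies_hz <= high)
    weights = spectrum.power[mask]
    if weighting == "amplitude":
        weights = np.sqrt(weights)
    elif weighting != "power":
        raise ValueError("weighting must be 'power' or 'amplitude'")
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "zero in-band power: silent or invalid token in "
            f"[{low}, {high}] Hz"
        )
    return float(np.dot(spectrum.frequencies_hz[mask], weights) / total)


def token_centroid(
    segment: Waveform,
    config: SpectralConfig = SpectralConfig(),
    taper_cache: dict[int, TaperSet] | None = None,
) -> float:
    """Centroid of one token: mid-window -> DPSS -> multitaper PSD -> centroid.

    Deterministic in (segment, config).  ``taper_cache`` (keyed on window
    length) avoids recomputing identical taper sets across tokens.
    """
    window, _short = mid_window(segment, config.window_ms)
    n = window.samples.size
    if taper_cache is not None and n in taper_cache:
        tapers = taper_cache[n]
    else:
        tapers = dpss_tapers(n, config.nw, config.k_tapers)
        if taper_cache is not None:
            taper_cache[n] = tapers
    spectrum = multitaper_psd(window, tapers)
    nyquist = segment.sample_rate_hz / 2.0
    high = config.band_high_hz if config.band_high_hz is not None else nyquist
    return spectral_centroid(spectrum, (config.band_low_hz, high), config.weighting)
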