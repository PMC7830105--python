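"""Morlet continuous wavelet transform with logarithmic frequency spacing.

The transform is

    W(s, t) = (1/s) ∫ psi((u - t)/s) g(u) du,

with the Morlet mother wavelet psi(u) = π^(-1/4) exp(-i 2π u) exp(-u²/2).
The central frequency is 1, so scale maps to frequency as f = 1/s.  Note the
1/s (not the more common 1/√s) normalisation: with it, the ridge amplitude
of a sinusoid is proportional to the component amplitude and independent of
frequency.  Users comparing against other wavelet toolboxes should expect a
√s discrepancy in raw coefficient magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import ValidationError

__all__ = ["WaveletConfig", "WaveletSpectrum", "wavelet_transform",
           "amplitude_phase"]

_PI4 = np.pi ** (-0.25)
#: Kernel support in units of the scale s (Gaussian envelope ~ exp(-u^2/2)).
_SUPPORT = 5.0


@dataclass
class WaveletConfig:
    """Frequency grid for the transform: log-spaced from fmin to fmax."""

    fmin: float = 0.07
    fmax: float = 2.0
    voices_per_octave: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.fmin < self.fmax):
            raise ValidationError("need 0 < fmin < fmax")
        if self.voices_per_octave < 1:
            raise ValidationError("voices_per_octave must be >= 1")

    def frequencies(self) -> np.ndarray:
        n_oct = np.log2(self.fmax / self.fmin)
        n = int(np.floor(n_oct * self.voices_per_octave)) + 1
        freqs = self.fmin * 2.0 ** (np.arange(n) / self.voices_per_octave)
        if freqs[-1] < self.fmax * (1 - 1e-12):
            freqs = np.append(freqs, self.fmax)
        return freqs


@dataclass
class WaveletSpectrum:
    """Complex wavelet coefficients on a (frequency, time) grid.

    ``coefficients[k, n]`` is X(ω_k, t_n) = a + ib; ``coi`` is True where the
    coefficient lies inside the cone of influence (i.e. is reliable).
    """

    frequencies: np.ndarray       # Hz, ascending
    times: np.ndarray             # s
    coefficients: np.ndarray      # complex, (n_freq, n_time)
    coi: np.ndarray               # bool, True = reliable

    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def phase(self) -> np.ndarray:
        """Quadrant-aware phase arctan2(b, a) in (-π, π]."""
        return np.angle(self.coefficients)


def _morlet_kernel(scale: float, fs: float) -> np.ndarray:
    """Sampled (1/s) psi(v/s) on a symmetric grid, v = u - t."""
    half = int(np.ceil(_SUPPORT * scale * fs))
    v = np.arange(-half, half + 1) / fs
    u = v / scale
    return (_PI4 / scale) * np.exp(-1j * 2 * np.pi * u) * np.exp(-0.5 * u * u)


def wavelet_transform(samples: np.ndarray, fs: float,
                      config: WaveletConfig | None = None) -> WaveletSpectrum:
    """Continuous Morlet wavelet transform of one channel.

    Implemented as FFT-based correlation of the signal with the scaled
    wavelet at each frequency of the log-spaced grid; the integral is
    discretised with step 1/fs.
    """
    if config is None:
        config = WaveletConfig()
    g = np.asarray(samples, float)
    if config.fmax > fs / 2:
        raise ValidationError(f"fmax {config.fmax} exceeds Nyquist {fs / 2}")
    if g.size < 3 * fs / config.fmin:
        raise ValidationError(
            "record shorter than 3 periods of the lowest analysed frequency")
    freqs = config.frequencies()
    times = np.arange(g.size) / fs
    coeffs = np.empty((freqs.size, g.size), complex)
    coi = np.empty((freqs.size, g.size), bool)
    duration = (g.size - 1) / fs
    for k, f in enumerate(freqs):
        s = 1.0 / f
        kernel = _morlet_kernel(s, fs)
        # W(s,t) = sum_u g(u) k(u-t) / fs  -> correlation
        coeffs[k] = fftconvolve(g, kernel[::-1], mode="same") / fs
        edge = s * np.sqrt(2)
        coi[k] = (times >= edge) & (duration - times >= edge)
    return WaveletSpectrum(frequencies=freqs, times=times,
                           coefficients=coeffs, coi=coi)


def amplitude_phase(spectrum: WaveletSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude sqrt(a²+b²) and quadrant-aware phase of the coefficients."""
    return spectrum.amplitude(), spectrum.phase()


def ridge_frequency(spectrum: WaveletSpectrum) -> np.ndarray:
    """Frequency of maximal amplitude at each time (simple ridge extractor)."""
    return spectrum.frequencies[np.argmax(spectrum.amplitude(), axis=0)]
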