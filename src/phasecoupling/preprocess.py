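"""Signal conditioning and phase extraction.

The pipeline mirrors standard practice for cardio-respiratory phase
dynamics: moving-average detrend, z-normalisation, zero-phase Butterworth
bandpass into the respiratory (0.1–0.6 Hz) and cardiac (0.6–2 Hz) bands,
protophase via the analytic signal, and the protophase-to-phase
transformation that maps the observable-dependent protophase to the
invariant phase with uniform density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .exceptions import DegenerateInputError, ValidationError

__all__ = [
    "BandComponent",
    "PhaseSeries",
    "moving_average_detrend",
    "zscore_normalize",
    "bandpass_extract",
    "protophase",
    "protophase_to_phase",
    "extract_phase",
    "instantaneous_rate",
]

RESPIRATORY_BAND = (0.1, 0.6)
CARDIAC_BAND = (0.6, 2.0)


@dataclass
class BandComponent:
    """A bandpass-filtered oscillatory mode of one channel."""

    label: str                     # "respiratory" or "cardiac"
    band: tuple[float, float]      # Hz
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        lo, hi = self.band
        if not (0 < lo < hi < self.fs / 2):
            raise ValidationError(
                f"band {self.band} must lie within (0, fs/2={self.fs / 2})")


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase of one oscillatory mode.

    ``kind`` distinguishes the raw analytic-signal angle (``protophase``)
    from the transformed invariant phase (``phase``); a ``phase`` series
    must advance on average (positive mean velocity).
    """

    phase: np.ndarray
    fs: float
    kind: str = "phase"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, float)
        if self.kind not in ("protophase", "phase"):
            raise ValidationError(f"bad kind {self.kind!r}")
        if not np.all(np.isfinite(self.phase)):
            raise ValidationError("non-finite phase values")
        if self.kind == "phase" and self.phase.size > 1:
            if (self.phase[-1] - self.phase[0]) <= 0:
                raise ValidationError("phase must advance on average")

    @property
    def n_samples(self) -> int:
        return self.phase.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.phase.size) / self.fs

    def cycles(self) -> float:
        """Total number of 2π cycles covered."""
        return float(self.phase[-1] - self.phase[0]) / (2 * np.pi)

    def crop(self, start_s: float, end_s: float) -> "PhaseSeries":
        """Sub-series over absolute times [start_s, end_s)."""
        i0 = int(round((start_s - self.t0) * self.fs))
        i1 = int(round((end_s - self.t0) * self.fs))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        return PhaseSeries(self.phase[i0:i1].copy(), self.fs, self.kind,
                           t0=self.t0 + i0 / self.fs)


def moving_average_detrend(samples: np.ndarray, fs: float,
                           window_s: float = 30.0) -> np.ndarray:
    """Subtract a centered moving average of width ``window_s``.

    The averaging window shrinks near the edges (min_periods=1), so the
    output has the same length as the input.
    """
    samples = np.asarray(samples, float)
    if window_s <= 0:
        raise ValidationError("detrend window must be positive")
    if window_s * fs >= samples.size:
        raise ValidationError("detrend window must be shorter than the record")
    w = max(int(round(window_s * fs)), 1)
    trend = pd.Series(samples).rolling(w, center=True, min_periods=1).mean()
    return samples - trend.to_numpy()


def zscore_normalize(samples: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the standard deviation."""
    samples = np.asarray(samples, float)
    sd = samples.std()
    if sd == 0:
        raise DegenerateInputError("constant signal cannot be z-normalised")
    return (samples - samples.mean()) / sd


def bandpass_extract(samples: np.ndarray, fs: float,
                     band: tuple[float, float],
                     order: int = 2,
                     label: str | None = None) -> BandComponent:
    """Zero-phase Butterworth bandpass (order ``order`` per pass, applied
    forward–backward, so effective order is doubled and lag is zero)."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValidationError(f"band {band} outside (0, Nyquist={fs / 2}) Hz")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, np.asarray(samples, float))
    if label is None:
        label = "respiratory" if hi <= RESPIRATORY_BAND[1] else "cardiac"
    return BandComponent(label=label, band=band, samples=filtered, fs=fs)


def protophase(component: BandComponent) -> PhaseSeries:
    """Unwrapped angle of the analytic signal (Hilbert embedding)."""
    x = component.samples
    if not np.any(x):
        raise DegenerateInputError("all-zero component has no phase")
    theta = np.unwrap(np.angle(hilbert(x)))
    return PhaseSeries(theta, component.fs, kind="protophase")


def protophase_to_phase(proto: PhaseSeries, n_harmonics: int = 48) -> PhaseSeries:
    """Map a protophase to the invariant phase with uniform density.

    Uses the Fourier-coefficient transformation

        phi(theta) = theta + sum_{0<|n|<=N} S_n/(i n) * (e^{i n theta} - 1)

    with ``S_n = <e^{-i n theta}>`` the empirical coefficients of the wrapped
    protophase distribution.  The map satisfies phi(theta + 2π) =
    phi(theta) + 2π, so total phase gain (cycle count) is preserved.
    """
    theta = proto.phase
    if (theta[-1] - theta[0]) < 10 * 2 * np.pi:
        raise ValidationError(
            "protophase-to-phase transformation needs >= 10 cycles")
    n = np.arange(1, n_harmonics + 1)
    # S_n for positive n; negative n follow by conjugation since theta is real
    S = np.exp(-1j * np.outer(n, theta)).mean(axis=1)
    # phi = theta + 2*Re[ sum_n S_n/(i n) (e^{i n theta} - 1) ]
    expo = np.exp(1j * np.outer(n, theta)) - 1.0
    corr = (S / (1j * n)) @ expo
    phi = theta + 2.0 * corr.real
    return PhaseSeries(phi, proto.fs, kind="phase", t0=proto.t0)


def extract_phase(samples: np.ndarray, fs: float, band: tuple[float, float],
                  order: int = 2, detrend_window_s: float = 30.0,
                  n_harmonics: int = 48) -> PhaseSeries:
    """Full phase pipeline for one channel and one band.

    detrend -> z-normalise -> bandpass -> protophase -> invariant phase.
    """
    x = moving_average_detrend(samples, fs, detrend_window_s)
    x = zscore_normalize(x)
    comp = bandpass_extract(x, fs, band, order=order)
    return protophase_to_phase(protophase(comp), n_harmonics=n_harmonics)


def instantaneous_rate(phase: PhaseSeries, smooth_s: float = 2.0) -> np.ndarray:
    """Instantaneous rate in beats/min: 60 * dphi/dt / 2π, smoothed.

    The derivative uses centered finite differences; ``smooth_s`` sets the
    width of a centered moving-average smoother (0 disables smoothing).
    """
    if phase.kind != "phase":
        raise ValidationError("instantaneous_rate needs an invariant phase")
    if phase.phase[-1] - phase.phase[0] <= 0:
        raise ValidationError("zero mean velocity violates the phase contract")
    vel = np.gradient(phase.phase, 1.0 / phase.fs)
    if not np.all(np.isfinite(vel)):
        raise ValidationError("non-finite phase velocity")
    rate = 60.0 * vel / (2 * np.pi)
    if smooth_s > 0:
        w = max(int(round(smooth_s * phase.fs)), 1)
        rate = pd.Series(rate).rolling(w, center=True, min_periods=1).mean().to_numpy()
    return rate
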