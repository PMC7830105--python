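"""Ground-truthed synthetic data: coupled phase oscillators and composite
BP/SAS-like recordings following the four-stage slow-breathing protocol.

The generator integrates the stochastic phase model

    dphi_i/dt = omega_i + q_i(phi_i, phi_j) + xi_i(t)

by Euler–Maruyama at the output rate and composes observable channels as

    g(t) = A_c cos(phi_cardiac) + A_r cos(phi_resp) + measurement noise.

Respiratory sinus arrhythmia enters purely as additive phase coupling of
sinusoidal form, q_cardiac = a * sin(phi_resp + delta); the four-stage
protocol (A baseline, B paced 6 breaths/min, C paced with inspiratory
resistance, D recovery; 10 min each) changes the respiratory frequency, the
coupling gain and, during paced stages, the phase lag delta of the coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .io import SignalRecord, StageProtocol
from .preprocess import PhaseSeries

__all__ = [
    "CouplingTerm",
    "OscillatorSpec",
    "StageSpec",
    "ProtocolSpec",
    "GroundTruth",
    "simulate_phase_pair",
    "compose_observable",
    "simulate_protocol",
    "default_protocol",
]


@dataclass(frozen=True)
class CouplingTerm:
    """One Fourier term of a coupling function q_i(phi_self, phi_other):
    ``coefficient * kind(k_self * phi_self + k_other * phi_other)``."""

    kind: str          # "sin" or "cos"
    k_self: int
    k_other: int
    coefficient: float

    def __call__(self, phi_self, phi_other):
        arg = self.k_self * phi_self + self.k_other * phi_other
        f = np.sin if self.kind == "sin" else np.cos
        return self.coefficient * f(arg)


@dataclass(frozen=True)
class OscillatorSpec:
    """One phase oscillator: natural frequency (rad/s), coupling terms
    defining q_i, and dynamical noise intensity (rad/sqrt(s))."""

    omega: float
    coupling: tuple[CouplingTerm, ...] = ()
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValidationError("natural frequency must be positive")
        if self.noise < 0:
            raise ValidationError("noise intensity must be non-negative")

    def drift(self, phi_self, phi_other):
        total = self.omega
        for term in self.coupling:
            total = total + term(phi_self, phi_other)
        return total


@dataclass
class GroundTruth:
    """Exact phases, per-oscillator specs per stage, and the seed used."""

    phases: dict[str, np.ndarray]
    specs: dict[str, dict[str, OscillatorSpec]]  # stage -> oscillator -> spec
    seed: int
    fs: float = 0.0

    def phase_series(self, name: str) -> PhaseSeries:
        return PhaseSeries(self.phases[name], self.fs, kind="phase")


def _check_fs(fs: float, *specs: OscillatorSpec) -> None:
    fmax = max(s.omega for s in specs) / (2 * np.pi)
    if fs < 10 * fmax:
        raise ValidationError(
            f"fs = {fs} Hz too low for a {fmax:.3g} Hz oscillator "
            f"(need >= {10 * fmax:.3g} Hz)")


def _integrate_forced(spec: OscillatorSpec, forcing: np.ndarray, h: float,
                      xi: np.ndarray, phi0: float) -> np.ndarray:
    """Vectorised Euler–Maruyama when the drift does not depend on the
    oscillator's own phase (all coupling terms have k_self = 0)."""
    drift = np.full(forcing.size, spec.omega)
    for term in spec.coupling:
        drift += term(0.0, forcing)
    incr = h * drift + np.sqrt(h) * spec.noise * xi
    phi = np.empty(forcing.size)
    phi[0] = phi0
    np.cumsum(incr[:-1], out=phi[1:])
    phi[1:] += phi0
    return phi


def _integrate_pair(spec1: OscillatorSpec, spec2: OscillatorSpec,
                    n_steps: int, fs: float, rng: np.random.Generator,
                    phi0: tuple[float, float] = (0.0, 0.0)):
    """Euler–Maruyama integration of two coupled phases at step h = 1/fs."""
    h = 1.0 / fs
    sqh = np.sqrt(h)
    xi = rng.standard_normal((2, n_steps))
    # fast path: oscillator 2 autonomous and oscillator 1 forced only by
    # phi_2 (the generator's RSA configuration) -> closed cumulative sums
    if not spec2.coupling and all(t.k_self == 0 for t in spec1.coupling):
        phi2 = _integrate_forced(
            OscillatorSpec(spec2.omega, (), spec2.noise),
            np.zeros(n_steps), h, xi[1], phi0[1])
        phi1 = _integrate_forced(spec1, phi2, h, xi[0], phi0[0])
        return phi1, phi2
    phi1 = np.empty(n_steps)
    phi2 = np.empty(n_steps)
    phi1[0], phi2[0] = phi0
    for n in range(n_steps - 1):
        phi1[n + 1] = (phi1[n] + h * spec1.drift(phi1[n], phi2[n])
                       + sqh * spec1.noise * xi[0, n])
        phi2[n + 1] = (phi2[n] + h * spec2.drift(phi2[n], phi1[n])
                       + sqh * spec2.noise * xi[1, n])
    return phi1, phi2


def simulate_phase_pair(spec1: OscillatorSpec, spec2: OscillatorSpec,
                        duration: float, fs: float, seed: int
                        ) -> tuple[PhaseSeries, PhaseSeries, GroundTruth]:
    """Simulate a coupled phase pair for ``duration`` seconds at rate ``fs``.

    Oscillator 1's coupling terms take phi_1 as phi_self and phi_2 as
    phi_other, and vice versa.  Raises if ``fs`` is below ten times the
    fastest natural frequency (aliasing guard) or duration < 60 s.
    """
    if duration < 60:
        raise ValidationError("duration must be >= 60 s")
    _check_fs(fs, spec1, spec2)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    phi1, phi2 = _integrate_pair(spec1, spec2, n, fs, rng)
    truth = GroundTruth(
        phases={"osc1": phi1, "osc2": phi2},
        specs={"all": {"osc1": spec1, "osc2": spec2}},
        seed=seed, fs=fs)
    return (PhaseSeries(phi1, fs, "phase"), PhaseSeries(phi2, fs, "phase"),
            truth)


def compose_observable(phase_cardiac: PhaseSeries, phase_resp: PhaseSeries,
                       amplitudes: tuple[float, float] = (1.0, 0.5),
                       noise_sd: float = 0.0, seed: int = 0,
                       channel: str = "SIGNAL") -> SignalRecord:
    """Compose g(t) = A_c cos(phi_c) + A_r cos(phi_r) + white noise."""
    if (phase_cardiac.fs != phase_resp.fs
            or phase_cardiac.n_samples != phase_resp.n_samples):
        raise ValidationError("cardiac and respiratory phases must align")
    a_c, a_r = amplitudes
    g = a_c * np.cos(phase_cardiac.phase) + a_r * np.cos(phase_resp.phase)
    if noise_sd > 0:
        g = g + np.random.default_rng(seed).normal(0.0, noise_sd, g.size)
    return SignalRecord(channels=[channel], samples=g[None, :],
                        fs=phase_cardiac.fs)


@dataclass(frozen=True)
class StageSpec:
    """One protocol stage of the generator.

    ``resp_gain`` multiplies the respiration-to-cardiac coupling coefficient
    and ``coupling_shift`` adds a phase lag to its respiratory argument
    (emulating the altered respiratory-to-cardiac transfer during paced
    breathing that shifts the coupling function along the respiratory axis).
    """

    label: str
    duration_s: float
    resp_freq_hz: float
    resp_gain: float = 1.0
    coupling_shift: float = 0.0
    amplitudes: tuple[float, float] = (1.0, 0.5)
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("stage duration must be positive")
        if not (0.05 <= self.resp_freq_hz <= 0.6):
            raise ValidationError(
                f"respiratory frequency {self.resp_freq_hz} Hz outside the "
                "respiration band")


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered stage specs for the generator."""

    stages: tuple[StageSpec, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValidationError("protocol needs at least one stage")

    @property
    def total_duration(self) -> float:
        return sum(s.duration_s for s in self.stages)


#: Default channel roles: cardiac natural frequencies (Hz) per channel.
DEFAULT_CHANNELS = {"BP": 1.00, "SAS_LEFT": 1.04, "SAS_RIGHT": 0.96}
#: Baseline respiration-to-cardiac coupling coefficient (rad/s).
BASE_COUPLING = 0.4
#: Dynamical noise intensities (rad/sqrt(s)).
CARDIAC_NOISE = 0.10
RESP_NOISE = 0.20


def default_protocol() -> ProtocolSpec:
    """The study's four-stage protocol: A baseline, B paced 6 breaths/min,
    C paced with resistance, D recovery; 10 min each (40 min total).

    Paced stages breathe at 0.1 Hz with enhanced respiratory drive (gain ×2
    in B, ×3 in C), stronger respiratory amplitude in the observables, and a
    shifted coupling function (B more than C, so recovery is most similar to
    baseline and resistance partially restores the baseline shape).
    """
    return ProtocolSpec(stages=(
        StageSpec("A", 600.0, 0.25, 1.0, 0.0, (1.0, 2.0), 0.1),
        StageSpec("B", 600.0, 0.10, 2.0, 1.1, (1.0, 3.0), 0.1),
        StageSpec("C", 600.0, 0.10, 3.0, 0.6, (1.0, 4.0), 0.1),
        StageSpec("D", 600.0, 0.25, 1.0, 0.0, (1.0, 2.0), 0.1),
    ))


def simulate_protocol(protocol: ProtocolSpec | None = None,
                      channels: dict[str, float] | None = None,
                      fs: float = 50.0, seed: int = 0
                      ) -> tuple[SignalRecord, StageProtocol, GroundTruth]:
    """Simulate a full multichannel protocol recording.

    All channels share one respiratory phase; each channel has its own
    cardiac phase driven by the shared respiration through
    ``q_c = gain * BASE_COUPLING * sin(phi_resp + shift)``.  Phases are
    continuous across stage boundaries; coupling gains and respiratory
    frequency switch stepwise at the boundaries.

    Returns the composite recording, the stage protocol, and the exact
    ground truth (phases and per-stage oscillator specs).
    """
    if protocol is None:
        protocol = default_protocol()
    if channels is None:
        channels = dict(DEFAULT_CHANNELS)
    for name in channels:
        if not isinstance(channels[name], (int, float)):
            raise ConfigurationError(f"unknown channel role for {name!r}")
    rng = np.random.default_rng(seed)
    names = list(channels)

    resp_phase: list[np.ndarray] = []
    card_phase: dict[str, list[np.ndarray]] = {n: [] for n in names}
    spec_by_stage: dict[str, dict[str, OscillatorSpec]] = {}
    stages: list[tuple[str, float, float]] = []
    t = 0.0
    phi_r = 0.0
    phi_c = {n: rng.uniform(0, 2 * np.pi) for n in names}

    h = 1.0 / fs
    for st in protocol.stages:
        n_steps = int(round(st.duration_s * fs))
        stages.append((st.label, t, t + n_steps * h))
        omega_r = 2 * np.pi * st.resp_freq_hz
        resp_spec = OscillatorSpec(omega=omega_r, noise=RESP_NOISE)
        spec_by_stage[st.label] = {"resp": resp_spec}
        # shared respiratory phase for this stage
        pr = _integrate_forced(resp_spec, np.zeros(n_steps), h,
                               rng.standard_normal(n_steps), phi_r)
        phi_r = pr[-1] + h * omega_r  # carry continuity into the next stage
        resp_phase.append(pr)
        for name in names:
            coeff = st.resp_gain * BASE_COUPLING
            # sin(phi_resp + shift) = cos(shift) sin(phi_r) + sin(shift) cos(phi_r)
            cspec = OscillatorSpec(
                omega=2 * np.pi * channels[name],
                coupling=(
                    CouplingTerm("sin", 0, 1, coeff * np.cos(st.coupling_shift)),
                    CouplingTerm("cos", 0, 1, coeff * np.sin(st.coupling_shift)),
                ),
                noise=CARDIAC_NOISE)
            spec_by_stage[st.label][name] = cspec
            pc = _integrate_forced(cspec, pr, h,
                                   rng.standard_normal(n_steps), phi_c[name])
            phi_c[name] = pc[-1] + h * cspec.drift(pc[-1], pr[-1])
            card_phase[name].append(pc)
        t += n_steps * h

    resp = np.concatenate(resp_phase)
    phases = {"resp": resp}
    rows = []
    for name in names:
        pc = np.concatenate(card_phase[name])
        phases[f"{name}_cardiac"] = pc
        g = np.empty(pc.size)
        i = 0
        for st in protocol.stages:
            n_steps = int(round(st.duration_s * fs))
            sl = slice(i, i + n_steps)
            a_c, a_r = st.amplitudes
            g[sl] = (a_c * np.cos(pc[sl]) + a_r * np.cos(resp[sl])
                     + rng.normal(0.0, st.noise_sd, n_steps))
            i += n_steps
        rows.append(g)

    record = SignalRecord(channels=names, samples=np.vstack(rows), fs=fs)
    truth = GroundTruth(phases=phases, specs=spec_by_stage, seed=seed, fs=fs)
    return record, StageProtocol(stages), truth
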