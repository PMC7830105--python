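"""Statsmodels-style modelling surface.

:class:`PhaseCouplingModel` holds a pair of unwrapped phases (oscillator 1
= cardiac, oscillator 2 = respiratory, by package convention) and the model
configuration; :meth:`PhaseCouplingModel.fit` runs the windowed dynamical
Bayesian inference and returns a :class:`PhaseCouplingResults` carrying the
per-window estimates, the derived coupling measures and their surrogate
significance threshold.

    >>> model = PhaseCouplingModel.from_signals(bp, bp, fs=50)  # doctest: +SKIP
    >>> res = model.fit()                                       # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import FourierBasis, build_basis
from .dbi import InferenceResult, coupling_coefficients, infer_windows
from .exceptions import DegenerateInputError, ValidationError
from .io import RunConfig, SignalRecord, StageProtocol
from .measures import (CouplingGrid, coupling_grid, coupling_strength,
                       directionality, directed_strengths, group_average_grid,
                       polar_similarity, stage_aggregate)
from .preprocess import PhaseSeries, extract_phase
from .surrogates import SurrogateEnsemble, surrogate_strength_threshold

__all__ = ["PhaseCouplingModel", "PhaseCouplingResults"]


class PhaseCouplingModel:
    """Coupled phase-oscillator model of one directed interaction pair.

    Parameters
    ----------
    phase_cardiac, phase_respiratory : PhaseSeries
        Unwrapped invariant phases of the two modes (equal fs and length).
    order : int
        Fourier expansion order K of the phase model (default 2).
    window_s : float
        Inference window length in seconds (non-overlapping).
    propagation : float
        Prior-diffusion constant between windows; 0 = independent windows.
    """

    def __init__(self, phase_cardiac: PhaseSeries,
                 phase_respiratory: PhaseSeries,
                 order: int = 2, window_s: float = 50.0,
                 propagation: float = 0.2) -> None:
        self.phase1 = phase_cardiac
        self.phase2 = phase_respiratory
        self.basis: FourierBasis = build_basis(order)
        self.window_s = float(window_s)
        self.propagation = float(propagation)

    @classmethod
    def from_signals(cls, cardiac_source: np.ndarray,
                     respiratory_source: np.ndarray, fs: float,
                     config: RunConfig | None = None) -> "PhaseCouplingModel":
        """Build the model from two raw signal channels.

        The cardiac phase is extracted from ``cardiac_source`` and the
        respiratory phase from ``respiratory_source`` (which may be the same
        channel) through the full preprocessing pipeline: detrend,
        z-normalise, bandpass, protophase, protophase-to-phase.  The first
        and last ``config.edge_exclude_s`` seconds are dropped to keep
        filter and analytic-signal edge effects out of the inference.
        """
        cfg = config or RunConfig()
        ph_c = extract_phase(cardiac_source, fs, cfg.cardiac_band,
                             order=cfg.filter_order,
                             detrend_window_s=cfg.detrend_window_s,
                             n_harmonics=cfg.protophase_harmonics)
        ph_r = extract_phase(respiratory_source, fs, cfg.respiratory_band,
                             order=cfg.filter_order,
                             detrend_window_s=cfg.detrend_window_s,
                             n_harmonics=cfg.protophase_harmonics)
        t_end = ph_c.t0 + ph_c.n_samples / fs
        ph_c = ph_c.crop(ph_c.t0 + cfg.edge_exclude_s, t_end - cfg.edge_exclude_s)
        ph_r = ph_r.crop(ph_r.t0 + cfg.edge_exclude_s, t_end - cfg.edge_exclude_s)
        return cls(ph_c, ph_r, order=cfg.fourier_order,
                   window_s=cfg.window_s, propagation=cfg.propagation)

    @classmethod
    def from_recording(cls, record: SignalRecord, cardiac_channel: str,
                       respiratory_channel: str,
                       config: RunConfig | None = None) -> "PhaseCouplingModel":
        """Build the model for one directed pair of a multichannel record:
        respiratory phase of ``respiratory_channel`` driving the cardiac
        phase of ``cardiac_channel``."""
        return cls.from_signals(record.channel(cardiac_channel),
                                record.channel(respiratory_channel),
                                record.fs, config=config)

    def fit(self, tol: float = 1e-5, max_iter: int = 100,
            prior_variance: float = 100.0,
            fix_noise: np.ndarray | None = None) -> "PhaseCouplingResults":
        """Run the windowed inference and return a results object."""
        inference = infer_windows(
            self.phase1, self.phase2, self.basis,
            window_s=self.window_s, propagation=self.propagation,
            tol=tol, max_iter=max_iter, prior_variance=prior_variance,
            fix_noise=fix_noise)
        return PhaseCouplingResults(model=self, inference=inference)


@dataclass
class PhaseCouplingResults:
    """Fitted coupling model: per-window estimates and derived measures."""

    model: PhaseCouplingModel
    inference: InferenceResult

    @property
    def basis(self) -> FourierBasis:
        return self.inference.basis

    @property
    def n_windows(self) -> int:
        return len(self.inference)

    @property
    def midtimes(self) -> np.ndarray:
        return self.inference.midtimes

    @property
    def converged(self) -> np.ndarray:
        return np.array([e.converged for e in self.inference.estimates])

    def omega(self, oscillator: int) -> np.ndarray:
        """Per-window natural frequency of one oscillator, rad/s."""
        return np.array([e.omega[oscillator - 1]
                         for e in self.inference.estimates])

    def strength(self, oscillator: int = 1) -> np.ndarray:
        """Per-window coupling strength sigma INTO ``oscillator`` (default:
        respiration -> cardiac)."""
        return np.array([
            coupling_strength(coupling_coefficients(e, oscillator, self.basis))
            for e in self.inference.estimates])

    def directionality(self) -> np.ndarray:
        """Per-window directionality index D(t); NaN where undefined."""
        out = np.empty(self.n_windows)
        for w, est in enumerate(self.inference.estimates):
            try:
                out[w] = directionality(directed_strengths(est, self.basis))
            except DegenerateInputError:
                out[w] = np.nan
        return out

    def noise_intensity(self) -> np.ndarray:
        """Per-window inferred noise intensities, shape (n_windows, 2),
        in rad/sqrt(s) (square roots of the noise-covariance diagonal)."""
        return np.sqrt(np.stack([np.diag(e.noise_cov)
                                 for e in self.inference.estimates]))

    def coupling_grid(self, oscillator: int = 1, M: int = 100,
                      windows: slice | np.ndarray | None = None,
                      coupling_only: bool = True) -> CouplingGrid:
        """Time-averaged coupling function of one oscillator on an M×M grid.

        Averages the coefficient vectors over ``windows`` (all by default)
        and evaluates the coupling function; with ``coupling_only`` the grid
        uses only terms involving the partner's phase, i.e. the coupling
        function proper.
        """
        coeffs = self.inference.coefficient_matrix(oscillator)
        if windows is not None:
            coeffs = coeffs[windows]
        if coeffs.size == 0:
            raise ValidationError("no windows selected")
        mean_c = coeffs.mean(axis=0)
        if coupling_only:
            mean_c = np.where(self.basis.coupling_mask(oscillator), mean_c, 0.0)
        pair = "resp->card" if oscillator == 1 else "card->resp"
        return coupling_grid(mean_c, self.basis, M=M, label=pair)

    def stage_table(self, protocol: StageProtocol,
                    statistic: str = "median") -> pd.DataFrame:
        """Per-stage aggregates of sigma (into the cardiac mode) and D."""
        sig = stage_aggregate(self.midtimes, self.strength(1), protocol,
                              statistic)
        dvals = stage_aggregate(self.midtimes, self.directionality(), protocol,
                                statistic)
        return pd.DataFrame({"sigma": sig, "D": dvals})

    def stage_grids(self, protocol: StageProtocol, oscillator: int = 1,
                    M: int = 100) -> dict[str, CouplingGrid]:
        """Window-averaged coupling-function grid per protocol stage."""
        out: dict[str, CouplingGrid] = {}
        for label, start, end in protocol.stages:
            sel = (self.midtimes >= start) & (self.midtimes < end)
            if sel.any():
                out[label] = self.coupling_grid(oscillator, M=M, windows=sel)
        return out

    def similarity(self, other: "PhaseCouplingResults | CouplingGrid",
                   oscillator: int = 1, M: int = 100) -> float:
        """Polar similarity (percent) between this fit's time-averaged
        coupling function and another fit's (or an explicit grid)."""
        mine = self.coupling_grid(oscillator, M=M)
        theirs = other if isinstance(other, CouplingGrid) \
            else other.coupling_grid(oscillator, M=M)
        return polar_similarity(mine, theirs)

    def surrogate_threshold(self, n_surr: int = 100, seed: int = 0,
                            permute: str = "driver") -> SurrogateEnsemble:
        """Cycle-permutation null ensemble for the strength into osc. 1."""
        return surrogate_strength_threshold(
            self.model.phase1, self.model.phase2, self.basis,
            window_s=self.model.window_s,
            propagation=self.model.propagation,
            n_surr=n_surr, seed=seed, permute=permute)

    def summary(self) -> str:
        """Human-readable summary table of the fitted interaction."""
        f1 = self.omega(1) / (2 * np.pi)
        f2 = self.omega(2) / (2 * np.pi)
        sig = self.strength(1)
        d = self.directionality()
        noise = self.noise_intensity()
        lines = [
            "Phase coupling model (dynamical Bayesian inference)",
            "=" * 55,
            f"windows: {self.n_windows} x {self.model.window_s:.0f} s"
            f"   basis order K={self.basis.order} ({len(self.basis)} terms)"
            f"   propagation={self.model.propagation}",
            f"converged windows: {int(self.converged.sum())}/{self.n_windows}",
            "-" * 55,
            f"cardiac frequency  (osc 1): {f1.mean():7.4f} Hz"
            f"  (sd {f1.std():.4f})",
            f"respiratory freq.  (osc 2): {f2.mean():7.4f} Hz"
            f"  (sd {f2.std():.4f})",
            f"coupling strength sigma (resp->card): median "
            f"{np.median(sig):.4f}  IQR [{np.percentile(sig, 25):.4f}, "
            f"{np.percentile(sig, 75):.4f}]",
            f"directionality D: median {np.nanmedian(d):+.3f}"
            f"  ({'respiration drives cardiac' if np.nanmedian(d) < 0 else 'cardiac drives respiration'})",
            f"noise intensity (rad/sqrt(s)): osc1 {noise[:, 0].mean():.4f}, "
            f"osc2 {noise[:, 1].mean():.4f}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-window measures as a tidy DataFrame."""
        return pd.DataFrame({
            "midtime_s": self.midtimes,
            "omega1_rad_s": self.omega(1),
            "omega2_rad_s": self.omega(2),
            "sigma_into_1": self.strength(1),
            "sigma_into_2": self.strength(2),
            "D": self.directionality(),
            "converged": self.converged,
        })
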