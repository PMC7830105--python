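"""Cycle phase permutation surrogates and significance thresholds.

A cycle phase permutation surrogate cuts an unwrapped phase at its upward
crossings of successive multiples of 2π into complete cycles, randomly
permutes the cycles (as blocks of within-cycle phase increments) and
re-accumulates them into a continuous unwrapped phase.  Intra-cycle dynamics
are preserved exactly while inter-cycle (and hence inter-oscillator) timing
relations are destroyed; the total phase gain is conserved by construction.

Coupling estimates on such surrogates give the null distribution of the
coupling strength; the significance threshold is the surrogate mean plus
two standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import FourierBasis, build_basis
from .dbi import infer_windows
from .exceptions import ValidationError
from .measures import CouplingGrid, coupling_grid, coupling_strength, \
    group_average_grid
from .preprocess import PhaseSeries

__all__ = ["SurrogateEnsemble", "cycle_phase_permutation",
           "surrogate_strength_threshold", "surrogate_mean_grid"]


@dataclass
class SurrogateEnsemble:
    """Null-distribution summary from an ensemble of surrogates."""

    strengths: np.ndarray                 # per-surrogate sigma values
    grids: list[CouplingGrid] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, float)
        if self.strengths.size < 2:
            raise ValidationError(
                "need >= 2 surrogates for a mean + 2 SD threshold")

    @property
    def mean(self) -> float:
        return float(self.strengths.mean())

    @property
    def sd(self) -> float:
        return float(self.strengths.std(ddof=1))

    @property
    def threshold(self) -> float:
        """Significance threshold: surrogate mean plus two standard
        deviations."""
        return self.mean + 2.0 * self.sd


def cycle_phase_permutation(phase: PhaseSeries,
                            seed: int | np.random.Generator = 0
                            ) -> PhaseSeries:
    """Randomly permute the complete 2π cycles of an unwrapped phase.

    Leading and trailing partial cycles stay in place; the permuted interior
    cycles are re-accumulated so the surrogate is continuous and its total
    phase gain equals the original's exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    phi = phase.phase
    # upward crossings of multiples of 2π: index of first sample at/above
    # each level k*2π reached inside the record
    k0 = int(np.ceil(phi[0] / (2 * np.pi)))
    if phi[0] % (2 * np.pi) == 0:
        k0 += 1  # a start exactly on a level begins, not ends, a cycle
    k1 = int(np.floor(phi[-1] / (2 * np.pi)))
    levels = np.arange(k0, k1 + 1) * 2 * np.pi
    if levels.size < 4:  # need >= 3 complete interior cycles
        raise ValidationError(
            "cycle permutation needs at least 3 complete cycles")
    cuts = np.searchsorted(phi, levels, side="left")
    incr = np.diff(phi)
    # blocks of increments: [start..cut0), [cut0..cut1), ..., [cutN..end)
    n_cycles = cuts.size - 1
    order = rng.permutation(n_cycles)
    blocks = [incr[:cuts[0] - 1] if cuts[0] > 0 else incr[:0]]
    blocks += [incr[cuts[i] - 1:cuts[i + 1] - 1] for i in order]
    blocks.append(incr[cuts[-1] - 1:])
    new_incr = np.concatenate(blocks)
    surrogate = np.empty_like(phi)
    surrogate[0] = phi[0]
    np.cumsum(new_incr, out=surrogate[1:])
    surrogate[1:] += phi[0]
    # conserve the total gain exactly against floating-point reordering
    surrogate[-1] = phi[-1]
    return PhaseSeries(surrogate, phase.fs, phase.kind, t0=phase.t0)


def _median_strength(result, basis: FourierBasis, oscillator: int) -> float:
    mask = basis.coupling_mask(oscillator)
    vals = [coupling_strength(e.coefficients[oscillator - 1][mask])
            for e in result.estimates]
    return float(np.median(vals))


def surrogate_strength_threshold(phase1: PhaseSeries, phase2: PhaseSeries,
                                 basis: FourierBasis | int = 2,
                                 window_s: float = 50.0,
                                 propagation: float = 0.2,
                                 n_surr: int = 100,
                                 seed: int = 0,
                                 permute: str = "driver",
                                 collect_grids: bool = False,
                                 grid_size: int = 64) -> SurrogateEnsemble:
    """Null distribution of the coupling strength into oscillator 1.

    For each surrogate the candidate driver phase (oscillator 2 by default;
    ``permute`` in {"driver", "driven", "both"}) is cycle-permuted, the
    windowed inference is re-run, and the median over windows of the
    coupling strength into oscillator 1 is recorded.  The ensemble threshold
    is the surrogate mean plus two standard deviations.
    """
    if n_surr < 2:
        raise ValidationError("need n_surr >= 2 (sd undefined otherwise)")
    if permute not in ("driver", "driven", "both"):
        raise ValidationError(f"bad permute mode {permute!r}")
    if isinstance(basis, int):
        basis = build_basis(basis)
    rng = np.random.default_rng(seed)
    strengths = np.empty(n_surr)
    grids: list[CouplingGrid] = []
    failures = 0
    for s in range(n_surr):
        p1 = cycle_phase_permutation(phase1, rng) if permute in ("driven", "both") \
            else phase1
        p2 = cycle_phase_permutation(phase2, rng) if permute in ("driver", "both") \
            else phase2
        try:
            res = infer_windows(p1, p2, basis, window_s=window_s,
                                propagation=propagation)
        except ValidationError:
            failures += 1
            strengths[s] = np.nan
            continue
        strengths[s] = _median_strength(res, basis, oscillator=1)
        if collect_grids:
            mask = basis.coupling_mask(1)
            coeffs = np.mean([e.coefficients[0] for e in res.estimates], axis=0)
            coeffs = np.where(mask, coeffs, 0.0)
            grids.append(coupling_grid(coeffs, basis, M=grid_size,
                                       label="surrogate"))
    if failures > 0.2 * n_surr:
        raise ValidationError(
            f"inference failed in {failures}/{n_surr} surrogates")
    strengths = strengths[np.isfinite(strengths)]
    return SurrogateEnsemble(strengths=strengths, grids=grids)


def surrogate_mean_grid(ensemble: SurrogateEnsemble) -> CouplingGrid:
    """Element-wise mean of the surrogate coupling-function grids; near-flat
    when the surrogates have destroyed a genuine coupling."""
    if not ensemble.grids:
        raise ValidationError("ensemble holds no grids")
    return group_average_grid(ensemble.grids, label="surrogate mean")
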