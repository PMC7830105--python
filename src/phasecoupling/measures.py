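"""Coupling-function grids and the three quantitative coupling measures.

* directionality index  D = (c2 - c1)/(c1 + c2), where c_i is the Euclidean
  norm of the coupling coefficients acting ON oscillator i; D < 0 means the
  second oscillator (respiration, by convention) predominantly drives the
  first (cardiac);
* coupling strength     sigma = Euclidean norm of the coupling-coefficient
  subvector of one directed influence;
* polar similarity      |rho| = |<q1~ q2~>| / (|q1~| |q2~|) × 100, the
  magnitude of the centered correlation of two coupling functions over the
  2π×2π grid, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import FourierBasis
from .dbi import InferenceResult, WindowEstimate, coupling_coefficients
from .exceptions import DegenerateInputError, ValidationError
from .io import StageProtocol

__all__ = [
    "CouplingGrid",
    "DirectedStrengths",
    "coupling_grid",
    "directionality",
    "coupling_strength",
    "polar_similarity",
    "directed_strengths",
    "stage_aggregate",
    "group_average_grid",
]


@dataclass
class CouplingGrid:
    """A coupling function q(phi_1, phi_2) sampled on a uniform M×M grid
    over [0, 2π)²; ``values[a, b]`` is q at phi_1 = 2πa/M, phi_2 = 2πb/M."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("coupling grid must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite grid values")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def centered(self) -> np.ndarray:
        return self.values - self.values.mean()

    def amplitude(self) -> float:
        """Peak-to-peak amplitude max(q) - min(q) over the grid."""
        return float(self.values.max() - self.values.min())


@dataclass
class DirectedStrengths:
    """Norms of the coupling coefficients acting ON each oscillator."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValidationError("coupling norms must be non-negative")


def coupling_grid(coefficients: np.ndarray, basis: FourierBasis,
                  M: int = 100, label: str = "") -> CouplingGrid:
    """Evaluate the coupling function of one oscillator on the M×M grid.

    Uses all non-constant basis terms (the constant natural-frequency term
    is excluded); ``coefficients`` is the full per-oscillator coefficient
    vector aligned to the basis.
    """
    if M < 8:
        raise ValidationError("grid size must be >= 8")
    coefficients = np.asarray(coefficients, float)
    if coefficients.size != len(basis):
        raise ValidationError(
            f"{coefficients.size} coefficients for a {len(basis)}-term basis")
    ax = np.arange(M) * (2 * np.pi / M)
    phi1, phi2 = np.meshgrid(ax, ax, indexing="ij")
    q = np.zeros((M, M))
    for coef, term in zip(coefficients[1:], basis.terms[1:]):
        if coef != 0.0:
            q += coef * term(phi1, phi2)
    return CouplingGrid(values=q, label=label)


def coupling_strength(subvector: np.ndarray) -> float:
    """Coupling strength sigma: Euclidean norm of a coupling subvector.

    The strength is reported as the square root of the sum of squared
    coupling coefficients, making it a proper norm (invariant under basis
    re-enumeration and phase-origin rotation).
    """
    return float(np.linalg.norm(np.asarray(subvector, float)))


def directed_strengths(estimate: WindowEstimate,
                       basis: FourierBasis) -> DirectedStrengths:
    """Per-window norms of coupling into oscillator 1 and into oscillator 2."""
    return DirectedStrengths(
        c1=coupling_strength(coupling_coefficients(estimate, 1, basis)),
        c2=coupling_strength(coupling_coefficients(estimate, 2, basis)),
    )


def directionality(strengths: DirectedStrengths) -> float:
    """Directionality index D = (c2 - c1)/(c1 + c2) in [-1, 1].

    D < 0 means oscillator 2 predominantly drives oscillator 1 (with the
    package convention 1 = cardiac, 2 = respiratory: respiration drives the
    cardiac mode); raises if both norms vanish, in which case the direction
    is undefined and must be reported as missing rather than 0.
    """
    c1, c2 = strengths.c1, strengths.c2
    if c1 + c2 == 0:
        raise DegenerateInputError("direction undefined when c1 = c2 = 0")
    return (c2 - c1) / (c1 + c2)


def polar_similarity(grid1: CouplingGrid, grid2: CouplingGrid) -> float:
    """Similarity modulus |rho| of two coupling functions, in percent.

    |rho| = |<q1~ q2~>| / (|q1~||q2~|) × 100, with q~ the deviation from the
    grid mean, <.> the average over the 2π×2π grid and |q~| the grid
    root-mean-square.  100 means identical shape (up to scale and sign),
    0 means orthogonal shapes.
    """
    if grid1.size != grid2.size:
        raise ValidationError("grids must have equal size")
    q1 = grid1.centered()
    q2 = grid2.centered()
    n1 = np.sqrt((q1 * q1).mean())
    n2 = np.sqrt((q2 * q2).mean())
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("constant grid has no shape to compare")
    return float(abs((q1 * q2).mean()) / (n1 * n2) * 100.0)


def stage_aggregate(midtimes: np.ndarray, values: np.ndarray,
                    protocol: StageProtocol,
                    statistic: str = "median") -> dict[str, float]:
    """Aggregate per-window values into per-stage values.

    A window belongs to the stage whose half-open interval contains its
    midtime.  Missing values (NaN) are ignored; a stage with no windows maps
    to NaN.
    """
    if statistic not in ("mean", "median"):
        raise ValidationError(f"statistic must be mean or median")
    midtimes = np.asarray(midtimes, float)
    values = np.asarray(values, float)
    fn = np.nanmean if statistic == "mean" else np.nanmedian
    out: dict[str, float] = {}
    for label, start, end in protocol.stages:
        in_stage = (midtimes >= start) & (midtimes < end)
        vals = values[in_stage]
        vals = vals[np.isfinite(vals)]
        out[label] = float(fn(vals)) if vals.size else float("nan")
    return out


def group_average_grid(grids: list[CouplingGrid],
                       label: str = "") -> CouplingGrid:
    """Element-wise arithmetic mean of coupling-function grids."""
    if not grids:
        raise ValidationError("cannot average an empty list of grids")
    M = grids[0].size
    if any(g.size != M for g in grids):
        raise ValidationError("grids must share one size")
    return CouplingGrid(np.mean([g.values for g in grids], axis=0),
                        label=label or grids[0].label)
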