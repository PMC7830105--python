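"""Windowed dynamical Bayesian inference for coupled phase oscillators.

The data model is a pair of stochastic phase equations

    dphi_i/dt = omega_i + q_i(phi_i, phi_j) + xi_i(t),   i = 1, 2,

with the deterministic right-hand side expanded in the Fourier basis
``Phi_k(phi_1, phi_2)`` (see :mod:`.basis`) and xi white Gaussian noise with
2×2 covariance ``E``.  Within each time window the scheme alternates, until
convergence, between

  (i)  the noise update
         E = (h/N) * sum_n r_n r_n^T,     r_n = phidot_n - C Phi(phi*_n),

  (ii) the Gaussian parameter update with stacked coefficient vector
       c = [c^(1); c^(2)]:
         Xi_post  = Xi_prior + h * sum_n (E^-1 kron Phi_n Phi_n^T)
         r_post   = Xi_prior c_prior
                    + h * sum_n Phi_n (E^-1 phidot_n)_i          (block i)
                    - (h/2) * sum_n dPhi_n/dphi_i                (block i)
         c_post   = Xi_post^-1 r_post,

where phase velocities are forward finite differences
phidot_n = (phi_{n+1} - phi_n)/h and the basis is evaluated at window
midpoints phi*_n = (phi_{n+1} + phi_n)/2.  The -(h/2) sum dPhi/dphi term is
the drift (Stratonovich-type) correction of the midpoint discretisation.

Between consecutive windows the posterior propagates: the next prior mean is
the current posterior mean and the prior covariance is the posterior
covariance inflated diagonally by (p * c_post)^2 per coefficient, where p is
the propagation constant; this lets the inferred parameters follow
time-varying dynamics.  p = 0 gives independent windows with the initial
(weakly informative) prior each time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import FourierBasis, build_basis
from .exceptions import ValidationError
from .preprocess import PhaseSeries

__all__ = ["WindowEstimate", "InferenceResult", "infer_windows",
           "coupling_coefficients"]


@dataclass
class WindowEstimate:
    """Inferred model for one time window.

    ``coefficients`` has shape (2, n_terms): row i holds c^(i+1) aligned to
    the basis ordering, so ``coefficients[i, 0]`` is the natural frequency
    omega_{i+1} in rad/s.  ``noise_cov`` is the inferred 2×2 noise covariance
    E (rad²/s); ``posterior_cov`` the (2B × 2B) posterior covariance of the
    stacked coefficient vector.
    """

    midtime: float
    coefficients: np.ndarray
    noise_cov: np.ndarray
    posterior_cov: np.ndarray
    converged: bool = True
    n_iterations: int = 0

    @property
    def omega(self) -> np.ndarray:
        """Natural (constant-term) frequencies of the two oscillators, rad/s."""
        return self.coefficients[:, 0]


@dataclass
class InferenceResult:
    """Ordered window estimates plus the configuration that produced them."""

    estimates: list[WindowEstimate]
    basis: FourierBasis
    window_s: float
    propagation: float

    def __post_init__(self) -> None:
        mids = [e.midtime for e in self.estimates]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValidationError("window midtimes must strictly increase")

    def __len__(self) -> int:
        return len(self.estimates)

    @property
    def midtimes(self) -> np.ndarray:
        return np.array([e.midtime for e in self.estimates])

    def coefficient_matrix(self, oscillator: int) -> np.ndarray:
        """(n_windows, n_terms) coefficients c^(i) over time."""
        return np.stack([e.coefficients[oscillator - 1] for e in self.estimates])


def coupling_coefficients(estimate: WindowEstimate, oscillator: int,
                          basis: FourierBasis) -> np.ndarray:
    """Coefficients through which the partner drives ``oscillator``.

    Returns the subvector of c^(i) over basis terms with nonzero partner
    index, in canonical basis order.
    """
    mask = basis.coupling_mask(oscillator)
    return estimate.coefficients[oscillator - 1][mask]


def _window_update(phi_mid: np.ndarray, phidot: np.ndarray, h: float,
                   basis: FourierBasis, c_prior: np.ndarray,
                   xi_prior: np.ndarray, fix_noise: np.ndarray | None,
                   tol: float, max_iter: int):
    """One window's alternating noise/parameter update.  Returns
    (c_post (2,B), E, post_cov, converged, n_iter)."""
    B = len(basis)
    P = basis.design(phi_mid[0], phi_mid[1])            # (B, N)
    N = P.shape[1]
    PPt = h * (P @ P.T)                                  # (B, B)
    Pdot = P @ phidot.T * h                              # (B, 2): sum Phi*phidot_i
    # drift correction: (h/2) sum_n dPhi/dphi_i per equation i
    v = np.stack([
        basis.design_derivative(phi_mid[0], phi_mid[1], wrt=i + 1).sum(axis=1)
        for i in range(2)
    ], axis=1) * (h / 2.0)                               # (B, 2)

    c = c_prior.copy()                                   # (2, B)
    E = fix_noise.copy() if fix_noise is not None else np.eye(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if fix_noise is None:
            resid = phidot - c @ P                       # (2, N)
            E = (h / N) * (resid @ resid.T)
            E += 1e-12 * np.eye(2)                       # guard: keep invertible
        Einv = np.linalg.inv(E)
        # stacked precision and information vector
        Xi = xi_prior + np.kron(Einv, PPt)
        r = xi_prior @ c_prior.reshape(-1) + (Pdot @ Einv - v).T.reshape(-1)
        c_new = np.linalg.solve(Xi, r).reshape(2, B)
        change = np.linalg.norm(c_new - c) / max(np.linalg.norm(c_new), 1e-300)
        c = c_new
        if change < tol:
            converged = True
            break
    post_cov = np.linalg.inv(Xi)
    return c, E, post_cov, converged, it


def infer_windows(phase1: PhaseSeries, phase2: PhaseSeries,
                  basis: FourierBasis | int = 2,
                  window_s: float = 50.0,
                  propagation: float = 0.2,
                  tol: float = 1e-5,
                  max_iter: int = 100,
                  prior_variance: float = 100.0,
                  fix_noise: np.ndarray | None = None) -> InferenceResult:
    """Run windowed Bayesian inference on a pair of unwrapped phases.

    Parameters
    ----------
    phase1, phase2 : PhaseSeries
        Unwrapped phases with equal sampling rate and length; oscillator 1
        is conventionally the cardiac mode and oscillator 2 the respiratory
        mode.
    basis : FourierBasis or int
        The Fourier basis, or an order K from which to build it.
    window_s : float
        Window length in seconds; windows are non-overlapping.
    propagation : float
        Prior-diffusion constant p; 0 makes windows independent.
    prior_variance : float
        Diagonal variance of the initial zero-mean prior.  ``numpy.inf``
        gives a flat prior (zero precision).
    fix_noise : (2, 2) array, optional
        If given, the noise covariance E is held fixed at this value instead
        of being inferred (used for oracle equivalence with weighted least
        squares).

    Returns
    -------
    InferenceResult
        Windows whose estimates did not converge within ``max_iter`` are
        flagged via ``WindowEstimate.converged``.
    """
    if isinstance(basis, int):
        basis = build_basis(basis)
    if phase1.fs != phase2.fs or phase1.n_samples != phase2.n_samples:
        raise ValidationError("phase series must share fs and length")
    for p in (phase1, phase2):
        if p.phase[-1] - p.phase[0] <= 0:
            raise ValidationError("phases must increase on average")
    fs = phase1.fs
    h = 1.0 / fs
    n_win = int(round(window_s * fs))
    B = len(basis)
    if n_win < 4 * B:
        raise ValidationError(
            f"window of {n_win} samples too short for {B} basis terms "
            f"(need >= {4 * B})")

    phi = np.vstack([phase1.phase, phase2.phase])        # (2, N)
    phidot_full = np.diff(phi, axis=1) / h
    phimid_full = 0.5 * (phi[:, 1:] + phi[:, :-1])

    if np.isinf(prior_variance):
        xi_init = np.zeros((2 * B, 2 * B))
    else:
        xi_init = np.eye(2 * B) / prior_variance
    c_prior = np.zeros((2, B))
    xi_prior = xi_init.copy()

    estimates: list[WindowEstimate] = []
    n_samples = phi.shape[1]
    for start in range(0, n_samples - n_win + 1, n_win):
        # velocities between consecutive samples inside this window
        sl = slice(start, start + n_win - 1)
        c, E, post_cov, ok, it = _window_update(
            phimid_full[:, sl], phidot_full[:, sl], h, basis,
            c_prior, xi_prior, fix_noise, tol, max_iter)
        midtime = phase1.t0 + (start + n_win / 2.0) * h
        estimates.append(WindowEstimate(
            midtime=midtime, coefficients=c, noise_cov=E,
            posterior_cov=post_cov, converged=ok, n_iterations=it))
        if propagation > 0:
            # propagate: posterior -> next prior, with diagonal diffusion
            sigma = post_cov + np.diag((propagation * c.reshape(-1)) ** 2)
            xi_prior = np.linalg.inv(sigma)
            c_prior = c.copy()
        else:
            xi_prior = xi_init.copy()
            c_prior = np.zeros((2, B))
    return InferenceResult(estimates=estimates, basis=basis,
                           window_s=window_s, propagation=propagation)
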