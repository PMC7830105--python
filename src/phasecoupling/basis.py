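"""Fourier basis for the coupled phase-oscillator model.

The phase dynamics of each oscillator are expanded as

    dphi_i/dt = sum_k c_k^(i) * Phi_k(phi_1, phi_2)

where the Phi_k are a constant term plus sin/cos(k1*phi_1 + k2*phi_2) over a
canonical half-plane of integer index pairs.  Enumerating (k1, k2) over the
half-plane k1 > 0, or k1 = 0 and k2 > 0, covers every distinct harmonic
exactly once (the opposite pair gives the same functions up to sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["BasisTerm", "FourierBasis", "build_basis"]


@dataclass(frozen=True)
class BasisTerm:
    """One basis function: ``kind('const'|'sin'|'cos')`` of k1*phi1 + k2*phi2."""
    kind: str
    k1: int
    k2: int

    def __call__(self, phi1, phi2):
        if self.kind == "const":
            return np.ones_like(np.broadcast_arrays(phi1, phi2)[0], dtype=float)
        arg = self.k1 * np.asarray(phi1) + self.k2 * np.asarray(phi2)
        return np.sin(arg) if self.kind == "sin" else np.cos(arg)

    def derivative(self, phi1, phi2, wrt: int):
        """d(term)/d(phi_wrt), wrt in {1, 2}."""
        k = self.k1 if wrt == 1 else self.k2
        if self.kind == "const" or k == 0:
            return np.zeros_like(np.broadcast_arrays(phi1, phi2)[0], dtype=float)
        arg = self.k1 * np.asarray(phi1) + self.k2 * np.asarray(phi2)
        return k * np.cos(arg) if self.kind == "sin" else -k * np.sin(arg)


@dataclass(frozen=True)
class FourierBasis:
    """Canonically ordered Fourier basis of order K.

    Term count is ``1 + ((2K+1)^2 - 1)`` (one constant, then a sin and a cos
    for each of the ((2K+1)^2 - 1)/2 half-plane index pairs); 9 terms for
    K = 1, 25 for K = 2.
    """

    order: int
    terms: tuple[BasisTerm, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"Fourier order must be >= 1, got {self.order}")
        terms = [BasisTerm("const", 0, 0)]
        K = self.order
        for k1 in range(0, K + 1):
            for k2 in range(-K, K + 1):
                if k1 == 0 and k2 <= 0:
                    continue  # half-plane: k1 > 0, or k1 == 0 and k2 > 0
                terms.append(BasisTerm("sin", k1, k2))
                terms.append(BasisTerm("cos", k1, k2))
        object.__setattr__(self, "terms", tuple(terms))

    def __len__(self) -> int:
        return len(self.terms)

    def design(self, phi1: np.ndarray, phi2: np.ndarray) -> np.ndarray:
        """Evaluate all terms; shape (n_terms, n_samples)."""
        phi1 = np.asarray(phi1, float)
        phi2 = np.asarray(phi2, float)
        out = np.empty((len(self.terms), phi1.size))
        out[0] = 1.0
        for r, term in enumerate(self.terms[1:], start=1):
            out[r] = term(phi1, phi2)
        return out

    def design_derivative(self, phi1, phi2, wrt: int) -> np.ndarray:
        """Evaluate d(Phi_k)/d(phi_wrt) for all terms; shape (n_terms, n)."""
        phi1 = np.asarray(phi1, float)
        phi2 = np.asarray(phi2, float)
        out = np.zeros((len(self.terms), phi1.size))
        for r, term in enumerate(self.terms[1:], start=1):
            out[r] = term.derivative(phi1, phi2, wrt)
        return out

    def coupling_mask(self, oscillator: int) -> np.ndarray:
        """Boolean mask of terms through which the PARTNER drives ``oscillator``.

        For oscillator i with partner j these are the non-constant terms with
        k_j != 0 — the terms through which phi_j enters the phase velocity of
        oscillator i.
        """
        if oscillator not in (1, 2):
            raise ValidationError(f"oscillator must be 1 or 2, got {oscillator}")
        partner_k = [(t.k2 if oscillator == 1 else t.k1) for t in self.terms]
        mask = np.array([k != 0 for k in partner_k])
        mask[0] = False
        return mask

    def nonconstant_mask(self) -> np.ndarray:
        mask = np.ones(len(self.terms), dtype=bool)
        mask[0] = False
        return mask


def build_basis(order: int) -> FourierBasis:
    """Build the canonical Fourier basis of order K (K = 2 in the study)."""
    return FourierBasis(order)
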