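import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phasecoupling import (CouplingTerm, OscillatorSpec, ValidationError,
                           build_basis, coupling_coefficients, infer_windows,
                           simulate_phase_pair)
from phasecoupling.dbi import WindowEstimate
from phasecoupling.preprocess import PhaseSeries


def linear_phases(f1, f2, duration, fs):
    t = np.arange(0, duration, 1 / fs)
    return (PhaseSeries(2 * np.pi * f1 * t, fs),
            PhaseSeries(2 * np.pi * f2 * t, fs))


class TestBasis:
    @pytest.mark.parametrize("order,count", [(1, 9), (2, 25), (3, 49)])
    def test_term_count(self, order, count):
        assert len(build_basis(order)) == count

    def test_invalid_order_rejected(self):
        with pytest.raises(ValidationError):
            build_basis(0)

    def test_all_cross_terms_present(self):
        basis = build_basis(2)
        cross = {(t.k1, t.k2) for t in basis.terms
                 if t.k1 != 0 and t.k2 != 0}
        assert cross == {(k1, k2) for k1 in (1, 2) for k2 in
                         (-2, -1, 1, 2)}

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_terms_2pi_periodic(self, phi1, phi2):
        basis = build_basis(2)
        a = basis.design(np.array([phi1]), np.array([phi2]))
        b = basis.design(np.array([phi1 + 2 * np.pi]), np.array([phi2]))
        c = basis.design(np.array([phi1]), np.array([phi2 + 2 * np.pi]))
        np.testing.assert_allclose(a, b, atol=1e-9)
        np.testing.assert_allclose(a, c, atol=1e-9)

    def test_coupling_mask_selects_partner_terms(self):
        basis = build_basis(2)
        mask1 = basis.coupling_mask(1)
        assert not mask1[0]
        for term, flag in zip(basis.terms, mask1):
            assert flag == (term.kind != "const" and term.k2 != 0)


class TestOracleEquivalence:
    def test_flat_prior_fixed_noise_equals_weighted_least_squares(self):
        """With a flat prior and fixed E the posterior mean must equal the
        closed-form weighted least-squares solution (including the midpoint
        drift correction), computed here independently with dense algebra."""
        rng = np.random.default_rng(7)
        fs = 20.0
        t = np.arange(0, 60, 1 / fs)
        phi1 = 2 * np.pi * 1.1 * t + 0.05 * rng.normal(size=t.size).cumsum()
        phi2 = 2 * np.pi * 0.25 * t + 0.05 * rng.normal(size=t.size).cumsum()
        p1 = PhaseSeries(phi1, fs)
        p2 = PhaseSeries(phi2, fs)
        E = np.array([[0.02, 0.005], [0.005, 0.03]])
        basis = build_basis(2)
        res = infer_windows(p1, p2, basis, window_s=60.0, propagation=0.0,
                            prior_variance=np.inf, fix_noise=E, max_iter=50)
        assert len(res) == 1
        c_pkg = res.estimates[0].coefficients

        # independent closed form on the same discretisation
        h = 1 / fs
        phid = np.diff(np.vstack([phi1, phi2]), axis=1) / h
        mid1 = 0.5 * (phi1[1:] + phi1[:-1])
        mid2 = 0.5 * (phi2[1:] + phi2[:-1])
        P = basis.design(mid1, mid2)
        V = np.stack([basis.design_derivative(mid1, mid2, wrt=i + 1).sum(axis=1)
                      for i in range(2)], axis=1)
        Einv = np.linalg.inv(E)
        A = np.kron(Einv, h * (P @ P.T))
        b = ((h * (P @ phid.T)) @ Einv - (h / 2) * V).T.reshape(-1)
        c_ols = np.linalg.solve(A, b).reshape(2, -1)
        np.testing.assert_allclose(c_pkg, c_ols, atol=1e-8)

    def test_noiseless_uncoupled_linear_phases(self):
        p1, p2 = linear_phases(1.1, 0.25, 120, 50.0)
        res = infer_windows(p1, p2, 2, window_s=60.0, propagation=0.0)
        for est in res.estimates:
            np.testing.assert_allclose(est.omega,
                                       [2 * np.pi * 1.1, 2 * np.pi * 0.25],
                                       atol=1e-6)
            assert np.max(np.abs(est.coefficients[:, 1:])) < 1e-6


class TestParameterRecovery:
    def test_recovers_sine_coupling_coefficient(self, coupled_pair):
        p1, p2, truth = coupled_pair
        res = infer_windows(p1, p2, 2, window_s=50.0)
        basis = res.basis
        idx = next(i for i, t in enumerate(basis.terms)
                   if t.kind == "sin" and t.k1 == 0 and t.k2 == 1)
        med = np.median(res.coefficient_matrix(1)[:, idx])
        assert 0.3 < med < 0.5

    def test_stage_b_norm_recovery_across_seeds(self):
        """Relative RMSE of the recovered respiration->cardiac coupling norm
        over seeds of the paced-breathing (stage B) configuration < 15%."""
        shift = 1.1
        coeff = 0.8
        spec1 = OscillatorSpec(2 * np.pi * 1.0, (
            CouplingTerm("sin", 0, 1, coeff * np.cos(shift)),
            CouplingTerm("cos", 0, 1, coeff * np.sin(shift))), 0.1)
        spec2 = OscillatorSpec(2 * np.pi * 0.1, (), 0.2)
        norms = []
        for seed in range(8):
            p1, p2, _ = simulate_phase_pair(spec1, spec2, 300.0, 20.0, seed)
            res = infer_windows(p1, p2, 2, window_s=50.0)
            sig = [np.linalg.norm(coupling_coefficients(e, 1, res.basis))
                   for e in res.estimates]
            norms.append(np.median(sig))
        rel_rmse = np.sqrt(np.mean((np.array(norms) - coeff) ** 2)) / coeff
        assert rel_rmse < 0.15

    def test_noise_intensity_recovered(self):
        spec1 = OscillatorSpec(2 * np.pi * 1.1,
                               (CouplingTerm("sin", 0, 1, 0.4),), 0.1)
        spec2 = OscillatorSpec(2 * np.pi * 0.25, (), 0.2)
        ratios = []
        for seed in range(6):
            p1, p2, _ = simulate_phase_pair(spec1, spec2, 300.0, 20.0, seed)
            res = infer_windows(p1, p2, 2, window_s=50.0)
            e11 = np.median([e.noise_cov[0, 0] for e in res.estimates])
            ratios.append(np.sqrt(e11) / 0.1)
        assert abs(np.median(ratios) - 1.0) < 0.2

    def test_posterior_variance_shrinks_with_window_length(self):
        p1, p2 = linear_phases(1.1, 0.25, 240, 20.0)
        fixed = np.eye(2) * 0.01
        var = []
        for w in (60.0, 120.0, 240.0):
            res = infer_windows(p1, p2, 2, window_s=w, propagation=0.0,
                                fix_noise=fixed)
            var.append(np.trace(res.estimates[0].posterior_cov))
        assert var[0] > var[1] > var[2]


class TestCouplingCoefficients:
    def test_only_partner_terms_selected(self):
        basis = build_basis(2)
        coeffs = np.zeros((2, len(basis)))
        coeffs[0, 0] = 7.0  # constant term excluded
        est = WindowEstimate(0.0, coeffs, np.eye(2), np.eye(2 * len(basis)))
        assert np.all(coupling_coefficients(est, 1, basis) == 0)

    def test_unit_sine_coefficient_appears(self):
        basis = build_basis(2)
        coeffs = np.zeros((2, len(basis)))
        idx = next(i for i, t in enumerate(basis.terms)
                   if t.kind == "sin" and t.k1 == 0 and t.k2 == 1)
        coeffs[0, idx] = 1.0
        est = WindowEstimate(0.0, coeffs, np.eye(2), np.eye(2 * len(basis)))
        sub = coupling_coefficients(est, 1, basis)
        assert np.linalg.norm(sub) == pytest.approx(1.0)
        assert 1.0 in sub

    def test_norm_invariant_under_half_plane_reflection(self):
        """Re-enumerating the basis over the opposite half-plane maps
        sin(k·phi) -> -sin(-k·phi) and cos -> cos, leaving the norm of any
        coupling subvector unchanged."""
        basis = build_basis(2)
        rng = np.random.default_rng(0)
        coeffs = np.zeros((2, len(basis)))
        coeffs[0] = rng.normal(size=len(basis))
        est = WindowEstimate(0.0, coeffs, np.eye(2), np.eye(2 * len(basis)))
        sub = coupling_coefficients(est, 1, basis)
        # reflected enumeration: same functions, sines negated
        reflected = np.array([
            -c if t.kind == "sin" else c
            for c, t in zip(coeffs[0], basis.terms)])
        est2 = WindowEstimate(0.0, np.vstack([reflected, coeffs[1]]),
                              np.eye(2), np.eye(2 * len(basis)))
        sub2 = coupling_coefficients(est2, 1, basis)
        assert np.linalg.norm(sub) == pytest.approx(np.linalg.norm(sub2))

    def test_bad_oscillator_index_rejected(self):
        basis = build_basis(1)
        est = WindowEstimate(0.0, np.zeros((2, len(basis))), np.eye(2),
                             np.eye(2 * len(basis)))
        with pytest.raises(ValidationError):
            coupling_coefficients(est, 3, basis)


class TestContracts:
    def test_mismatched_series_rejected(self):
        p1, _ = linear_phases(1.0, 0.25, 120, 20.0)
        _, p2 = linear_phases(1.0, 0.25, 120, 25.0)
        with pytest.raises(ValidationError):
            infer_windows(p1, p2, 2, window_s=60.0)

    def test_window_too_short_for_basis_rejected(self):
        p1, p2 = linear_phases(1.0, 0.25, 120, 20.0)
        with pytest.raises(ValidationError):
            infer_windows(p1, p2, 2, window_s=2.0)

    def test_decreasing_phase_rejected(self):
        t = np.arange(0, 120, 0.05)
        with pytest.raises(ValidationError):
            PhaseSeries(-2 * np.pi * t, 20.0)
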