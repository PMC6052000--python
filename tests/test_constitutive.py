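"""Fibrous-matrix law: branch continuity, stress kernels, tangent, fitting."""

import warnings

import numpy as np
import pytest

from tendonscale.constitutive import (DeformationState, FibrousMatrixParams,
                                      IdentifiabilityWarning, cauchy_stress,
                                      cauchy_stress_batch,
                                      fiber_stress_derivative, fit_matrix_params,
                                      numerical_tangent, uniaxial_response)


def neo_hookean_oracle(F, kappa, G):
    """Independent textbook compressible neo-Hookean Cauchy stress."""
    J = np.linalg.det(F)
    B = F @ F.T
    Bbar = J ** (-2 / 3) * B
    dev = Bbar - np.trace(Bbar) / 3 * np.eye(3)
    return kappa * (J - 1) * np.eye(3) + G * dev / J


class TestFiberDerivative:
    def test_zero_below_and_at_lambda1(self, matrix_params):
        assert fiber_stress_derivative(1.0, matrix_params) == 0.0
        assert fiber_stress_derivative(matrix_params.lambda1, matrix_params) == 0.0

    def test_continuity_at_lambda2(self, matrix_params):
        p = matrix_params
        expected = p.E_f * (p.lambda2 - p.lambda1) / (p.n + 1)
        below = fiber_stress_derivative(p.lambda2 - 1e-12, p)
        at = fiber_stress_derivative(p.lambda2, p)
        assert at == pytest.approx(expected, rel=1e-9)
        assert below == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("lam_break", ["lambda1", "lambda2"])
    def test_c1_continuity(self, matrix_params, lam_break):
        p = matrix_params
        lb = getattr(p, lam_break)
        h = 1e-7
        d_lo = (fiber_stress_derivative(lb, p)
                - fiber_stress_derivative(lb - h, p)) / h
        d_hi = (fiber_stress_derivative(lb + h, p)
                - fiber_stress_derivative(lb, p)) / h
        assert abs(d_hi - d_lo) < 1e-4 * p.E_f

    def test_slope_at_lambda2_equals_Ef(self, matrix_params):
        p = matrix_params
        h = 1e-7
        d = (fiber_stress_derivative(p.lambda2 + h, p)
             - fiber_stress_derivative(p.lambda2 - h, p)) / (2 * h)
        assert d == pytest.approx(p.E_f, rel=1e-4)


class TestCauchyStress:
    def test_zero_at_identity(self, matrix_params):
        st = DeformationState.from_F(np.eye(3))
        assert np.allclose(cauchy_stress(st, matrix_params), 0.0)

    def test_pure_dilation_below_lambda1(self, matrix_params):
        s = 1.004  # below lambda1 = 1.01: no fiber term, dev part vanishes
        st = DeformationState.from_F(s * np.eye(3))
        sig = cauchy_stress(st, matrix_params)
        assert np.allclose(sig, matrix_params.kappa * (s ** 3 - 1) * np.eye(3),
                           rtol=1e-12, atol=1e-14)

    def test_reduces_to_neo_hookean_when_Ef_zero(self, rng):
        p = FibrousMatrixParams.from_youngs(E_b=2.0, E_f=0.0, lambda1=1.01,
                                            lambda2=1.05, n=3, m=5)
        for _ in range(20):
            F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            sig = cauchy_stress(DeformationState.from_F(F), p)
            assert np.allclose(sig, neo_hookean_oracle(F, p.kappa, p.G),
                               atol=1e-10)

    def test_objectivity_under_rotations(self, matrix_params, rng):
        from scipy.stats import special_ortho_group
        F = np.diag([1.06, 0.97, 0.99])
        sig = cauchy_stress(DeformationState.from_F(F), matrix_params)
        for Q in special_ortho_group.rvs(3, size=5,
                                         random_state=np.random.RandomState(7)):
            sig_rot = cauchy_stress(DeformationState.from_F(Q @ F), matrix_params)
            assert np.allclose(sig_rot, Q @ sig @ Q.T, atol=1e-10)

    def test_fiber_stress_eigenvectors_are_principal_directions(self, matrix_params):
        F = np.array([[1.08, 0.03, 0.0], [0.0, 0.96, 0.01], [0.0, 0.0, 0.98]])
        st = DeformationState.from_F(F)
        p0 = FibrousMatrixParams(kappa=matrix_params.kappa, G=matrix_params.G,
                                 E_f=0.0, lambda1=1.01, lambda2=1.04, n=5, m=10)
        sig_f = cauchy_stress(st, matrix_params) - cauchy_stress(st, p0)
        # each principal direction must be an eigenvector of the fiber stress
        for a in range(3):
            na = st.principal_directions[:, a]
            v = sig_f @ na
            assert np.linalg.norm(np.cross(v, na)) < 1e-10 * (
                np.linalg.norm(v) + 1.0)

    def test_inverted_element_rejected(self, matrix_params):
        with pytest.raises(ValueError, match="inverted"):
            DeformationState.from_F(np.diag([-1.0, 1.0, 1.0]))

    def test_batch_matches_single_state(self, matrix_params, rng):
        for _ in range(50):
            F2 = np.eye(2) + 0.12 * rng.standard_normal((2, 2))
            lh = 1.0 + 0.1 * rng.standard_normal()
            if (F2[0, 0] * F2[1, 1] - F2[0, 1] * F2[1, 0]) * lh <= 0.1:
                continue
            s2, sh = cauchy_stress_batch(F2[None], np.array([lh]), matrix_params)
            Ff = np.zeros((3, 3))
            Ff[:2, :2] = F2
            Ff[2, 2] = lh
            ref = cauchy_stress(DeformationState.from_F(Ff), matrix_params)
            assert np.allclose(s2[0], ref[:2, :2], atol=1e-12)
            assert sh[0] == pytest.approx(ref[2, 2], abs=1e-12)


class TestUniaxialResponse:
    def test_zero_at_unit_stretch(self, matrix_params):
        assert uniaxial_response(np.array([1.0]), matrix_params)[0] == 0.0

    def test_small_strain_modulus_isotropic(self):
        p = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=0.0, lambda1=1.01,
                                            lambda2=1.05, n=3, m=5)
        g = np.array([1.0, 1.00001])
        s = uniaxial_response(g, p)
        E = (s[1] - s[0]) / 1e-5
        expected = 9 * p.kappa * p.G / (3 * p.kappa + p.G)
        assert E == pytest.approx(expected, rel=1e-3)

    def test_tangent_jump_across_lambda1_stress_continuous(self, matrix_params):
        l1 = matrix_params.lambda1
        g = np.array([1.0, l1 - 2e-4, l1 - 1e-4, l1 + 1e-4, l1 + 2e-4])
        s = uniaxial_response(g, matrix_params)
        # stress continuous across the branch point: the jump over a 2e-4
        # stretch gap is bounded by ~1.5x the local tangent modulus
        assert abs(s[3] - s[2]) < 1.5 * matrix_params.E_b * 2e-4
        # fiber branch engages only above lambda1: tangent grows beyond
        g2 = np.array([1.0, matrix_params.lambda2 + 0.02,
                       matrix_params.lambda2 + 0.021])
        s2 = uniaxial_response(g2, matrix_params)
        t_hi = (s2[2] - s2[1]) / 0.001
        t_lo = (s[2] - s[1]) / 1e-4
        assert t_hi > 2.0 * t_lo

    def test_energy_consistency_closed_loop(self, matrix_params):
        # hyperelastic: work along up-down uniaxial loop cancels
        g_up = np.linspace(1.0, 1.08, 200)
        s_up = uniaxial_response(g_up, matrix_params)
        w_up = np.trapezoid(s_up, g_up)
        w_dn = np.trapezoid(s_up[::-1], g_up[::-1])
        assert abs(w_up + w_dn) < 1e-12 * abs(w_up)

    def test_stress_monotone_in_fiber_ratio(self):
        g = np.linspace(1.0, 1.08, 40)
        prev = None
        for Ef in (0.0, 1.0, 10.0, 100.0):
            p = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=Ef, lambda1=1.01,
                                                lambda2=1.04, n=5, m=10)
            s = uniaxial_response(g, p)
            if prev is not None:
                assert np.all(s >= prev - 1e-10)
            prev = s


class TestNumericalTangent:
    def test_isotropic_moduli_at_identity(self):
        p = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=0.0, lambda1=1.01,
                                            lambda2=1.05, n=3, m=5)
        C = numerical_tangent(DeformationState.from_F(np.eye(3)), p)
        kappa = (C[0, 0] + 2 * C[0, 1]) / 3
        G = (C[0, 0] - C[0, 1]) / 2
        assert kappa == pytest.approx(p.kappa, rel=1e-4)
        assert G == pytest.approx(p.G, rel=1e-4)

    def test_major_symmetry_in_branch_interior(self, matrix_params):
        F = np.diag([1.06, 0.97, 0.97])  # axial stretch inside fiber regime
        C = numerical_tangent(DeformationState.from_F(F), matrix_params)
        assert np.abs(C - C.T).max() < 1e-6 * np.abs(C).max()

    def test_matches_directional_secant(self, matrix_params, rng):
        F = np.diag([1.05, 0.975, 0.975])
        st = DeformationState.from_F(F)
        C = numerical_tangent(st, matrix_params, h=1e-6)
        D = rng.standard_normal((3, 3))
        D = 0.5 * (D + D.T)
        h = 1e-6
        tau = lambda Fm: (np.linalg.det(Fm)
                          * cauchy_stress(DeformationState.from_F(Fm),
                                          matrix_params))
        dtau = (tau((np.eye(3) + h / 2 * D) @ F)
                - tau((np.eye(3) - h / 2 * D) @ F)) / h
        voigt = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
        dvec = np.array([D[i, j] for i, j in voigt])
        # off-diagonal Voigt strains appear twice in D
        dvec[3:] *= 2.0
        pred = C @ dvec
        got = np.array([dtau[i, j] for i, j in voigt])
        assert np.allclose(pred, got, rtol=2e-5,
                           atol=1e-5 * np.abs(got).max())

    def test_h_bounds(self, matrix_params):
        st = DeformationState.from_F(np.eye(3))
        with pytest.raises(ValueError):
            numerical_tangent(st, matrix_params, h=1e-2)


class TestFitMatrixParams:
    def test_noiseless_round_trip(self, matrix_params):
        g = np.linspace(1.0, 1.12, 80)
        s = uniaxial_response(g, matrix_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_matrix_params(g, s)
        for name, true in [("E_b", 1.0), ("E_f", 30.0), ("lambda1", 1.01),
                           ("lambda2", 1.04), ("n", 5.0), ("m", 10.0)]:
            assert getattr(fit.params, name) == pytest.approx(true, rel=0.02), name

    def test_short_curve_flags_unidentifiable(self, matrix_params):
        g = np.linspace(1.0, 1.008, 30)   # never reaches lambda1 = 1.01
        s = uniaxial_response(g, matrix_params)
        with pytest.warns(IdentifiabilityWarning):
            fit = fit_matrix_params(g, s)
        assert fit.warnings

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FibrousMatrixParams(kappa=1.0, G=1.0, E_f=1.0, lambda1=1.05,
                                lambda2=1.01, n=2, m=2)
        with pytest.raises(ValueError):
            FibrousMatrixParams(kappa=-1.0, G=1.0, E_f=1.0, lambda1=1.0,
                                lambda2=1.1, n=2, m=2)
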