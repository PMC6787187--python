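"""Constitutive model: energies, stresses, plane stress, kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import asamesh as am
from asamesh.errors import (
    GeometryError,
    IncompressibilityError,
    InvertedElementError,
)
from asamesh.mechanics import ACTIVE_PRESSURE, AS_PRINTED, Kinematics


def random_gradient(rng, spread=0.3):
    """Random F with positive J, in-plane block plus thickness stretch."""
    while True:
        F = np.eye(3) + rng.uniform(-spread, spread, (3, 3))
        F[2, :2] = 0.0
        F[:2, 2] = 0.0
        if np.linalg.det(F) > 0.2:
            return F


class TestLameConversion:
    def test_calibrated_values(self):
        mu, lam = am.lame_from_engineering(1.9, 0.3)
        assert mu == pytest.approx(0.7308, abs=5e-5)
        assert lam == pytest.approx(1.0962, abs=5e-5)

    def test_zero_poisson(self):
        assert am.lame_from_engineering(4.0, 0.0) == (2.0, 0.0)

    def test_hand_arithmetic(self):
        mu, lam = am.lame_from_engineering(3.0, 0.25)
        assert mu == pytest.approx(1.2, rel=1e-12)
        assert lam == pytest.approx(1.2, rel=1e-12)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(IncompressibilityError):
            am.lame_from_engineering(1.9, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(E=st.floats(1e-3, 1e3), nu=st.floats(-0.9, 0.45))
    def test_engineering_constants_round_trip(self, E, nu):
        # (mu, lam) must invert back to the engineering constants
        mu, lam = am.lame_from_engineering(E, nu)
        assert mu > 0
        E_back = mu * (3 * lam + 2 * mu) / (lam + mu)
        nu_back = lam / (2 * (lam + mu))
        assert E_back == pytest.approx(E, rel=1e-10)
        assert nu_back == pytest.approx(nu, rel=1e-8, abs=1e-10)

    def test_material_params_derive_consistently(self):
        mat = am.MaterialParams(E_young=1.9, nu=0.3)
        mu, lam = am.lame_from_engineering(1.9, 0.3)
        assert mat.mu == pytest.approx(mu, rel=1e-12)
        assert mat.lam == pytest.approx(lam, rel=1e-12)


class TestFreeEnergy:
    def test_rest_state_zero_in_both_modes(self):
        kin = Kinematics(np.eye(3))
        for mode in (AS_PRINTED, ACTIVE_PRESSURE):
            mat = am.MaterialParams(active_mode=mode)
            act = am.ActivationState(0.7)
            assert am.free_energy_density(kin, act, mat) == pytest.approx(0.0, abs=1e-14)

    def test_isotropic_stretch_scalar_oracle(self):
        mat = am.MaterialParams(active_mode=AS_PRINTED)
        kin = Kinematics(np.diag([1.1, 1.1, 1.1]))
        mu, lam = mat.mu, mat.lam
        expected = 0.5 * mu * (3 * 1.21 - 3 - 2 * np.log(1.331)) \
            + 0.5 * lam * np.log(1.331) ** 2
        val = am.free_energy_density(kin, am.ActivationState(0.0), mat)
        assert val == pytest.approx(expected, rel=1e-12)

    def test_mode_difference_identity(self):
        # U(as_printed) - U(active_pressure) = eta*beta*[(ln J)^2 - (J - 1)]
        rng = np.random.default_rng(7)
        m_ap = am.MaterialParams(active_mode=AS_PRINTED)
        m_pr = am.MaterialParams(active_mode=ACTIVE_PRESSURE)
        for _ in range(20):
            kin = Kinematics(random_gradient(rng))
            eta = rng.uniform(0, 1)
            act = am.ActivationState(eta)
            d = am.free_energy_density(kin, act, m_ap) \
                - am.free_energy_density(kin, act, m_pr)
            expected = eta * 2.0 * (np.log(kin.J) ** 2 - (kin.J - 1.0))
            assert d == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_as_printed_rest_state_is_global_minimum(self):
        # the printed active term is minimised at J = 1, so U >= 0 = U(I)
        rng = np.random.default_rng(11)
        mat = am.MaterialParams(active_mode=AS_PRINTED)
        for _ in range(50):
            kin = Kinematics(random_gradient(rng))
            act = am.ActivationState(rng.uniform(0, 1))
            assert am.free_energy_density(kin, act, mat) >= -1e-13

    def test_frame_indifference(self):
        rng = np.random.default_rng(3)
        mat = am.MaterialParams(active_mode=ACTIVE_PRESSURE)
        act = am.ActivationState(0.6)
        for _ in range(20):
            F = random_gradient(rng)
            theta = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            U1 = am.free_energy_density(Kinematics(F), act, mat)
            U2 = am.free_energy_density(Kinematics(R @ F), act, mat)
            assert U2 == pytest.approx(U1, rel=1e-12)


class TestFirstPKStress:
    def test_rest_state_stress_free_as_printed(self):
        mat = am.MaterialParams(active_mode=AS_PRINTED)
        st = am.first_pk_stress(Kinematics(np.eye(3)), am.ActivationState(1.0), mat)
        assert np.abs(st.P).max() < 1e-14

    def test_identity_active_pressure_gives_isotropic_tension(self):
        mat = am.MaterialParams(active_mode=ACTIVE_PRESSURE)  # beta = 2
        st = am.first_pk_stress(Kinematics(np.eye(3)), am.ActivationState(1.0), mat)
        assert np.allclose(st.sigma, 2.0 * np.eye(3), atol=1e-13)

    @pytest.mark.parametrize("mode", [AS_PRINTED, ACTIVE_PRESSURE])
    def test_stress_is_energy_gradient(self, mode):
        rng = np.random.default_rng(17)
        mat = am.MaterialParams(active_mode=mode)
        h = 1e-6
        for _ in range(100):
            F = random_gradient(rng)
            eta = rng.uniform(0, 1)
            act = am.ActivationState(eta)
            P = am.first_pk_stress(Kinematics(F), act, mat).P
            for i, J in [(0, 0), (0, 1), (1, 0), (1, 1), (2, 2)]:
                Fp, Fm = F.copy(), F.copy()
                Fp[i, J] += h
                Fm[i, J] -= h
                fd = (am.free_energy_density(Kinematics(Fp), act, mat)
                      - am.free_energy_density(Kinematics(Fm), act, mat)) / (2 * h)
                assert P[i, J] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_cauchy_from_pk_identity(self):
        rng = np.random.default_rng(23)
        mat = am.MaterialParams()
        for _ in range(10):
            kin = Kinematics(random_gradient(rng))
            st = am.first_pk_stress(kin, am.ActivationState(0.5), mat)
            assert np.allclose(st.sigma, st.P @ kin.F.T / kin.J, rtol=1e-10)

    def test_stress_scales_with_moduli(self):
        rng = np.random.default_rng(29)
        mat = am.MaterialParams()
        kin = Kinematics(random_gradient(rng))
        act = am.ActivationState(0.8)
        P1 = am.first_pk_stress(kin, act, mat).P
        P2 = am.first_pk_stress(kin, act, mat.scaled(3.5)).P
        assert np.allclose(P2, 3.5 * P1, rtol=1e-12)


class TestPlaneStressThickness:
    def test_rest_state_unit_thickness(self):
        mat = am.MaterialParams(active_mode=ACTIVE_PRESSURE)
        lam3 = am.plane_stress_thickness(np.eye(2), am.ActivationState(0.0), mat)
        assert lam3 == pytest.approx(1.0, abs=1e-12)

    def test_active_tension_thins_sheet_vs_grid_scan(self):
        mat = am.MaterialParams(active_mode=ACTIVE_PRESSURE)
        act = am.ActivationState(1.0)
        lam3 = am.plane_stress_thickness(np.eye(2), act, mat)
        assert lam3 < 1.0
        # independent dense-grid scan of the 33-stress root
        grid = np.linspace(0.3, 1.2, 90_001)
        resid = [am.first_pk_stress(Kinematics.from_plane(np.eye(2), t), act,
                                    mat).sigma[2, 2] for t in grid[::900]]
        coarse = grid[::900]
        sign_flip = np.flatnonzero(np.diff(np.sign(resid)))[0]
        assert coarse[sign_flip] <= lam3 <= coarse[sign_flip + 1]
        s33 = am.first_pk_stress(Kinematics.from_plane(np.eye(2), lam3), act,
                                 mat).sigma[2, 2]
        assert abs(s33) < 1e-10 * max(mat.mu, mat.beta)

    def test_as_printed_reduces_to_shifted_lame(self):
        # with the printed active term, lam3(eta) equals the passive solve
        # with lam replaced by lam + 2*eta*beta
        rng = np.random.default_rng(31)
        act = am.ActivationState(0.6)
        for _ in range(5):
            F2 = np.eye(2) + rng.uniform(-0.2, 0.2, (2, 2))
            if np.linalg.det(F2) <= 0.3:
                continue
            mat = am.MaterialParams(active_mode=AS_PRINTED)
            lam3 = am.plane_stress_thickness(F2, act, mat)
            lam_shift = mat.lam + 2 * act.eta_iso * mat.beta
            # passive material with E', nu' chosen to give (mu, lam_shift)
            nu_p = lam_shift / (2 * (mat.mu + lam_shift))
            E_p = 2 * mat.mu * (1 + nu_p)
            mat_shift = am.MaterialParams(E_young=E_p, nu=nu_p, beta=0.0,
                                          active_mode=ACTIVE_PRESSURE)
            lam3_shift = am.plane_stress_thickness(F2, am.ActivationState(0.0),
                                                   mat_shift)
            assert lam3 == pytest.approx(lam3_shift, rel=1e-9)

    def test_inverted_plane_gradient_rejected(self):
        mat = am.MaterialParams()
        with pytest.raises(InvertedElementError):
            am.plane_stress_thickness(np.diag([1.0, -1.0]), am.ActivationState(0.0), mat)


class TestKinematicsFromDisplacement:
    X = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 20.0]])

    def test_zero_displacement(self):
        kin = am.kinematics_from_displacement(self.X, np.zeros((3, 2)), 1.0)
        assert np.allclose(kin.F, np.eye(3))
        assert kin.I_C == pytest.approx(3.0)
        assert kin.J == pytest.approx(1.0)
        assert np.abs(kin.el_strain).max() < 1e-14

    def test_affine_displacement_reproduces_gradient(self):
        A = np.array([[1.1, 0.2], [-0.05, 0.9]])
        u = self.X @ (A - np.eye(2)).T
        kin = am.kinematics_from_displacement(self.X, u, 1.0)
        assert np.allclose(kin.F[:2, :2], A, atol=1e-13)

    def test_rigid_rotation_is_strain_free(self):
        th = 0.4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        u = self.X @ (R - np.eye(2)).T
        kin = am.kinematics_from_displacement(self.X, u, 1.0)
        assert kin.J == pytest.approx(1.0, rel=1e-12)
        assert np.allclose(kin.C, np.eye(3), atol=1e-12)
        assert np.abs(kin.el_strain).max() < 1e-12
        assert np.abs(kin.green_lagrange).max() < 1e-12

    def test_printed_strain_is_twice_green_lagrange(self):
        rng = np.random.default_rng(5)
        u = rng.uniform(-3, 3, (3, 2))
        kin = am.kinematics_from_displacement(self.X, u, 0.9)
        assert np.allclose(kin.el_strain, 2 * kin.green_lagrange, rtol=1e-14)

    def test_degenerate_triangle_rejected(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(GeometryError):
            am.kinematics_from_displacement(X, np.zeros((3, 2)), 1.0)

    def test_inverted_gradient_rejected(self):
        with pytest.raises(InvertedElementError):
            Kinematics(np.diag([1.0, -1.0, 1.0]))
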