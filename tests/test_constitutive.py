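import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from porogrowth.constitutive import (
    KinematicsError,
    MaterialParams,
    ParameterError,
    StateError,
    TransportParams,
    compute_kinematics,
    elastic_tangent,
    fluxes,
    kinematics_from_F,
    lame_from_c10_d1,
    neo_hookean_stress,
    partition_concentration,
    potentials_forward,
    secondary_from_potentials,
    total_stress,
    transport_coeffs,
)
from conftest import random_spd

TABLE_MAT = MaterialParams(C10=1e6, D1=5.5e-9)
TABLE_TP = TransportParams()  # artery defaults


class TestLame:
    def test_artery_values(self):
        lam, mu, kappa = lame_from_c10_d1(1e6, 5.5e-9)
        assert mu == pytest.approx(2e6)
        assert kappa == pytest.approx(3.6364e8, rel=1e-4)
        assert lam == pytest.approx(3.6230e8, rel=1e-4)

    def test_unit_scale(self):
        lam, mu, kappa = lame_from_c10_d1(0.5, 2.0)
        assert (lam, mu, kappa) == pytest.approx((1.0 / 3.0, 1.0, 1.0))

    @given(st.floats(1e-3, 1e9), st.floats(1e-12, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_defining_identity(self, C10, D1):
        lam, mu, kappa = lame_from_c10_d1(C10, D1)
        assert abs(lam + (2.0 / 3.0) * mu - kappa) <= 1e-12 * max(kappa, mu)

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ParameterError):
            lame_from_c10_d1(*bad)


class TestKinematics:
    def test_reference_state(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.0)
        assert np.allclose(kin.F, np.eye(3))
        assert kin.J == pytest.approx(1.0)
        assert np.allclose(kin.E, 0.0)
        assert np.allclose(kin.Ce, np.eye(3))
        assert kin.Je == pytest.approx(1.0)

    def test_pure_growth_split(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.1)
        assert np.allclose(kin.Fe, np.eye(3) / 1.1)
        assert kin.Je == pytest.approx(1.1**-3)
        assert kin.Jg == pytest.approx(1.331)

    def test_jacobian_multiplicativity(self, rng):
        for _ in range(20):
            gu = rng.uniform(-0.1, 0.1, (2, 2))
            hoop = 1.0 + rng.uniform(-0.1, 0.1)
            th = rng.uniform(0.8, 1.2)
            kin = compute_kinematics(gu, hoop, th)
            assert kin.J == pytest.approx(kin.Je * kin.Jg, rel=1e-12)
            assert np.allclose(kin.H, np.linalg.inv(kin.C))

    def test_inverted_element_raises(self):
        with pytest.raises(KinematicsError):
            compute_kinematics(np.array([[-2.0, 0.0], [0.0, 0.0]]), 1.0, 1.0)


class TestNeoHookean:
    def test_stress_free_reference(self):
        S = neo_hookean_stress(np.eye(3), TABLE_MAT)
        assert np.allclose(S, 0.0, atol=1e-9)

    def test_isotropic_stretch_hand_value(self):
        # Ce = 1.21 I, lam=2, mu=1: ln Je = 3 ln 1.1,
        # Seff_e = ((2*3*ln1.1 - 1)/1.21 + 1) I
        mat = MaterialParams(C10=0.5, D1=2.0 / (2.0 + 2.0 / 3.0))
        assert mat.lam == pytest.approx(2.0) and mat.mu == pytest.approx(1.0)
        S = neo_hookean_stress(1.21 * np.eye(3), mat)
        expected = (2.0 * 3.0 * np.log(1.1) - 1.0) / 1.21 + 1.0
        assert np.allclose(S, expected * np.eye(3))
        assert expected == pytest.approx(0.6462, abs=2e-4)

    def test_symmetry(self, rng):
        for _ in range(10):
            Ce = random_spd(rng)
            S = neo_hookean_stress(Ce, TABLE_MAT)
            assert np.allclose(S, S.T)

    def test_non_spd_rejected(self):
        with pytest.raises(KinematicsError):
            neo_hookean_stress(-np.eye(3), TABLE_MAT)


class TestElasticTangent:
    def test_identity_limit(self):
        mat = TABLE_MAT
        Le = elastic_tangent(np.eye(3), mat)
        d = np.eye(3)
        expected = (
            mat.lam * np.einsum("ij,kl->ijkl", d, d)
            + mat.mu * (np.einsum("ik,lj->ijkl", d, d) + np.einsum("il,kj->ijkl", d, d))
        )
        assert np.allclose(Le, expected)

    def test_finite_difference_consistency(self, rng):
        """Le : dCe / 2 matches central differences of the stress at 100
        random SPD elastic strains (rel. tol 1e-6)."""
        h = 1e-7
        for _ in range(100):
            Ce = random_spd(rng)
            Le = elastic_tangent(Ce, TABLE_MAT)
            Sfun = lambda X: neo_hookean_stress(X, TABLE_MAT)
            dnum = np.zeros((3, 3, 3, 3))
            for k in range(3):
                for l in range(3):
                    dC = np.zeros((3, 3))
                    dC[k, l] += 0.5 * h
                    dC[l, k] += 0.5 * h
                    dnum[:, :, k, l] = (Sfun(Ce + dC) - Sfun(Ce - dC)) / (2.0 * h)
            # contract both with a random symmetric direction
            V = random_spd(rng) - np.eye(3)
            lhs = np.einsum("ijkl,kl->ij", Le, V) / 2.0
            rhs = np.einsum("ijkl,kl->ij", dnum, V)
            assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-6 * np.abs(rhs).max())

    def test_major_symmetry(self, rng):
        for _ in range(10):
            Le = elastic_tangent(random_spd(rng), TABLE_MAT)
            assert np.allclose(Le, np.einsum("ijkl->klij", Le))
            assert np.allclose(Le, np.einsum("ijkl->jikl", Le))


class TestTotalStress:
    def test_no_growth_no_pressure(self, rng):
        gu = rng.uniform(-0.05, 0.05, (2, 2))
        kin = compute_kinematics(gu, 1.02, 1.0)
        Se = neo_hookean_stress(kin.Ce, TABLE_MAT)
        st_ = total_stress(Se, kin, pf=0.0)
        assert np.allclose(st_.S, Se)

    def test_growth_pullback_quarter(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 2.0)
        Se = 5.0 * np.eye(3)
        st_ = total_stress(Se, kin, pf=0.0)
        assert np.allclose(st_.Seff, 1.25 * np.eye(3))

    def test_pure_pore_pressure(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.0)
        st_ = total_stress(np.zeros((3, 3)), kin, pf=7.0)
        assert np.allclose(st_.S, -7.0 * np.eye(3))
        assert np.allclose(st_.sigma, -7.0 * np.eye(3))

    def test_growth_free_reduction(self, rng):
        """theta = 1 reproduces the classical mixture stress S = Seff_e - J H pf."""
        for _ in range(10):
            gu = rng.uniform(-0.05, 0.05, (2, 2))
            hoop = 1.0 + rng.uniform(-0.05, 0.05)
            kin = compute_kinematics(gu, hoop, 1.0)
            Se = neo_hookean_stress(kin.Ce, TABLE_MAT)
            pf = rng.uniform(0, 1e4)
            st_ = total_stress(Se, kin, pf=pf)
            assert np.allclose(st_.S, Se - kin.J * kin.H * pf)

    def test_objectivity_under_rotation(self, rng):
        """A rigid rotation of F leaves Je and tr(M) unchanged."""
        from scipy.spatial.transform import Rotation

        gu = rng.uniform(-0.05, 0.05, (2, 2))
        kin = compute_kinematics(gu, 1.03, 1.05)
        Q = Rotation.random(random_state=7).as_matrix()
        kin_rot = kinematics_from_F(Q @ kin.F, 1.05)
        assert kin_rot.Je == pytest.approx(kin.Je, rel=1e-12)
        for k in (kin, kin_rot):
            k.Seff_e = neo_hookean_stress(k.Ce, TABLE_MAT)
        s1 = total_stress(kin.Seff_e, kin, pf=10.0)
        s2 = total_stress(kin_rot.Seff_e, kin_rot, pf=10.0)
        assert s2.trM == pytest.approx(s1.trM, rel=1e-10)


class TestTransport:
    def test_lff_table_values(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.0)
        Lff, Lfc, Lcf, Lcc = transport_coeffs(kin, 0.0128, TABLE_TP)
        assert np.allclose(Lff, 2e-14 * np.eye(3))
        assert np.allclose(Lfc, 2e-14 * 6e-4 * 0.0128 * np.eye(3))
        assert Lfc == pytest.approx(1.536e-19 * np.eye(3), rel=1e-3)

    def test_lcc_fickian_reduction(self):
        """The diffusive species mobility reduces to Fick's law
        jc = -dcc * grad(c)."""
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.0)
        tp = TABLE_TP
        c = 0.0128
        coeffs = transport_coeffs(kin, c, tp)
        grad_c = np.array([37.0, 0.0, 0.0])  # mol/m^4
        grad_mu_c = tp.RT / c * grad_c
        _, jcr = fluxes(np.zeros(3), grad_mu_c, coeffs)
        beta_corr = 1.0 + c * tp.kff * tp.bfc**2 * tp.RT / (tp.dcc)
        assert np.allclose(jcr, -tp.dcc * grad_c * beta_corr, rtol=1e-10)
        assert beta_corr == pytest.approx(1.0, abs=1e-4)  # convective self-term tiny

    def test_onsager_reciprocity(self, rng):
        gu = rng.uniform(-0.05, 0.05, (2, 2))
        kin = compute_kinematics(gu, 1.02, 1.0)
        Lff, Lfc, Lcf, Lcc = transport_coeffs(kin, 5e-3, TABLE_TP)
        assert np.allclose(Lfc, Lcf)

    def test_zero_gradients_zero_fluxes(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.0)
        coeffs = transport_coeffs(kin, 1e-3, TABLE_TP)
        jfr, jcr = fluxes(np.zeros(3), np.zeros(3), coeffs)
        assert np.allclose(jfr, 0.0) and np.allclose(jcr, 0.0)

    def test_pure_darcy_limit(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.0)
        coeffs = transport_coeffs(kin, 1e-3, TABLE_TP)
        g = np.array([1e7, 0.0, 0.0])
        jfr, _ = fluxes(g, np.zeros(3), coeffs)
        assert np.allclose(jfr, -2e-14 * g)

    def test_nonpositive_concentration_rejected(self):
        kin = compute_kinematics(np.zeros((2, 2)), 1.0, 1.0)
        with pytest.raises(StateError):
            transport_coeffs(kin, 0.0, TABLE_TP)


class TestPotentials:
    def test_no_osmosis_fluid_potential_is_pressure(self):
        mu_f, _ = potentials_forward(1234.5, 1e-3, TABLE_TP)
        assert mu_f == pytest.approx(1234.5)

    def test_round_trip(self, rng):
        tp = TransportParams(phi_c=0.3, p0o=500.0, mu0c=-2e4)
        for _ in range(20):
            pf = rng.uniform(-1e4, 1e4)
            c = rng.uniform(1e-5, 1e-1)
            mu_f, mu_c = potentials_forward(pf, c, tp)
            pf2, c2 = secondary_from_potentials(mu_f, mu_c, tp)
            assert pf2 == pytest.approx(pf, rel=1e-12, abs=1e-9)
            assert c2 == pytest.approx(c, rel=1e-12)

    def test_datum_concentration(self):
        tp = TABLE_TP
        c_datum = np.exp(-tp.mu0c / tp.RT) / tp.gamma_mat
        _, mu_c = potentials_forward(0.0, c_datum, tp)
        assert mu_c == pytest.approx(0.0, abs=1e-9)

    def test_partition_boundary_concentrations(self):
        """Bath 6.40e-3 / 6.40e-4 mol/m^3 with partition coefficient 0.5 give
        material-side 0.0128 and 1.28e-3 mol/m^3."""
        assert partition_concentration(6.40e-3, 0.5) == pytest.approx(0.0128)
        assert partition_concentration(6.40e-4, 0.5) == pytest.approx(1.28e-3)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(StateError):
            potentials_forward(0.0, -1e-3, TABLE_TP)

    def test_overflow_rejected(self):
        with pytest.raises(StateError):
            secondary_from_potentials(0.0, 1e10, TABLE_TP)
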