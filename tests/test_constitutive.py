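"""Constitutive-law oracles: conversions, energies, stresses, objectivity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from softinverse import constitutive as co


class TestParameterConversions:
    @pytest.mark.parametrize(
        "E, nu, mu",
        [(1e3, 0.5, 1e3 / 3.0), (0.0, 0.5, 0.0), (1e6, 0.5, 1e6 / 3.0)],
    )
    def test_shear_from_young(self, E, nu, mu):
        assert co.shear_from_young(E, nu) == pytest.approx(mu, rel=1e-12)

    @pytest.mark.parametrize("E, nu", [(-1.0, 0.5), (1e3, -0.1), (1e3, 0.6)])
    def test_invalid_parameters_raise(self, E, nu):
        with pytest.raises(co.InvalidParameterError):
            co.shear_from_young(E, nu)

    def test_young_shear_round_trip(self, rng):
        for _ in range(20):
            E = float(10 ** rng.uniform(2, 10))
            nu = float(rng.uniform(0.0, 0.5))
            mu = co.shear_from_young(E, nu)
            assert co.young_from_shear(mu, nu) == pytest.approx(E, rel=1e-14)

    def test_material_parameters_derived(self):
        m = co.MaterialParameters(1e6, 0.5, thickness=0.3)
        assert m.shear_modulus == pytest.approx(1e6 / 3.0)
        assert m.arterial_stiffness == pytest.approx(3e5)
        with pytest.raises(co.InvalidParameterError):
            co.MaterialParameters(-1.0, 0.5)
        with pytest.raises(co.InvalidParameterError):
            co.MaterialParameters(1e3, 0.5).arterial_stiffness  # no thickness


class TestNeoHookean:
    @pytest.mark.parametrize(
        "stretches, mu, expected",
        [
            ((1.0, 1.0, 1.0), 7.3, 0.0),
            ((2.0, 2**-0.5, 2**-0.5), 2.0, 2.0),
            ((1.5, 1 / 1.5, 1.0), 1.0, 0.3472222222222223),
        ],
    )
    def test_energy_examples(self, stretches, mu, expected):
        assert co.neo_hookean_energy(stretches, mu) == pytest.approx(expected)

    def test_energy_rejects_nonpositive_stretch(self):
        with pytest.raises(co.InvalidStateError):
            co.neo_hookean_energy((1.0, -0.5, 1.0), 1.0)

    def test_reference_state_stress_free_at_p_mu(self):
        st = co.DeformationState(np.eye(3), pressure=4.2)
        sigma = co.neo_hookean_cauchy_stress(st, mu=4.2)
        assert np.allclose(sigma, 0.0, atol=1e-12)

    def test_rigid_rotation_stress_free(self):
        R = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        st = co.DeformationState(R, pressure=1.7)
        sigma = co.neo_hookean_cauchy_stress(st, mu=1.7)
        assert np.allclose(sigma, 0.0, atol=1e-12)

    def test_incompressible_uniaxial_closed_form(self):
        # lateral stress vanishes for p = mu / lambda; sigma11 = mu (l^2 - 1/l)
        lam, mu = 2.0, 1.0
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        st = co.DeformationState(F, pressure=mu / lam)
        sigma = co.neo_hookean_cauchy_stress(st, mu)
        assert sigma[0, 0] == pytest.approx(mu * (lam**2 - 1 / lam), rel=1e-12)
        assert sigma[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_incompressibility_violation_raises(self):
        st = co.DeformationState(1.1 * np.eye(3))
        with pytest.raises(co.IncompressibilityError):
            co.neo_hookean_cauchy_stress(st, 1.0)

    def test_energy_derivative_matches_principal_stress(self, rng):
        """sigma_i = lambda_i dW/dlambda_i - p on random incompressible states."""
        for _ in range(50):
            l1, l2 = np.exp(rng.uniform(-0.5, 0.5, size=2))
            l3 = 1.0 / (l1 * l2)
            lam = np.array([l1, l2, l3])
            mu = float(10 ** rng.uniform(0, 5))
            p = float(rng.uniform(-1, 1) * mu)
            h = 1e-7
            for i in range(3):
                lp, lm = lam.copy(), lam.copy()
                lp[i] += h
                lm[i] -= h
                dW = (
                    co.neo_hookean_energy(lp, mu) - co.neo_hookean_energy(lm, mu)
                ) / (2 * h)
                sigma_i = lam[i] * dW - p
                expected = co.neo_hookean_principal_stresses(lam, mu, p)[i]
                assert sigma_i == pytest.approx(expected, rel=1e-6)

    def test_objectivity_under_rotation(self, rng):
        for _ in range(20):
            F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            F /= np.linalg.det(F) ** (1 / 3)  # make isochoric
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            st, strot = co.DeformationState(F, 0.8), co.DeformationState(R @ F, 0.8)
            lam1, _ = st.principal()
            lam2, _ = strot.principal()
            assert np.allclose(lam1, lam2, atol=1e-10)
            s1 = co.neo_hookean_cauchy_stress(st, 2.0)
            s2 = co.neo_hookean_cauchy_stress(strot, 2.0)
            assert np.linalg.norm(s2) == pytest.approx(np.linalg.norm(s1), abs=1e-10)
            assert np.allclose(R @ s1 @ R.T, s2, atol=1e-9)


class TestStVK:
    def test_zero_strain_zero_stress(self):
        assert np.allclose(co.stvk_pk2_stress(np.zeros((3, 3)), 2.0, 1.0), 0.0)

    def test_linearity(self, rng):
        E = rng.standard_normal((3, 3))
        E = 0.5 * (E + E.T)
        S1 = co.stvk_pk2_stress(E, 1.3, 0.7)
        S2 = co.stvk_pk2_stress(2 * E, 1.3, 0.7)
        assert np.allclose(S2, 2 * S1, rtol=1e-13)

    def test_diagonal_example(self):
        E = np.diag([0.1, 0.0, 0.0])
        S = co.stvk_pk2_stress(E, lame_lambda=0.0, mu=1.0)
        assert np.allclose(S, np.diag([0.2, 0.0, 0.0]))

    def test_asymmetric_input_raises(self):
        E = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(co.InvalidStateError):
            co.stvk_pk2_stress(E, 1.0, 1.0)
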