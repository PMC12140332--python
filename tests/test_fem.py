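"""Forward-solver checks against closed-form oracles and invariants."""

import numpy as np
import pytest

from softinverse import fem
from softinverse.constitutive import (
    MaterialParameters,
    nearly_incompressible_cauchy_stress,
)
from softinverse.mesh import InvalidConfigError, build_beam_mesh, build_sphere_mesh
from softinverse.shapes import BrickAbnormalitySpec, label_elements

SOFT = {0: MaterialParameters(1e3, 0.5), 1: MaterialParameters(1e3, 0.5)}


def uniaxial_load(mesh, stretch, n_steps=5):
    L = mesh.nodes[:, 0].max()
    return fem.LoadProgram(
        n_steps=n_steps,
        fixed=[
            (mesh.node_set(lambda n: n[:, 0] < 1e-9), (True, False, False)),
            (mesh.node_set(lambda n: n[:, 1] < 1e-9), (False, True, False)),
            (mesh.node_set(lambda n: n[:, 2] < 1e-9), (False, False, True)),
        ],
        prescribed=[
            (mesh.node_set(lambda n, L=L: n[:, 0] > L - 1e-9), 0, (stretch - 1) * L)
        ],
    )


class TestQuasistatic:
    def test_zero_load_zero_history(self):
        mesh = build_beam_mesh((50, 25, 3), (4, 2, 1))
        load = fem.LoadProgram(
            n_steps=3, fixed=[(mesh.node_set(lambda n: n[:, 0] < 1e-9), (True,) * 3)]
        )
        hist = fem.solve_quasistatic(mesh, SOFT, load)
        assert np.allclose(hist.displacements, 0.0)
        assert hist.displacements.shape[0] == 4

    def test_prescribed_face_hits_target_exactly(self):
        mesh = build_beam_mesh((50, 25, 3), (5, 2, 2))
        label_elements(mesh, BrickAbnormalitySpec(40.0, 10.0))
        mats = {0: MaterialParameters(1e3, 0.5), 1: MaterialParameters(1e6, 0.5)}
        hist = fem.solve_quasistatic(mesh, mats, fem.beam_load_program(mesh, 30.0, 5))
        right = mesh.node_set(lambda n: n[:, 0] > 50 - 1e-9)
        uz = hist.displacements[-1][right, 2]
        assert np.allclose(uz, 30.0, atol=1e-12)
        assert np.allclose(hist.displacements[-1][right, :2], 0.0, atol=1e-12)

    def test_single_hex_uniaxial_oracle(self):
        """Reaction-derived nominal stress vs incompressible mu (l - l^-2)."""
        mesh = build_beam_mesh((1, 1, 1), (1, 1, 1))
        mats = {0: MaterialParameters(1e3, 0.5), 1: MaterialParameters(1e3, 0.5)}
        lam = 1.2
        hist = fem.solve_quasistatic(mesh, mats, uniaxial_load(mesh, lam))
        f = fem.assemble_internal_forces(mesh, mats, hist.displacements[-1])
        right = mesh.node_set(lambda n: n[:, 0] > 1 - 1e-9)
        nominal = f[right, 0].sum()  # reference area 1 mm^2
        oracle = mats[0].shear_modulus * (lam - lam**-2)
        assert nominal == pytest.approx(oracle, rel=0.01)

    def test_patch_homogeneous_deformation_stress(self):
        """Single element under an affine map matches the penalty-form stress."""
        mesh = build_beam_mesh((1, 1, 1), (1, 1, 1))
        mat = MaterialParameters(1e3, 0.5)
        F = np.array([[1.1, 0.05, 0.0], [0.0, 0.95, 0.02], [0.01, 0.0, 1.02]])
        u = mesh.nodes @ (F - np.eye(3)).T
        f_int = fem.assemble_internal_forces(mesh, {0: mat, 1: mat}, u)
        # analytic nominal traction: P = J sigma F^{-T}, integrated over faces
        sigma = nearly_incompressible_cauchy_stress(
            F, mat.shear_modulus, mat.effective_bulk_modulus(0.499)
        )
        J = np.linalg.det(F)
        P = J * sigma @ np.linalg.inv(F).T
        sys_ = fem._System(
            mesh, {0: mat, 1: mat}, fem.LoadProgram(n_steps=1), "neo_hookean", 0.499
        )
        k = sys_.kernel
        f_local = np.matmul(
            np.broadcast_to(P, (1, 8, 3, 3)), k.gradNwT
        ).sum(axis=1).swapaxes(-1, -2)[0]
        f_oracle = np.zeros_like(f_int)
        f_oracle[mesh.elements[0]] = f_local  # local element -> global node ids
        scale = np.abs(f_oracle).max()
        assert np.allclose(f_int, f_oracle, atol=1e-8 * scale)

    def test_path_independence(self):
        mesh = build_beam_mesh((50, 25, 3), (5, 2, 2))
        mats = {0: MaterialParameters(1e3, 0.5), 1: MaterialParameters(1e3, 0.5)}
        u5 = fem.solve_quasistatic(
            mesh, mats, fem.beam_load_program(mesh, 15.0, 5)
        ).displacements[-1]
        u10 = fem.solve_quasistatic(
            mesh, mats, fem.beam_load_program(mesh, 15.0, 10)
        ).displacements[-1]
        assert np.abs(u10 - u5).max() <= 1e-6 * np.abs(u5).max()

    def test_mesh_convergence_sanity(self):
        mats = {0: MaterialParameters(1e3, 0.5), 1: MaterialParameters(1e3, 0.5)}
        tips = []
        for div in [(6, 2, 2), (12, 4, 4)]:
            mesh = build_beam_mesh((50, 25, 3), div)
            hist = fem.solve_quasistatic(mesh, mats, fem.beam_load_program(mesh, 15.0, 5))
            mid = mesh.node_set(
                lambda n: (np.abs(n[:, 0] - 25) < 1e-9)
                & (np.abs(n[:, 1]) < 1e-9)
                & (n[:, 2] > 3 - 1e-9)
            )
            tips.append(hist.displacements[-1][mid[0], 2])
        assert abs(tips[1] - tips[0]) / abs(tips[1]) < 0.02

    def test_stiff_inclusion_straightens_its_span(self):
        """Raising E_a flattens the bending sag inside the abnormal span."""
        mesh = build_beam_mesh((50, 25, 3), (10, 3, 2))
        sags = []
        for Ea in (1e3, 1e6):
            label_elements(mesh, BrickAbnormalitySpec(40.0, 10.0))
            mats = {0: MaterialParameters(1e3, 0.5), 1: MaterialParameters(Ea, 0.5)}
            hist = fem.solve_quasistatic(mesh, mats, fem.beam_load_program(mesh, 30.0, 5))
            z = {}
            for x in (30.0, 40.0, 50.0):
                ids = mesh.node_set(
                    lambda n, x=x: (np.abs(n[:, 0] - x) < 1e-9)
                    & (np.abs(n[:, 1]) < 1e-9)
                    & (n[:, 2] > 3 - 1e-9)
                )
                z[x] = hist.displacements[-1][ids[0], 2]
            sags.append(abs(z[40.0] - 0.5 * (z[30.0] + z[50.0])))
        assert sags[1] < sags[0]


class TestInflate:
    def test_zero_pressure(self):
        mesh = build_sphere_mesh(100.0, 3.0, refinement=1)
        mats = {
            0: MaterialParameters(1e3, 0.5, thickness=3.0),
            1: MaterialParameters(1e3, 0.5, thickness=3.0),
        }
        hist = fem.inflate(mesh, mats, fem.LoadProgram(n_steps=2, pressure=0.0))
        assert np.allclose(hist.displacements, 0.0)

    def test_spherical_membrane_pressure_stretch_oracle(self):
        """P = 2 mu (t/R)(l^-1 - l^-7) for the homogeneous balloon."""
        mesh = build_sphere_mesh(100.0, 3.0, refinement=3)
        mats = {
            0: MaterialParameters(1e3, 0.5, thickness=3.0),
            1: MaterialParameters(1e3, 0.5, thickness=3.0),
        }
        P = 8.0
        hist = fem.inflate(mesh, mats, fem.LoadProgram(n_steps=5, pressure=P))
        r = np.linalg.norm(mesh.nodes + hist.displacements[-1], axis=1)
        lam = r.mean() / 100.0
        assert lam <= 1.2
        mu = mats[0].shear_modulus
        P_oracle = 2 * mu * (3.0 / 100.0) * (lam**-1 - lam**-7)
        assert P_oracle == pytest.approx(P, rel=0.02)
        # spherical symmetry of the homogeneous response
        assert r.max() / r.min() <= 1.01

    def test_pressure_beyond_limit_point_raises(self):
        mesh = build_sphere_mesh(100.0, 3.0, refinement=1)
        mats = {
            0: MaterialParameters(1e3, 0.5, thickness=3.0),
            1: MaterialParameters(1e3, 0.5, thickness=3.0),
        }
        # limit pressure of the Neo-Hookean balloon is ~12.4 Pa here
        with pytest.raises(fem.NonConvergenceError) as exc:
            fem.inflate(mesh, mats, fem.LoadProgram(n_steps=5, pressure=40.0))
        assert 0.0 <= exc.value.last_fraction < 1.0

    def test_hex_mesh_rejected(self):
        mesh = build_beam_mesh((1, 1, 1), (1, 1, 1))
        with pytest.raises(InvalidConfigError):
            fem.inflate(mesh, SOFT, fem.LoadProgram(n_steps=1, pressure=1.0))


class TestDynamic:
    def test_zero_ramp_stays_at_rest(self):
        mesh = build_beam_mesh((50, 25, 3), (4, 1, 1))
        load = fem.beam_load_program(mesh, 0.0, n_steps=3)
        hist = fem.solve_dynamic(mesh, SOFT, load, total_time=10.0, substeps_per_frame=2)
        assert np.allclose(hist.displacements, 0.0)

    def test_lumped_mass_totals_density_times_volume(self):
        mesh = build_beam_mesh((50, 25, 3), (5, 2, 2))
        sys_ = fem._System(mesh, SOFT, fem.LoadProgram(n_steps=1), "neo_hookean", 0.499)
        m = sys_.lumped_mass()
        assert m.sum() == pytest.approx(3 * 1.0 * 50 * 25 * 3, rel=1e-12)

    def test_moduli_scaling_changes_transient(self, tiny_beam_case):
        """Scaling both moduli leaves statics unchanged but not the transient."""
        c = tiny_beam_case
        D1 = c.simulate({}, preset="desk")
        D2 = c.simulate({"E_b": 2e3, "E_a": 2e6}, preset="desk")
        assert np.abs(D1 - D2).max() > 1e-3


class TestKeypoints:
    def test_full_tracking_is_identity(self):
        hist = fem.DisplacementHistory(
            np.arange(2 * 4 * 3, dtype=float).reshape(2, 4, 3), np.array([0.0, 1.0])
        )
        D = fem.extract_keypoints(hist, fem.TrackingSet(np.arange(4)))
        assert np.array_equal(D, hist.displacements)

    def test_component_mask(self):
        hist = fem.DisplacementHistory(
            np.arange(2 * 4 * 3, dtype=float).reshape(2, 4, 3), np.array([0.0, 1.0])
        )
        D = fem.extract_keypoints(
            hist, fem.TrackingSet([1, 3], components=(False, False, True))
        )
        assert D.shape == (2, 2, 1)
        assert np.array_equal(D[:, :, 0], hist.displacements[:, [1, 3], 2])

    def test_out_of_range_id_raises(self):
        hist = fem.DisplacementHistory(np.zeros((2, 4, 3)), np.array([0.0, 1.0]))
        with pytest.raises(InvalidConfigError):
            fem.extract_keypoints(hist, fem.TrackingSet([9]))

    def test_empty_tracking_set_rejected(self):
        with pytest.raises(InvalidConfigError):
            fem.TrackingSet(np.array([], dtype=int))
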