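"""Quasi-static nonlinear finite-element forward solver (the virtual twin).

Solves hyperelastic equilibrium under prescribed-displacement and follower
pressure load programs, producing the per-load-step nodal displacement
history whose tracked keypoints constitute the simulated observation D̂.

Formulation
-----------
* 8-node hexahedra (solids): nearly-incompressible Neo-Hookean energy
  W = (μ/2)(J^(-2/3) I1 − 3) + (κ/2)(J̄ − 1)², with a mean-dilatation
  treatment (the volumetric term uses the element-average Jacobian J̄) to
  avoid volumetric locking as ν → 0.5.  A Saint Venant-Kirchhoff variant with
  the analogous element-averaged volumetric term is available for
  cross-model tests.
* 3-node membrane triangles (thin structures): incompressible plane-stress
  Neo-Hookean membrane, energy per reference area
  T·(μ/2)(tr C₂ + 1/det C₂ − 3); no bending stiffness.  Pressure is a
  follower load along the deformed face normal.

The load "time" axis is the load-step axis: all loads are ramped linearly
over ``n_steps`` increments and each increment is solved to equilibrium by
damped Newton (relative residual 1e-8, automatic step halving down to 1/64
of an increment).  For displacement-driven bodies, where static equilibrium
depends only on modulus ratios, an implicit Newmark transient solver makes
the absolute moduli observable.  Element residuals are analytic; hexahedra
use the exact consistent tangent, membranes a per-element finite-difference
tangent of the analytic residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from softinverse.constitutive import MaterialParameters
from softinverse.mesh import InvalidConfigError, Mesh

__all__ = [
    "LoadProgram",
    "TrackingSet",
    "DisplacementHistory",
    "NonConvergenceError",
    "solve_quasistatic",
    "solve_dynamic",
    "inflate",
    "extract_keypoints",
    "assemble_internal_forces",
    "beam_load_program",
]

_GP = 1.0 / np.sqrt(3.0)


class NonConvergenceError(RuntimeError):
    """Newton failed below the step-halving floor.

    Carries the last converged load fraction and partial history.
    """

    def __init__(self, msg, last_fraction=0.0, partial_history=None):
        super().__init__(msg)
        self.last_fraction = last_fraction
        self.partial_history = partial_history


class _DegenerateState(RuntimeError):
    """Inverted/collapsed element encountered at a trial iterate."""


def _det3(A):
    """Determinant of stacked 3x3 matrices (explicit cofactor expansion)."""
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _invT3(A, det):
    """Transpose-inverse of stacked 3x3 matrices via the adjugate."""
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    out[..., 0, 1] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    out[..., 0, 2] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    out[..., 1, 0] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    out[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    out[..., 1, 2] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    out[..., 2, 0] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    out[..., 2, 1] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    out[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    out /= det[..., None, None]
    return out


@dataclass
class LoadProgram:
    """Boundary conditions and loads, ramped linearly over ``n_steps``.

    fixed : list of (node_ids, component_mask) — components pinned to zero.
    prescribed : list of (node_ids, component, final_value) — ramped Dirichlet.
    pressure : follower pressure (Pa) on membrane faces, positive along the
        outward face normal (inflation).
    body_force : force per unit mass b, scaled by density.
    """

    n_steps: int = 10
    fixed: list = field(default_factory=list)
    prescribed: list = field(default_factory=list)
    pressure: float = 0.0
    body_force: tuple = (0.0, 0.0, 0.0)
    constrain_rigid_modes: bool = False

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise InvalidConfigError("n_steps must be >= 1")


@dataclass
class TrackingSet:
    """Keypoint node ids plus the component mask entering the loss."""

    node_ids: np.ndarray
    components: tuple = (True, True, True)

    def __post_init__(self) -> None:
        self.node_ids = np.atleast_1d(np.asarray(self.node_ids, dtype=np.int64))
        if self.node_ids.size == 0:
            raise InvalidConfigError("tracking set must be non-empty")
        if not any(self.components):
            raise InvalidConfigError("component mask must select >= 1 component")


@dataclass
class DisplacementHistory:
    """Nodal displacements u (mm) indexed (step, node, component); step 0 = 0."""

    displacements: np.ndarray
    load_fractions: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.load_fractions) - 1


def extract_keypoints(history: DisplacementHistory, tracking: TrackingSet) -> np.ndarray:
    """Slice the keypoint trajectory array D̂ (steps, keypoints, masked comps)."""
    n = history.displacements.shape[1]
    if np.any(tracking.node_ids < 0) or np.any(tracking.node_ids >= n):
        raise InvalidConfigError("tracking node id out of range")
    mask = np.asarray(tracking.components, dtype=bool)
    return history.displacements[:, tracking.node_ids][:, :, mask]


# ---------------------------------------------------------------- hex element

def _hex_reference_gradients():
    """Shape values and ξ-gradients at the 2×2×2 Gauss points.

    Returns (dNdxi (8gp, 8node, 3), N (8gp, 8node)); all weights are 1.
    """
    sgn = np.array(
        [
            [-1, -1, -1],
            [1, -1, -1],
            [1, 1, -1],
            [-1, 1, -1],
            [-1, -1, 1],
            [1, -1, 1],
            [1, 1, 1],
            [-1, 1, 1],
        ],
        dtype=float,
    )
    gp = _GP * sgn  # Gauss points share the corner pattern
    N = np.empty((8, 8))
    dN = np.empty((8, 8, 3))
    for g in range(8):
        xi = gp[g]
        for a in range(8):
            s = sgn[a]
            N[g, a] = 0.125 * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
            dN[g, a, 0] = 0.125 * s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2])
            dN[g, a, 1] = 0.125 * s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2])
            dN[g, a, 2] = 0.125 * s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1])
    return dN, N


class _HexKernel:
    """Vectorized residual evaluation for all hexahedra of a mesh."""

    def __init__(self, mesh, materials, model, nu_eff):
        self.conn = mesh.elements
        X = mesh.nodes[self.conn]  # (ne, 8, 3)
        dNdxi, Nval = _hex_reference_gradients()
        M = np.einsum("gak,eaI->egkI", dNdxi, X)  # ∂X_I/∂ξ_k
        detM = np.linalg.det(M)
        if np.any(detM <= 0.0):
            raise InvalidConfigError("non-positive element Jacobian in reference mesh")
        Minv = np.linalg.inv(M)
        # ∂N_a/∂X_I = ∂N_a/∂ξ_k (M⁻¹)_{I k}
        self.gradN = np.einsum("gak,egIk->egaI", dNdxi, Minv)
        self.dV = detM  # unit Gauss weights
        self.gradNwT = np.swapaxes(self.gradN, -1, -2) * detM[:, :, None, None]
        self.Ve = self.dV.sum(axis=1)
        self.NdV = np.einsum("ga,eg->ea", Nval, self.dV)
        self.model = model
        region = mesh.region
        mu = np.array([materials[r].shear_modulus for r in region])
        self.mu = mu
        self.rho = np.array([materials[r].density for r in region])
        if model == "neo_hookean":
            self.kappa = np.array(
                [materials[r].effective_bulk_modulus(nu_eff) for r in region]
            )
        elif model == "stvk":
            nus = np.array([min(materials[r].poisson_ratio, nu_eff) for r in region])
            E = np.array([materials[r].young_modulus for r in region])
            self.lam = E * nus / ((1.0 + nus) * (1.0 - 2.0 * nus))
        else:
            raise InvalidConfigError(f"unknown constitutive model {model!r}")
        self.n_dof_per_elem = 24
        self.char_length = float(np.mean(self.Ve) ** (1.0 / 3.0))
        self._tiled = {}

    def gather(self, nodes, u):
        return (nodes + u.reshape(-1, 3))[self.conn]

    def _arrays(self, rep: int):
        """Element arrays tiled ``rep`` times along the element axis.

        The finite-difference tangent evaluates all 24 single-dof
        perturbations as one stacked residual call; tiling keeps every
        matmul contiguous (no broadcasting)."""
        if rep == 1:
            return self
        if rep not in self._tiled:
            t = _HexKernel.__new__(_HexKernel)
            t.gradN = np.tile(self.gradN, (rep, 1, 1, 1))
            t.gradNwT = np.tile(self.gradNwT, (rep, 1, 1, 1))
            t.dV = np.tile(self.dV, (rep, 1))
            t.Ve = np.tile(self.Ve, rep)
            t.mu = np.tile(self.mu, rep)
            t.model = self.model
            if self.model == "neo_hookean":
                t.kappa = np.tile(self.kappa, rep)
            else:
                t.lam = np.tile(self.lam, rep)
            self._tiled[rep] = t
        return self._tiled[rep]

    def tangent_elements(self, x):
        """Consistent element tangents K_e (ne, 24, 24) at positions x.

        Exact linearization of :meth:`residual`: for the Neo-Hookean model
        A = ∂P_dev/∂F plus the mean-dilatation volumetric terms
        κ/Ve (∂v/∂x)⊗(∂v/∂x) + κ(J̄−1) ∂²v/∂x²; for StVK the analogous
        split with the element-averaged tr E.
        """
        ne = len(self.conn)
        gradN, dV = self.gradN, self.dV
        xt = np.swapaxes(x, -1, -2)[:, None, :, :]
        F = np.matmul(xt, gradN)
        J = _det3(F)
        if not np.all(J > 0.0):
            raise _DegenerateState("element inversion (det F <= 0)")
        I3 = np.eye(3)

        def outer(X, Y):  # X_iJ Y_kL -> (e,g,i,J,k,L)
            return X[..., :, :, None, None] * Y[..., None, None, :, :]

        def cross(X):  # X_iL X_kJ -> (e,g,i,J,k,L)
            XT = np.swapaxes(X, -1, -2)
            return X[..., :, None, None, :] * XT[..., None, :, :, None]

        if self.model == "neo_hookean":
            H = _invT3(F, J)  # F^{-T}
            I1 = (F * F).sum(axis=(-1, -2))
            Jm23 = (J ** (-2.0 / 3.0))[..., None, None]
            D = F - (I1 / 3.0)[..., None, None] * H
            # A_dev[iJkL] = ∂P_dev/∂F
            A = outer(-(2.0 / 3.0) * Jm23 * D, H)
            A += Jm23[..., None, None] * (
                np.einsum("ik,JL->iJkL", I3, I3)[None, None]
                - (2.0 / 3.0) * outer(H, F)
                + (I1 / 3.0)[..., None, None, None, None] * cross(H)
            )
            A *= self.mu[:, None, None, None, None, None]
            # volumetric: ∂(J H_iJ)/∂F_kL = J (H_iJ H_kL − H_iL H_kJ)
            B = outer(H, H) - cross(H)
            Jbar = (J * dV).sum(axis=-1) / self.Ve
            A += (
                (self.kappa * (Jbar - 1.0))[:, None, None, None, None, None]
                * J[..., None, None, None, None]
                * B
            )
            w = np.matmul(J[..., None, None] * H, self.gradNwT).sum(axis=1)
            w = w.swapaxes(-1, -2).reshape(ne, 24)  # ∂v/∂x, (e, 24)
            K = self._contract(A)
            K += (self.kappa / self.Ve)[:, None, None] * (
                w[:, :, None] * w[:, None, :]
            )
            return K
        # StVK
        C = np.matmul(np.swapaxes(F, -1, -2), F)
        E = 0.5 * (C - I3)
        S2 = 2.0 * self.mu[:, None, None, None] * E
        FFt = np.matmul(F, np.swapaxes(F, -1, -2))
        A = np.einsum("ik,egJL->egiJkL", I3, S2, optimize=True)
        A += self.mu[:, None, None, None, None, None] * (
            cross(F) + np.einsum("JL,egik->egiJkL", I3, FFt, optimize=True)
        )
        trE = E[..., 0, 0] + E[..., 1, 1] + E[..., 2, 2]
        trEbar = (trE * dV).sum(axis=-1) / self.Ve
        A += (self.lam * trEbar)[:, None, None, None, None, None] * np.einsum(
            "ik,JL->iJkL", I3, I3
        )[None, None]
        K = self._contract(A)
        q = np.matmul(F, self.gradNwT).sum(axis=1)
        q = q.swapaxes(-1, -2).reshape(ne, 24)
        K += (self.lam / self.Ve)[:, None, None] * (q[:, :, None] * q[:, None, :])
        return K

    def _contract(self, A):
        """K_e[ai, bk] = Σ_g ∂N_a/∂X_J A[iJkL] ∂N_b/∂X_L dV via two matmuls."""
        ne, ng = A.shape[:2]
        # contract J with gradN_a: (e,g,a,J) x (e,g,J,ikL) -> (e,g,a,ikL)
        A1 = np.ascontiguousarray(np.moveaxis(A, 3, 2)).reshape(ne, ng, 3, 27)
        T1 = np.matmul(self.gradN, A1)  # (e, g, 8, 27) with 27 = (i, k, L)
        # contract L with dV-weighted gradN_b: (e,g,72,L) x (e,g,L,b)
        T2 = np.matmul(T1.reshape(ne, ng, 8 * 9, 3), self.gradNwT)
        K = T2.sum(axis=1).reshape(ne, 8, 3, 3, 8)  # (e, a, i, k, b)
        K = np.ascontiguousarray(K.transpose(0, 1, 2, 4, 3)).reshape(ne, 24, 24)
        return K

    def residual(self, x):
        """Internal nodal forces at current positions x ((r·ne), 8, 3)."""
        ne = len(self.conn)
        k = self._arrays(len(x) // ne)
        # F_{iJ} = Σ_a x_{ai} ∂N_a/∂X_J  per (element, gauss point)
        xt = np.swapaxes(x, -1, -2)[:, None, :, :]  # (m, 1, i, a)
        F = np.matmul(xt, k.gradN)  # (m, g, i, J)
        J = _det3(F)
        if not np.all(J > 0.0):
            raise _DegenerateState("element inversion (det F <= 0)")
        if self.model == "neo_hookean":
            FinvT = _invT3(F, J)
            I1 = (F * F).sum(axis=(-1, -2))
            Jm23 = J ** (-2.0 / 3.0)
            Pdev = (k.mu[:, None] * Jm23)[..., None, None] * (
                F - (I1 / 3.0)[..., None, None] * FinvT
            )
            # f_{ai} = Σ_g Σ_J P_{iJ} ∂N_a/∂X_J dV
            f = np.matmul(Pdev, k.gradNwT).sum(axis=1).swapaxes(-1, -2)
            Jbar = (J * k.dV).sum(axis=-1) / k.Ve
            dv = np.matmul(J[..., None, None] * FinvT, k.gradNwT).sum(axis=1)
            f += (k.kappa * (Jbar - 1.0))[:, None, None] * dv.swapaxes(-1, -2)
            return f
        # Saint Venant-Kirchhoff with element-averaged volumetric term
        C = np.matmul(np.swapaxes(F, -1, -2), F)
        E = 0.5 * (C - np.eye(3))
        trE = E[..., 0, 0] + E[..., 1, 1] + E[..., 2, 2]
        trEbar = (trE * k.dV).sum(axis=-1) / k.Ve
        P = 2.0 * k.mu[:, None, None, None] * np.matmul(F, E)
        f = np.matmul(P, k.gradNwT).sum(axis=1).swapaxes(-1, -2)
        dtr = np.matmul(F, k.gradNwT).sum(axis=1).swapaxes(-1, -2)
        f += (k.lam * trEbar)[:, None, None] * dtr
        return f

    def external(self, body_force, rho_scale=1.0):
        b = np.asarray(body_force, dtype=float)
        if not b.any():
            return None
        return (self.rho[:, None] * self.NdV)[..., None] * b  # (ne, 8, 3)


# ----------------------------------------------------------- membrane element

class _MembraneKernel:
    """Vectorized residual for 3-node incompressible Neo-Hookean membranes."""

    def __init__(self, mesh, materials, model, nu_eff):
        if model != "neo_hookean":
            raise InvalidConfigError("membrane elements support the Neo-Hookean law only")
        self.conn = mesh.elements
        X = mesh.nodes[self.conn]  # (nt, 3, 3)
        d1 = X[:, 1] - X[:, 0]
        d2 = X[:, 2] - X[:, 0]
        n = np.cross(d1, d2)
        a2 = np.linalg.norm(n, axis=1)
        if np.any(a2 <= 0.0):
            raise InvalidConfigError("degenerate membrane triangle")
        self.area = 0.5 * a2
        e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
        nh = n / a2[:, None]
        e2 = np.cross(nh, e1)
        Dm = np.empty((len(X), 2, 2))
        Dm[:, 0, 0] = np.einsum("ei,ei->e", e1, d1)
        Dm[:, 0, 1] = np.einsum("ei,ei->e", e1, d2)
        Dm[:, 1, 0] = np.einsum("ei,ei->e", e2, d1)
        Dm[:, 1, 1] = np.einsum("ei,ei->e", e2, d2)
        self.Dminv = np.linalg.inv(Dm)
        region = mesh.region
        mu = np.array([materials[r].shear_modulus for r in region])
        T = np.array([materials[r].thickness for r in region], dtype=float)
        if np.any(~np.isfinite(T)):
            raise InvalidConfigError("membrane materials need a thickness")
        self.muT = mu * T
        self.n_dof_per_elem = 9
        self.char_length = float(np.sqrt(np.mean(self.area)))
        self._tiled = {}

    def gather(self, nodes, u):
        return (nodes + u.reshape(-1, 3))[self.conn]

    def _arrays(self, rep: int):
        if rep == 1:
            return self
        if rep not in self._tiled:
            t = _MembraneKernel.__new__(_MembraneKernel)
            t.Dminv = np.tile(self.Dminv, (rep, 1, 1))
            t.area = np.tile(self.area, rep)
            t.muT = np.tile(self.muT, rep)
            self._tiled[rep] = t
        return self._tiled[rep]

    def residual(self, x, pressure=0.0):
        """Internal minus pressure nodal forces at positions x ((r·nt), 3, 3)."""
        k = self._arrays(len(x) // len(self.conn))
        d1 = x[..., 1, :] - x[..., 0, :]
        d2 = x[..., 2, :] - x[..., 0, :]
        Fm = np.matmul(np.stack([d1, d2], axis=-1), k.Dminv)  # (m, 3, 2)
        C = np.matmul(np.swapaxes(Fm, -1, -2), Fm)
        detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
        if not np.all(detC > 0.0):
            raise _DegenerateState("membrane triangle collapsed (det C <= 0)")
        Cinv = np.empty_like(C)
        Cinv[..., 0, 0] = C[..., 1, 1]
        Cinv[..., 1, 1] = C[..., 0, 0]
        Cinv[..., 0, 1] = -C[..., 0, 1]
        Cinv[..., 1, 0] = -C[..., 1, 0]
        Cinv /= detC[..., None, None]
        # S = μ (I − (det C)⁻¹ C⁻¹); thickness stretch λ3² = 1/det C
        S = np.eye(2) - Cinv / detC[..., None, None]
        P = np.matmul(Fm, S)
        G = (k.muT * k.area)[:, None, None] * np.matmul(
            P, np.swapaxes(k.Dminv, -1, -2)
        )
        f = np.empty(x.shape)
        f[..., 1, :] = G[..., 0]
        f[..., 2, :] = G[..., 1]
        f[..., 0, :] = -G[..., 0] - G[..., 1]
        if pressure != 0.0:
            fp = (pressure / 6.0) * np.cross(d1, d2)
            f -= fp[..., None, :]
        return f


# ------------------------------------------------------------------ assembly

class _System:
    def __init__(self, mesh, materials, load, model, nu_eff):
        self.mesh = mesh
        self.load = load
        self.ndof = 3 * mesh.n_nodes
        if mesh.element_type == "hex8":
            self.kernel = _HexKernel(mesh, materials, model, nu_eff)
            if load.pressure:
                raise InvalidConfigError(
                    "pressure loading is implemented for membrane meshes"
                )
        else:
            self.kernel = _MembraneKernel(mesh, materials, model, nu_eff)
        nd = self.kernel.n_dof_per_elem
        edof = (3 * self.kernel.conn[:, :, None] + np.arange(3)).reshape(-1, nd)
        self.edof = edof
        self.rows = np.repeat(edof, nd, axis=1).ravel()
        self.cols = np.tile(edof, (1, nd)).ravel()
        self.fd_step = 1e-6 * self.kernel.char_length

        # Dirichlet bookkeeping
        fixed = np.zeros(self.ndof, dtype=bool)
        for ids, cmask in load.fixed:
            ids = np.atleast_1d(np.asarray(ids, dtype=np.int64))
            for c, on in enumerate(cmask):
                if on:
                    fixed[3 * ids + c] = True
        pdofs, pvals = [], []
        for ids, comp, value in load.prescribed:
            ids = np.atleast_1d(np.asarray(ids, dtype=np.int64))
            pdofs.append(3 * ids + comp)
            pvals.append(np.full(len(ids), float(value)))
        self.presc_dofs = (
            np.concatenate(pdofs) if pdofs else np.empty(0, dtype=np.int64)
        )
        self.presc_vals = np.concatenate(pvals) if pvals else np.empty(0)
        if fixed[self.presc_dofs].any():
            raise InvalidConfigError("a dof is both fixed and prescribed")
        self.fixed = fixed
        free = ~fixed
        free[self.presc_dofs] = False
        self.free = free
        if load.constrain_rigid_modes:
            self.R = self._rigid_modes()[free]
        else:
            self.R = None
        # dynamic (Newmark) context: {"coef": µN/mm per kg, "m": (ndof,) kg,
        # "u_pred": (ndof,)} — adds inertia coef·m∘(u − u_pred) to the
        # residual and coef·m to the tangent diagonal
        self.dyn = None
        self._lu = None  # last factorized tangent, reused across increments

    def _rigid_modes(self):
        X = self.mesh.nodes - self.mesh.nodes.mean(axis=0)
        n = self.mesh.n_nodes
        R = np.zeros((3 * n, 6))
        for c in range(3):
            R[c::3, c] = 1.0
        axes = np.eye(3)
        for k in range(3):
            v = np.cross(np.broadcast_to(axes[k], X.shape), X)
            R[:, 3 + k] = v.ravel()
        return R / np.linalg.norm(R, axis=0)

    def lumped_mass(self) -> np.ndarray:
        """Row-sum lumped nodal mass vector (kg), hex meshes."""
        k = self.kernel
        if not isinstance(k, _HexKernel):
            raise InvalidConfigError("lumped mass implemented for hex meshes")
        m_e = k.rho[:, None] * k.NdV  # (ne, 8)
        m = np.bincount(
            self.kernel.conn.ravel(), weights=m_e.ravel(), minlength=self.mesh.n_nodes
        )
        return np.repeat(m, 3)

    def elem_residual(self, x, gamma):
        if isinstance(self.kernel, _MembraneKernel):
            return self.kernel.residual(x, pressure=gamma * self.load.pressure)
        return self.kernel.residual(x)

    def global_residual(self, u, gamma):
        """Residual r = f_int − f_ext and a force-scale reference."""
        x = self.kernel.gather(self.mesh.nodes, u)
        fe = self.elem_residual(x, gamma)
        r = np.bincount(
            self.edof.ravel(), weights=fe.reshape(-1), minlength=self.ndof
        )
        scale = float(np.linalg.norm(r))
        # pre-cancellation magnitude sets the achievable roundoff floor of
        # the assembled residual (dominant for very stiff inclusions)
        r_abs = np.bincount(
            self.edof.ravel(), weights=np.abs(fe).reshape(-1), minlength=self.ndof
        )
        self._last_floor = 50.0 * np.finfo(float).eps * float(np.linalg.norm(r_abs))
        if isinstance(self.kernel, _HexKernel):
            fb = self.kernel.external(self.load.body_force)
            if fb is not None:
                fb = gamma * fb
                rb = np.bincount(
                    self.edof.ravel(), weights=fb.reshape(-1), minlength=self.ndof
                )
                r -= rb
                scale = max(scale, float(np.linalg.norm(rb)))
        if isinstance(self.kernel, _MembraneKernel) and self.load.pressure:
            # pressure already inside elem residual; scale from its magnitude
            scale = max(scale, abs(gamma * self.load.pressure) * float(np.sum(self.kernel.area)))
        if self.dyn is not None:
            inertia = self.dyn["coef"] * self.dyn["m"] * (u - self.dyn["u_pred"])
            r = r + inertia
            scale = max(scale, float(np.linalg.norm(inertia)))
        return r, scale

    def tangent(self, u, gamma):
        x0 = self.kernel.gather(self.mesh.nodes, u)
        ne = len(x0)
        nd = self.kernel.n_dof_per_elem
        if isinstance(self.kernel, _HexKernel):
            K = self.kernel.tangent_elements(x0)
        else:
            # membranes: finite-difference the analytic residual, all nd
            # single-dof perturbations evaluated in one stacked call
            r0 = self.elem_residual(x0, gamma)
            h = self.fd_step
            xp = np.broadcast_to(x0.reshape(1, ne, nd), (nd, ne, nd)).copy()
            xp[np.arange(nd), :, np.arange(nd)] += h
            rj = self.elem_residual(xp.reshape(nd * ne, -1, 3), gamma)
            K = np.moveaxis(
                (rj.reshape(nd, ne, nd) - r0.reshape(ne, nd)) / h, 0, 2
            )  # (ne, nd_residual, nd_perturbed)
        A = sp.coo_matrix(
            (K.ravel(), (self.rows, self.cols)), shape=(self.ndof, self.ndof)
        ).tocsr()
        if self.dyn is not None:
            A = A + sp.diags(self.dyn["coef"] * self.dyn["m"])
        return A

    def _factorize(self, u, gamma):
        K = self.tangent(u, gamma)
        free = self.free
        Kff = K[free][:, free]
        if self.R is not None:
            Rs = sp.csr_matrix(self.R)
            A = sp.bmat([[Kff, Rs], [Rs.T, None]], format="csc")
        else:
            A = Kff.tocsc()
        return spla.splu(A)

    def _residual_norm(self, u, gamma):
        r, scale = self.global_residual(u, gamma)
        rn = float(np.linalg.norm(r[self.free]))
        if self.R is not None:
            rn = float(np.sqrt(rn**2 + np.linalg.norm(self.R.T @ u[self.free]) ** 2))
        return r, rn, max(scale, 1e-30), self._last_floor

    def newton(self, u, gamma, rtol, max_iter):
        """Damped Newton iteration with backtracking line search.

        The tangent is refactorized at every iterate (it is cheap relative
        to the solve sizes here); a step is accepted only if it reduces the
        residual norm (factor <= 0.95) or reaches the tolerance, with up to
        8 halvings of the step length.  Convergence is declared on the
        relative residual, on the roundoff floor of the assembled residual
        (dominant for very stiff inclusions), or on a vanishing update.
        """
        u = u.copy()
        u[self.fixed] = 0.0
        u[self.presc_dofs] = gamma * self.presc_vals
        free = self.free
        nfree = int(free.sum())
        r, rn, scale, floor = self._residual_norm(u, gamma)  # may raise degenerate
        rn0 = rn
        for _ in range(max_iter):
            if rn <= max(rtol * scale, floor, 1e-30):
                return u, True
            if not np.isfinite(rn) or rn > 1e4 * max(rn0, scale):
                return u, False  # diverging; let the caller cut the step
            try:
                lu = self._factorize(u, gamma)
            except RuntimeError:
                return u, False  # singular tangent; cut the step
            rhs = -r[free]
            if self.R is not None:
                rhs = np.concatenate([rhs, -self.R.T @ u[free]])
            du = lu.solve(rhs)[:nfree]
            if not np.all(np.isfinite(du)):
                return u, False
            alpha, accepted = 1.0, False
            for _ls in range(8):
                u2 = u.copy()
                u2[free] += alpha * du
                try:
                    r2, rn2, scale2, floor2 = self._residual_norm(u2, gamma)
                except _DegenerateState:
                    alpha *= 0.5
                    continue
                if rn2 <= 0.95 * rn or rn2 <= max(rtol * scale2, floor2, 1e-30):
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                return u, False  # no descent direction; cut the step
            step = alpha * float(np.linalg.norm(du))
            u, r, rn, scale, floor = u2, r2, rn2, scale2, floor2
            # vanishing update signals equilibrium at the roundoff floor
            if step <= 1e-10 * max(
                float(np.linalg.norm(u[free])), self.kernel.char_length
            ):
                return u, True
        return u, False


def solve_quasistatic(
    mesh: Mesh,
    materials: dict,
    load: LoadProgram,
    model: str = "neo_hookean",
    nu_eff: float = 0.499,
    rtol: float = 1e-8,
    max_iter: int = 50,
) -> DisplacementHistory:
    """Ramp the load program and solve each increment to equilibrium.

    ``materials`` maps region label -> :class:`MaterialParameters`.  Raises
    :class:`NonConvergenceError` (carrying the partial history) if an
    increment cannot be equilibrated even after halving down to 1/64 of a
    load step.
    """
    sys_ = _System(mesh, materials, load, model, nu_eff)
    n_steps = load.n_steps
    u = np.zeros(sys_.ndof)
    fractions = [0.0]
    hist = [u.copy()]
    g = 0.0
    u_prev, g_prev = None, None
    dg = 1.0 / n_steps
    floor = dg / 64.0
    for step in range(1, n_steps + 1):
        target = step / n_steps
        while g < target - 1e-12:
            trial = min(g + dg, target)
            attempts = []
            if u_prev is not None and g_prev is not None and g > g_prev:
                upred = u + (u - u_prev) * ((trial - g) / (g - g_prev))
                attempts.append(upred)
            attempts.append(u)
            ok = False
            for guess in attempts:
                try:
                    unew, ok = sys_.newton(guess, trial, rtol, max_iter)
                except _DegenerateState:
                    ok = False
                if ok:
                    break
            if ok:
                u_prev, g_prev = u, g
                u, g = unew, trial
                dg = min(dg * 2.0, 1.0 / n_steps)
            else:
                dg *= 0.5
                if dg < floor:
                    raise NonConvergenceError(
                        f"Newton failed near load fraction {g:.4f}",
                        last_fraction=g,
                        partial_history=DisplacementHistory(
                            np.array([h.reshape(-1, 3) for h in hist]),
                            np.array(fractions),
                        ),
                    )
        hist.append(u.copy())
        fractions.append(target)
    return DisplacementHistory(
        np.array([h.reshape(-1, 3) for h in hist]), np.array(fractions)
    )


_MASS_TO_FORCE = 1e3  # 1 kg·mm/s² = 1e3 µN, with stresses in Pa and lengths in mm


def solve_dynamic(
    mesh: Mesh,
    materials: dict,
    load: LoadProgram,
    total_time: float,
    substeps_per_frame: int = 10,
    model: str = "neo_hookean",
    nu_eff: float = 0.499,
    rtol: float = 1e-8,
    max_iter: int = 50,
) -> DisplacementHistory:
    """Implicit Newmark transient solve of the dynamic balance ρü = ∇·σ.

    The load ramps linearly over ``total_time`` seconds; ``load.n_steps``
    output frames are recorded, each integrated with ``substeps_per_frame``
    Newmark substeps (γ = 0.6, β = (γ + 1/2)²/4: mildly dissipative, which
    damps spurious high-frequency ringing while keeping the physical
    transient).  No physical damping is applied (none is part of the
    model): inertial transients are the point — for displacement-driven
    bodies they are what makes the absolute moduli observable, since static
    equilibrium depends only on modulus ratios.  Densities are in kg/mm³.
    """
    if total_time <= 0.0:
        raise InvalidConfigError("total_time must be > 0")
    sys_ = _System(mesh, materials, load, model, nu_eff)
    m = sys_.lumped_mass()
    n_frames = load.n_steps
    dt = total_time / (n_frames * substeps_per_frame)
    beta, gam = 0.3025, 0.6
    coef = _MASS_TO_FORCE / (beta * dt * dt)

    u = np.zeros(sys_.ndof)
    v = np.zeros(sys_.ndof)
    a = np.zeros(sys_.ndof)
    hist = [u.copy()]
    fractions = [0.0]
    t = 0.0
    for frame in range(1, n_frames + 1):
        t_end = frame * total_time / n_frames
        dt_cur = dt
        while t < t_end - 1e-12 * total_time:
            dt_try = min(dt_cur, t_end - t)
            gamma = min((t + dt_try) / total_time, 1.0)
            coef = _MASS_TO_FORCE / (beta * dt_try * dt_try)
            u_pred = u + dt_try * v + (0.5 - beta) * dt_try * dt_try * a
            sys_.dyn = {"coef": coef, "m": m, "u_pred": u_pred}
            ok = False
            for guess in (u_pred, u):
                try:
                    u_new, ok = sys_.newton(guess, gamma, rtol, max_iter)
                except _DegenerateState:
                    ok = False
                if ok:
                    break
            if ok:
                a_new = (u_new - u_pred) / (beta * dt_try * dt_try)
                v = v + dt_try * ((1.0 - gam) * a + gam * a_new)
                u, a = u_new, a_new
                t += dt_try
                dt_cur = min(dt_cur * 1.5, dt)
            else:
                dt_cur *= 0.5
                if dt_cur < dt / 32.0:
                    raise NonConvergenceError(
                        f"Newmark step failed at t = {t:.4f}s",
                        last_fraction=fractions[-1],
                        partial_history=DisplacementHistory(
                            np.array([h.reshape(-1, 3) for h in hist]),
                            np.array(fractions),
                        ),
                    )
        hist.append(u.copy())
        fractions.append(frame / n_frames)
    sys_.dyn = None
    return DisplacementHistory(
        np.array([h.reshape(-1, 3) for h in hist]), np.array(fractions)
    )


def inflate(
    mesh: Mesh, materials: dict, pressure_program: LoadProgram, **kwargs
) -> DisplacementHistory:
    """Inflation of a closed membrane by follower pressure on the inner face.

    Thin wrapper over :func:`solve_quasistatic`; rigid-body modes of the
    free-floating closed shell are removed by nullspace (Lagrange) constraints
    unless Dirichlet conditions are present.
    """
    if mesh.element_type != "tri3":
        raise InvalidConfigError("inflate expects a membrane mesh")
    if not pressure_program.fixed and not pressure_program.prescribed:
        pressure_program.constrain_rigid_modes = True
    return solve_quasistatic(mesh, materials, pressure_program, **kwargs)


def assemble_internal_forces(
    mesh: Mesh,
    materials: dict,
    u: np.ndarray,
    model: str = "neo_hookean",
    nu_eff: float = 0.499,
) -> np.ndarray:
    """Global internal nodal force vector at displacement u (for reactions)."""
    sys_ = _System(mesh, materials, LoadProgram(n_steps=1), model, nu_eff)
    r, _ = sys_.global_residual(np.asarray(u, dtype=float).ravel(), 1.0)
    return r.reshape(-1, 3)


def beam_load_program(
    mesh: Mesh, tip_displacement: float = 30.0, n_steps: int = 10
) -> LoadProgram:
    """Left face clamped; right face translated rigidly by +z ``tip_displacement``."""
    xmax = mesh.nodes[:, 0].max()
    left = mesh.node_set(lambda n: n[:, 0] < 1e-9)
    right = mesh.node_set(lambda n: n[:, 0] > xmax - 1e-9)
    return LoadProgram(
        n_steps=n_steps,
        fixed=[(left, (True, True, True))],
        prescribed=[
            (right, 0, 0.0),
            (right, 1, 0.0),
            (right, 2, float(tip_displacement)),
        ],
    )
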