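"""Hyperelastic material laws and parameter conversions.

The forward solver models soft, (nearly) incompressible materials with an
incompressible Neo-Hookean law whose strain-energy density is

    W(λ1, λ2, λ3) = (μ/2) (λ1² + λ2² + λ3² − 3),

where μ is the shear modulus and λi the principal stretches.  Exact
incompressibility (J = λ1 λ2 λ3 = 1, Poisson ratio ν = 0.5) is enforced in the
finite-element solver through a nearly-incompressible decomposition: the
deviatoric Neo-Hookean term plus a volumetric penalty (κ/2)(J − 1)² with the
bulk modulus κ derived from an effective ν slightly below 0.5.  This module
exposes both forms: the exact-incompressible principal-stretch form (used as
an analytic oracle) and the penalty form (used by the solver), together with
the Saint Venant-Kirchhoff law used for cross-model generality tests.

Units: moduli and stresses in Pa, lengths in mm throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParameters",
    "DeformationState",
    "InvalidParameterError",
    "InvalidStateError",
    "IncompressibilityError",
    "shear_from_young",
    "young_from_shear",
    "bulk_modulus",
    "lame_parameters",
    "neo_hookean_energy",
    "neo_hookean_principal_stresses",
    "neo_hookean_cauchy_stress",
    "nearly_incompressible_cauchy_stress",
    "stvk_pk2_stress",
]


class InvalidParameterError(ValueError):
    """A material parameter violates its physical bounds."""


class InvalidStateError(ValueError):
    """A kinematic quantity violates its invariants (e.g. non-positive stretch)."""


class IncompressibilityError(InvalidStateError):
    """The deformation violates J = 1 beyond tolerance where it is required."""


def shear_from_young(young: float, poisson: float) -> float:
    """Shear modulus μ = E / (2 (1 + ν)).

    Parameters
    ----------
    young : float
        Young's modulus E in Pa, must be >= 0.
    poisson : float
        Poisson ratio ν, must lie in [0, 0.5].
    """
    if young < 0.0:
        raise InvalidParameterError(f"Young's modulus must be >= 0, got {young}")
    if not 0.0 <= poisson <= 0.5:
        raise InvalidParameterError(f"Poisson ratio must be in [0, 0.5], got {poisson}")
    return young / (2.0 * (1.0 + poisson))


def young_from_shear(shear: float, poisson: float) -> float:
    """Inverse of :func:`shear_from_young`: E = 2 μ (1 + ν)."""
    if shear < 0.0:
        raise InvalidParameterError(f"shear modulus must be >= 0, got {shear}")
    if not 0.0 <= poisson <= 0.5:
        raise InvalidParameterError(f"Poisson ratio must be in [0, 0.5], got {poisson}")
    return 2.0 * shear * (1.0 + poisson)


def bulk_modulus(young: float, poisson: float) -> float:
    """Bulk modulus κ = E / (3 (1 − 2ν)); diverges as ν → 0.5."""
    if not 0.0 <= poisson < 0.5:
        raise InvalidParameterError(
            f"bulk modulus requires 0 <= nu < 0.5, got {poisson}"
        )
    return young / (3.0 * (1.0 - 2.0 * poisson))


def lame_parameters(young: float, poisson: float) -> tuple[float, float]:
    """Classical Lamé pair (λ, μ) from (E, ν) for the StVK law."""
    mu = shear_from_young(young, poisson)
    if poisson >= 0.5:
        raise InvalidParameterError("first Lamé parameter diverges at nu = 0.5")
    lam = young * poisson / ((1.0 + poisson) * (1.0 - 2.0 * poisson))
    return lam, mu


@dataclass(frozen=True)
class MaterialParameters:
    """Material description of one region (base or abnormal).

    ``thickness`` is only meaningful for membrane/shell structures; when
    present, the lumped stiffness AS = E·T (Pa·mm) is available as
    ``arterial_stiffness`` — the quantity reported for valve-type benchmarks,
    where a membrane's response depends on E and T only through their product.
    """

    young_modulus: float
    poisson_ratio: float = 0.5
    density: float = 1.0
    thickness: float | None = None

    def __post_init__(self) -> None:
        if self.young_modulus <= 0.0:
            raise InvalidParameterError(
                f"Young's modulus must be > 0, got {self.young_modulus}"
            )
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise InvalidParameterError(
                f"Poisson ratio must be in [0, 0.5], got {self.poisson_ratio}"
            )
        if self.thickness is not None and self.thickness <= 0.0:
            raise InvalidParameterError(
                f"thickness must be > 0, got {self.thickness}"
            )

    @property
    def shear_modulus(self) -> float:
        return shear_from_young(self.young_modulus, self.poisson_ratio)

    @property
    def arterial_stiffness(self) -> float:
        """AS = E · T in Pa·mm (membranes only)."""
        if self.thickness is None:
            raise InvalidParameterError(
                "arterial stiffness requires a thickness (membrane material)"
            )
        return self.young_modulus * self.thickness

    def effective_bulk_modulus(self, nu_eff: float = 0.499) -> float:
        """Penalty bulk modulus for the nearly-incompressible decomposition."""
        return bulk_modulus(self.young_modulus, min(self.poisson_ratio, nu_eff))


@dataclass
class DeformationState:
    """Pointwise kinematic state for the exact-incompressible stress evaluation."""

    deformation_gradient: np.ndarray
    pressure: float = 0.0
    _tol: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        F = np.asarray(self.deformation_gradient, dtype=float)
        if F.shape != (3, 3):
            raise InvalidStateError(f"deformation gradient must be 3x3, got {F.shape}")
        self.deformation_gradient = F
        if self.jacobian <= 0.0:
            raise InvalidStateError("deformation gradient must have det F > 0")

    @property
    def jacobian(self) -> float:
        return float(np.linalg.det(self.deformation_gradient))

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """Principal stretches λi and (reference) principal directions Ni.

        Returned directions are the orthonormal eigenvectors of C = FᵀF; the
        stretches are the square roots of its eigenvalues, descending order.
        """
        F = self.deformation_gradient
        C = F.T @ F
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        lam = np.sqrt(np.clip(w[order], 0.0, None))
        if np.any(lam <= 0.0):
            raise InvalidStateError("non-positive principal stretch")
        return lam, V[:, order]


def neo_hookean_energy(stretches, mu: float) -> float:
    """Incompressible Neo-Hookean energy density (μ/2)(λ1²+λ2²+λ3²−3)."""
    lam = np.asarray(stretches, dtype=float)
    if lam.shape != (3,):
        raise InvalidStateError(f"expected three principal stretches, got {lam.shape}")
    if np.any(lam <= 0.0):
        raise InvalidStateError(f"principal stretches must be > 0, got {lam}")
    return 0.5 * mu * float(np.sum(lam**2) - 3.0)


def neo_hookean_principal_stresses(stretches, mu: float, pressure: float) -> np.ndarray:
    """Principal Cauchy stresses σi = μ λi² − p of the incompressible law."""
    lam = np.asarray(stretches, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidStateError("principal stretches must be > 0")
    return mu * lam**2 - pressure


def neo_hookean_cauchy_stress(
    state: DeformationState, mu: float, j_tol: float = 1e-6
) -> np.ndarray:
    """Cauchy stress σ = F S Fᵀ − p I of the incompressible Neo-Hookean law.

    The second Piola-Kirchhoff tensor consistent with the energy
    (μ/2)(λ1²+λ2²+λ3²−3) is S = μ I, so σ = μ F Fᵀ − p I with principal
    values σi = μ λi² − p; the pressure p is the incompressibility
    multiplier carried in ``state``.  Requires |J − 1| <= ``j_tol``.  The
    reference state (F = I) is stress-free for p = μ.
    """
    J = state.jacobian
    if abs(J - 1.0) > j_tol:
        raise IncompressibilityError(
            f"|J - 1| = {abs(J - 1.0):.3e} exceeds tolerance {j_tol:.3e}"
        )
    F = state.deformation_gradient
    sigma = mu * F @ F.T - state.pressure * np.eye(3)
    return 0.5 * (sigma + sigma.T)


def nearly_incompressible_cauchy_stress(F, mu: float, kappa: float) -> np.ndarray:
    """Cauchy stress of the penalty-form law used by the FE solver.

    W = (μ/2)(J^{-2/3} I1 − 3) + (κ/2)(J − 1)², evaluated at deformation
    gradient F.  Serves as the patch-test oracle for the hexahedral element.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidStateError("det F must be > 0")
    B = F @ F.T
    I1 = float(np.trace(B))
    dev = B - (I1 / 3.0) * np.eye(3)
    return mu * J ** (-5.0 / 3.0) * dev + kappa * (J - 1.0) * np.eye(3)


def stvk_pk2_stress(green_strain, lame_lambda: float, mu: float) -> np.ndarray:
    """Saint Venant-Kirchhoff second Piola-Kirchhoff stress S = λ tr(E) I + 2 μ E."""
    E = np.asarray(green_strain, dtype=float)
    if E.shape != (3, 3):
        raise InvalidStateError(f"Green strain must be 3x3, got {E.shape}")
    if not np.allclose(E, E.T, atol=1e-10 * max(1.0, float(np.abs(E).max()))):
        raise InvalidStateError("Green strain must be symmetric")
    return lame_lambda * np.trace(E) * np.eye(3) + 2.0 * mu * E
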