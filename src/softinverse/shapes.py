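"""Abnormality (stiff-inclusion) shape parameterizations and element labelling.

Two families are supported:

* brick inclusions for the beam — an axis-aligned slab of center C and
  half-width W along the beam length (optionally a second center/half-width
  pair along z for the two-axis variant);
* revolved-curve generators for the balloon and valve — the planar polar
  curve R(θ) = R0 (1 + C1 cos 4θ + C2 cos 8θ) revolved about the z-axis of a
  frame translated by the offset P = (Px, Py, Pz), yielding complex
  axis-symmetric solids.  A point belongs to the solid iff its spherical
  radius about P is at most R(θ), with θ the polar angle from the local +z
  axis.  The intersection of the solid with the body is the abnormal region.

Membership is decided at element centroids (boundary inclusive), which makes
labelled element counts exact and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from softinverse.mesh import InvalidConfigError, Mesh

__all__ = [
    "BrickAbnormalitySpec",
    "RevolvedShapeSpec",
    "revolved_radius",
    "point_in_revolved_region",
    "point_in_brick_region",
    "label_elements",
]


@dataclass(frozen=True)
class BrickAbnormalitySpec:
    """Slab inclusion: |x − center| <= half_width (and optionally in z)."""

    center: float
    half_width: float
    center_z: float | None = None
    half_width_z: float | None = None

    def __post_init__(self) -> None:
        if self.half_width < 0.0:
            raise InvalidConfigError(f"half-width must be >= 0, got {self.half_width}")
        if (self.center_z is None) != (self.half_width_z is None):
            raise InvalidConfigError("center_z and half_width_z go together")
        if self.half_width_z is not None and self.half_width_z < 0.0:
            raise InvalidConfigError("z half-width must be >= 0")


@dataclass(frozen=True)
class RevolvedShapeSpec:
    """Revolved generator R(θ) = R0 (1 + C1 cos 4θ + C2 cos 8θ), offset by P."""

    base_radius: float
    c1: float = 0.0
    c2: float = 0.0
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.base_radius < 0.0:
            raise InvalidConfigError(f"R0 must be >= 0, got {self.base_radius}")
        if not (-0.5 <= self.c1 <= 0.5 and -0.5 <= self.c2 <= 0.5):
            raise InvalidConfigError(
                f"C1, C2 must lie in [-0.5, 0.5], got {self.c1}, {self.c2}"
            )
        object.__setattr__(
            self, "center_offset", tuple(float(v) for v in self.center_offset)
        )


def revolved_radius(theta, spec: RevolvedShapeSpec):
    """R(θ) of the generator curve; vectorized over θ (radians)."""
    theta = np.asarray(theta, dtype=float)
    r = spec.base_radius * (
        1.0 + spec.c1 * np.cos(4.0 * theta) + spec.c2 * np.cos(8.0 * theta)
    )
    return r if r.ndim else float(r)


def point_in_revolved_region(points, spec: RevolvedShapeSpec):
    """Membership test, boundary inclusive; vectorized over points (…, 3)."""
    p = np.asarray(points, dtype=float) - np.asarray(spec.center_offset)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    rho = np.linalg.norm(p, axis=-1)
    # polar angle from local +z axis; at the center rho = 0 take theta = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(rho > 0.0, p[..., 2] / np.where(rho > 0.0, rho, 1.0), 1.0)
    theta = np.arccos(np.clip(ct, -1.0, 1.0))
    inside = rho <= revolved_radius(theta, spec)
    return bool(inside[0]) if scalar else inside


def point_in_brick_region(points, spec: BrickAbnormalitySpec):
    """Slab membership along x (and optionally z), boundary inclusive."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    inside = np.abs(p[..., 0] - spec.center) <= spec.half_width
    if spec.center_z is not None:
        inside &= np.abs(p[..., 2] - spec.center_z) <= spec.half_width_z
    return bool(inside[0]) if np.asarray(points).ndim == 1 else inside


def label_elements(mesh: Mesh, spec) -> np.ndarray:
    """Label elements abnormal (1) whose centroid lies inside ``spec``.

    Writes the labels onto ``mesh.region`` and returns them.  ``spec`` may be
    ``None`` (homogeneous body: all base).  An empty abnormal set is legal.
    """
    cent = mesh.element_centroids()
    if spec is None:
        inside = np.zeros(len(cent), dtype=bool)
    elif isinstance(spec, BrickAbnormalitySpec):
        inside = point_in_brick_region(cent, spec)
    elif isinstance(spec, RevolvedShapeSpec):
        inside = point_in_revolved_region(cent, spec)
    else:
        raise InvalidConfigError(f"unknown abnormality spec {type(spec).__name__}")
    mesh.region = inside.astype(np.int64)
    return mesh.region
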