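"""Meshes for the benchmark geometries.

Two element technologies are used: 8-node hexahedra for solid bodies (the
beam) and 3-node membrane triangles for thin closed or dome-like structures
(balloon, valve).  All lengths are mm; node and element ids are 0-based.
Every element carries an integer region label: 0 = base material,
1 = abnormal material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "InvalidConfigError",
    "build_beam_mesh",
    "build_sphere_mesh",
    "build_dome_mesh",
]


class InvalidConfigError(ValueError):
    """A geometry/mesh configuration violates its preconditions."""


@dataclass
class Mesh:
    """Discretized geometry.

    ``element_type`` is ``"hex8"`` (solid) or ``"tri3"`` (membrane).  For
    hex8 meshes, connectivity follows the usual vertex ordering: bottom face
    counter-clockwise (as seen from +z) then top face.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_type: str
    region: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.element_type not in ("hex8", "tri3"):
            raise InvalidConfigError(f"unknown element type {self.element_type!r}")
        npe = 8 if self.element_type == "hex8" else 3
        if self.elements.ndim != 2 or self.elements.shape[1] != npe:
            raise InvalidConfigError(
                f"{self.element_type} connectivity must be (ne, {npe})"
            )
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise InvalidConfigError("connectivity index out of range")
        if self.region is None:
            self.region = np.zeros(len(self.elements), dtype=np.int64)
        else:
            self.region = np.asarray(self.region, dtype=np.int64)
        if len(self.region) != len(self.elements):
            raise InvalidConfigError("every element needs a region label")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_measures(self) -> np.ndarray:
        """Element volumes (hex8, mm³) or areas (tri3, mm²)."""
        if self.element_type == "tri3":
            x = self.nodes[self.elements]
            cr = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
            return 0.5 * np.linalg.norm(cr, axis=1)
        # hex volume by 2x2x2 Gauss quadrature of det(J)
        from softinverse.fem import _hex_reference_gradients

        dNdxi, _ = _hex_reference_gradients()
        x = self.nodes[self.elements]  # (ne, 8, 3)
        J = np.einsum("gak,eai->egki", dNdxi, x)
        return np.abs(np.linalg.det(J)).sum(axis=1)

    def node_set(self, predicate) -> np.ndarray:
        """Node ids whose coordinates satisfy ``predicate(nodes) -> bool mask``."""
        mask = predicate(self.nodes)
        return np.nonzero(mask)[0]


def build_beam_mesh(dimensions, divisions) -> Mesh:
    """Axis-aligned structured hexahedral beam on [0,L]x[0,W]x[0,H].

    ``divisions = (nx, ny, nz)`` gives nx·ny·nz elements and
    (nx+1)(ny+1)(nz+1) nodes.
    """
    L, W, H = (float(v) for v in dimensions)
    nx, ny, nz = (int(v) for v in divisions)
    if min(L, W, H) <= 0.0:
        raise InvalidConfigError(f"dimensions must be positive, got {dimensions}")
    if min(nx, ny, nz) < 1:
        raise InvalidConfigError(f"division counts must be >= 1, got {divisions}")
    xs = np.linspace(0.0, L, nx + 1)
    ys = np.linspace(0.0, W, ny + 1)
    zs = np.linspace(0.0, H, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                elems.append(
                    [
                        nid(i, j, k),
                        nid(i + 1, j, k),
                        nid(i + 1, j + 1, k),
                        nid(i, j + 1, k),
                        nid(i, j, k + 1),
                        nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1),
                        nid(i, j + 1, k + 1),
                    ]
                )
    return Mesh(nodes, np.array(elems), "hex8")


def build_sphere_mesh(radius: float, thickness: float, refinement: int = 3) -> Mesh:
    """Closed spherical membrane at the mid-surface radius.

    The shell of outer extent radius ± thickness/2 is represented by membrane
    triangles on the mid-surface (an icosphere with ``refinement`` subdivision
    levels); ``thickness`` parameterizes the membrane stiffness and is stored
    with the material, not the mesh.  Faces are oriented outward.
    """
    if not radius > thickness > 0.0:
        raise InvalidConfigError(
            f"need radius > thickness > 0, got radius={radius}, thickness={thickness}"
        )
    if refinement < 0:
        raise InvalidConfigError("refinement must be >= 0")
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=refinement, radius=radius)
    return Mesh(np.asarray(ico.vertices), np.asarray(ico.faces), "tri3")


def build_dome_mesh(radius: float, n_rings: int = 8) -> Mesh:
    """Hemispherical membrane dome (z >= 0) on a fixed equator circle.

    A simplified parametric tri-leaflet valve surface: the pressurized dome of
    radius ``radius`` (= r_co, the radius of the whole valve) stands in for
    three identical leaflets whose lower edges are fixed on the equator ring.
    Structured latitude/longitude triangulation with a pole fan; faces are
    oriented outward (away from the origin) so a positive trans-valvular
    pressure inflates the dome.
    """
    if radius <= 0.0:
        raise InvalidConfigError("radius must be > 0")
    if n_rings < 2:
        raise InvalidConfigError("need at least 2 latitude rings")
    n_phi = 4 * n_rings  # azimuthal resolution, divisible by 4
    nodes = []
    # rings from equator (theta = pi/2) towards the pole, excluding the pole
    for j in range(n_rings):
        theta = 0.5 * np.pi * (1.0 - j / n_rings)
        for m in range(n_phi):
            phi = 2.0 * np.pi * m / n_phi
            nodes.append(
                [
                    radius * np.sin(theta) * np.cos(phi),
                    radius * np.sin(theta) * np.sin(phi),
                    radius * np.cos(theta),
                ]
            )
    pole = len(nodes)
    nodes.append([0.0, 0.0, radius])
    elems = []
    for j in range(n_rings - 1):
        for m in range(n_phi):
            a = j * n_phi + m
            b = j * n_phi + (m + 1) % n_phi
            c = (j + 1) * n_phi + m
            d = (j + 1) * n_phi + (m + 1) % n_phi
            elems.append([a, b, d])
            elems.append([a, d, c])
    j = n_rings - 1
    for m in range(n_phi):
        a = j * n_phi + m
        b = j * n_phi + (m + 1) % n_phi
        elems.append([a, b, pole])
    return Mesh(np.array(nodes), np.array(elems), "tri3")
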