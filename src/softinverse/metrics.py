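"""Shape-recovery scoring: mask projections and structural similarity.

Recovered abnormality shapes are compared to the generating truth as binary
rasters: for the balloon, an equirectangular spherical-map projection of the
northern hemisphere; for the valve (and other point clouds), a PCA
projection of the abnormal-element centroids onto their two leading
principal axes.  Masks are scored with the structural similarity index
(SSIM), which is 1 for identical shapes.

Absolute SSIM values depend on the raster resolution and SSIM window; both
are recorded in the mask descriptor, and the canonical constants
(K1 = 0.01, K2 = 0.03, Gaussian window σ = 1.5, dynamic range 1) are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from softinverse.mesh import Mesh

__all__ = ["BinaryMask", "spherical_projection", "pca_projection", "ssim"]


@dataclass
class BinaryMask:
    """2-D binary raster with its provenance descriptor."""

    pixels: np.ndarray
    projection: str = "none"
    resolution: tuple = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not np.isin(self.pixels, (0, 1)).all():
            raise ValueError("mask values must be binary")
        self.pixels = self.pixels.astype(np.uint8)
        self.resolution = tuple(self.pixels.shape)


def spherical_projection(
    mesh: Mesh, hemisphere: str = "north", resolution: int = 128
) -> BinaryMask:
    """Equirectangular raster of the abnormal region on a spherical shell.

    Rows sweep the polar angle θ ∈ [0, π/2] (pole to equator, northern
    hemisphere), columns the azimuth φ ∈ [−π, π).  Each pixel takes the
    region label of the nearest surface-element centroid by direction.
    """
    if hemisphere != "north":
        raise ValueError("only the northern hemisphere projection is defined")
    cent = mesh.element_centroids()
    radii = np.linalg.norm(cent - cent.mean(axis=0), axis=1)
    if radii.std() > 0.2 * radii.mean():
        raise ValueError("mesh does not look like a spherical shell")
    center = mesh.nodes.mean(axis=0)
    dirs = cent - center
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    tree = cKDTree(dirs)

    theta = (np.arange(resolution) + 0.5) * (0.5 * np.pi / resolution)
    phi = -np.pi + (np.arange(resolution) + 0.5) * (2.0 * np.pi / resolution)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    q = np.stack(
        [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
    ).reshape(-1, 3)
    _, idx = tree.query(q)
    labels = mesh.region[idx].reshape(resolution, resolution)
    return BinaryMask(labels, projection="spherical-north", resolution=(resolution,) * 2)


def pca_projection(points: np.ndarray, resolution: int = 128, *, axes=None, extent=None) -> BinaryMask:
    """Rasterize 3-D points projected onto their two leading principal axes.

    When comparing a truth/estimate pair, fit the axes on the union
    (:func:`pca_projection_pair`) so both masks share one plane and raster
    extent; axis signs are fixed by making the first point's loadings
    non-negative, removing the reflection ambiguity of PCA.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need >= 3 points of dimension 3")
    if axes is None:
        axes = _pca_axes(pts)
    uv = (pts - axes["center"]) @ axes["basis"].T
    if extent is None:
        lo, hi = uv.min(axis=0), uv.max(axis=0)
        pad = 0.05 * np.maximum(hi - lo, 1e-12)
        extent = (lo - pad, hi + pad)
    lo, hi = extent
    ij = np.floor((uv - lo) / (hi - lo) * resolution).astype(int)
    ij = np.clip(ij, 0, resolution - 1)
    mask = np.zeros((resolution, resolution), dtype=np.uint8)
    mask[ij[:, 1], ij[:, 0]] = 1
    return BinaryMask(mask, projection="pca", resolution=(resolution,) * 2)


def _pca_axes(points: np.ndarray) -> dict:
    from sklearn.decomposition import PCA

    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    p = PCA(n_components=2).fit(pts - center)
    if p.explained_variance_[1] <= 1e-12 * max(p.explained_variance_[0], 1e-300):
        raise ValueError("degenerate (collinear) point set")
    basis = p.components_.copy()
    rel = pts[0] - center
    for k in range(2):
        if basis[k] @ rel < 0:
            basis[k] = -basis[k]
    return {"center": center, "basis": basis}


def pca_projection_pair(
    points_a: np.ndarray, points_b: np.ndarray, resolution: int = 128
) -> tuple[BinaryMask, BinaryMask]:
    """Project two point sets onto the principal plane of their union."""
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    axes = _pca_axes(np.vstack([pa, pb]))
    both = np.vstack([pa, pb])
    uv = (both - axes["center"]) @ axes["basis"].T
    lo, hi = uv.min(axis=0), uv.max(axis=0)
    pad = 0.05 * np.maximum(hi - lo, 1e-12)
    extent = (lo - pad, hi + pad)
    return (
        pca_projection(pa, resolution, axes=axes, extent=extent),
        pca_projection(pb, resolution, axes=axes, extent=extent),
    )


def ssim(mask_a: BinaryMask | np.ndarray, mask_b: BinaryMask | np.ndarray) -> float:
    """Structural similarity between two equal-shape binary masks.

    Standard formulation: Gaussian-weighted local means/variances/covariance
    (σ = 1.5), stabilizers K1 = 0.01 and K2 = 0.03 at dynamic range 1,
    averaged over all windows.  Symmetric; 1.0 for identical inputs.
    """
    from skimage.metrics import structural_similarity

    a = mask_a.pixels if isinstance(mask_a, BinaryMask) else np.asarray(mask_a)
    b = mask_b.pixels if isinstance(mask_b, BinaryMask) else np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a.astype(float),
            b.astype(float),
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )
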