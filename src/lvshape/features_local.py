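"""Pointwise neighborhood (local) features of the mesh vertex cloud.

For every vertex, all points within a fixed search radius form a
neighborhood (the vertex itself included). Eight features derive from the
eigenvalues l1 >= l2 >= l3 >= 0 of the neighborhood's 3D structure tensor
(the covariance of neighborhood points about their centroid, divisor k):

    linearity          L  = (l1 - l2) / l1
    planarity          P  = (l2 - l3) / l1
    sphericity         S  = l3 / l1
    omnivariance       O  = (l1 l2 l3)^(1/3)
    anisotropy         A  = (l1 - l3) / l1
    eigen-entropy      EE = -sum e_i ln e_i,  e_i = l_i / sum(l)
    sum of eigenvalues SE = l1 + l2 + l3
    change of curvature CC = l3 / (l1 + l2 + l3)

Four more are direct geometric statistics: farthest neighbor distance (FD),
point density (PD = k / sphere volume of radius r), and the height range /
standard deviation (HMax, HSD) along the world z axis.  Each pointwise
value is averaged over all vertices into a single scalar per mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "NeighborhoodSpec",
    "LocalFeatures",
    "radius_neighbors",
    "structure_tensor_eigs",
    "eigenfeatures",
    "geometric_local",
    "compute_local",
    "default_radius",
    "LOCAL_FEATURE_NAMES",
]

LOCAL_FEATURE_NAMES = (
    "A", "CC", "EE", "HSD", "FD", "L", "HMax", "O", "P", "PD", "S", "SE",
)


@dataclass
class NeighborhoodSpec:
    """Fixed-radius neighborhood definition.

    radius : search radius in mm. If None, ``compute_local`` uses
        4 x the median mesh edge length of the mesh at hand.
    min_neighbors : vertices with fewer neighbors (self included) are
        skipped from the averages and counted in the QC report.
    """

    radius: float | None = None
    min_neighbors: int = 3

    def __post_init__(self) -> None:
        if self.radius is not None and self.radius <= 0:
            raise ValueError("neighborhood radius must be > 0")


@dataclass
class LocalFeatures:
    values: dict[str, float]
    radius: float                 # mm, radius actually used
    median_edge_length: float     # mm
    n_skipped: int                # vertices below min_neighbors

    def as_dict(self) -> dict[str, float]:
        return {k: self.values[k] for k in LOCAL_FEATURE_NAMES}


def default_radius(mesh: trimesh.Trimesh, factor: float = 4.0) -> float:
    """Adaptive radius: ``factor`` times the median mesh edge length."""
    e = mesh.edges_unique
    lengths = np.linalg.norm(
        mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1
    )
    return float(factor * np.median(lengths))


def radius_neighbors(points: np.ndarray, spec: NeighborhoodSpec) -> list[np.ndarray]:
    """Indices of all points within ``spec.radius`` of each point (the point
    itself included); contractually identical to an exhaustive scan."""
    pts = np.asarray(points, dtype=float)
    if spec.radius is None:
        raise ValueError("radius_neighbors needs an explicit radius")
    tree = cKDTree(pts)
    return [np.asarray(ix, dtype=np.int64)
            for ix in tree.query_ball_point(pts, spec.radius)]


def structure_tensor_eigs(neigh_points: np.ndarray) -> np.ndarray:
    """Eigenvalues (descending, clamped >= 0) of the 3x3 covariance of a
    neighborhood about its centroid (population divisor k)."""
    pts = np.atleast_2d(np.asarray(neigh_points, dtype=float))
    d = pts - pts.mean(axis=0)
    cov = (d.T @ d) / len(pts)
    lam = np.linalg.eigvalsh(cov)[::-1]
    return _clamp_eigs(lam)


def _clamp_eigs(lam: np.ndarray) -> np.ndarray:
    """Round-off guard: negatives and eigenvalues below 1e-12 * l1 are
    exact zeros of a rank-deficient tensor (cube roots in omnivariance
    would otherwise amplify noise-level values)."""
    lam = np.clip(lam, 0.0, None)
    lam[lam < 1e-12 * lam.max(axis=-1, keepdims=True)] = 0.0
    return lam


def eigenfeatures(lam: np.ndarray) -> dict[str, float]:
    """Eight eigenvalue features; all-zero tensors (l1 = 0) map to zeros."""
    l1, l2, l3 = float(lam[0]), float(lam[1]), float(lam[2])
    if l1 <= 0.0:
        return {"L": 0.0, "P": 0.0, "S": 0.0, "O": 0.0, "A": 0.0,
                "EE": 0.0, "SE": 0.0, "CC": 0.0}
    s = l1 + l2 + l3
    e = np.array([l1, l2, l3]) / s
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(e > 0, e * np.log(e), 0.0))
    return {
        "L": (l1 - l2) / l1,
        "P": (l2 - l3) / l1,
        "S": l3 / l1,
        "O": (l1 * l2 * l3) ** (1.0 / 3.0),
        "A": (l1 - l3) / l1,
        "EE": float(ent),
        "SE": s,
        "CC": l3 / s,
    }


def geometric_local(
    neigh_points: np.ndarray, center: np.ndarray, spec: NeighborhoodSpec
) -> dict[str, float]:
    """FD, PD, HMax, HSD of one neighborhood (center's own entry included
    in the count k)."""
    pts = np.atleast_2d(np.asarray(neigh_points, dtype=float))
    center = np.asarray(center, dtype=float)
    r = spec.radius
    if r is None or r <= 0:
        raise ValueError("geometric_local needs an explicit radius")
    k = len(pts)
    fd = float(np.max(np.linalg.norm(pts - center, axis=1)))
    pd = k / (4.0 / 3.0 * np.pi * r ** 3)
    z = pts[:, 2]
    return {
        "FD": fd,
        "PD": float(pd),
        "HMax": float(z.max() - z.min()),
        "HSD": float(z.std()),  # population (divisor k)
    }


def _batched_local(points: np.ndarray, neighbors: list[np.ndarray], radius: float):
    """Vectorized per-vertex eigen + geometric features over all
    neighborhoods at once (reduceat over the concatenated neighbor lists)."""
    n = len(points)
    counts = np.array([len(ix) for ix in neighbors], dtype=np.int64)
    flat = np.concatenate(neighbors) if n else np.empty(0, np.int64)
    starts = np.zeros(n, dtype=np.int64)
    np.cumsum(counts[:-1], out=starts[1:])

    # center each neighborhood on its own vertex before taking moments:
    # covariance is translation-invariant and this avoids the cancellation
    # of raw second moments at world-coordinate scale
    P = points[flat] - points[np.repeat(np.arange(n), counts)]
    sums = np.add.reduceat(P, starts, axis=0)
    mean = sums / counts[:, None]
    # second moments
    prod = np.empty((len(P), 6))
    prod[:, 0] = P[:, 0] * P[:, 0]
    prod[:, 1] = P[:, 0] * P[:, 1]
    prod[:, 2] = P[:, 0] * P[:, 2]
    prod[:, 3] = P[:, 1] * P[:, 1]
    prod[:, 4] = P[:, 1] * P[:, 2]
    prod[:, 5] = P[:, 2] * P[:, 2]
    m2 = np.add.reduceat(prod, starts, axis=0) / counts[:, None]
    cov = np.empty((n, 3, 3))
    cov[:, 0, 0] = m2[:, 0] - mean[:, 0] ** 2
    cov[:, 0, 1] = cov[:, 1, 0] = m2[:, 1] - mean[:, 0] * mean[:, 1]
    cov[:, 0, 2] = cov[:, 2, 0] = m2[:, 2] - mean[:, 0] * mean[:, 2]
    cov[:, 1, 1] = m2[:, 3] - mean[:, 1] ** 2
    cov[:, 1, 2] = cov[:, 2, 1] = m2[:, 4] - mean[:, 1] * mean[:, 2]
    cov[:, 2, 2] = m2[:, 5] - mean[:, 2] ** 2
    lam = _clamp_eigs(np.linalg.eigvalsh(cov)[:, ::-1])

    l1, l2, l3 = lam[:, 0], lam[:, 1], lam[:, 2]
    safe1 = np.where(l1 > 0, l1, 1.0)
    s = l1 + l2 + l3
    safes = np.where(s > 0, s, 1.0)
    e = lam / safes[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(e > 0, e * np.log(np.where(e > 0, e, 1.0)), 0.0), axis=1)
    pos = l1 > 0
    feats = {
        "L": np.where(pos, (l1 - l2) / safe1, 0.0),
        "P": np.where(pos, (l2 - l3) / safe1, 0.0),
        "S": np.where(pos, l3 / safe1, 0.0),
        "O": np.where(pos, (l1 * l2 * l3) ** (1.0 / 3.0), 0.0),
        "A": np.where(pos, (l1 - l3) / safe1, 0.0),
        "EE": np.where(pos, ent, 0.0),
        "SE": np.where(pos, s, 0.0),
        "CC": np.where(pos, l3 / safes, 0.0),
    }

    # geometric features (P is already center-relative)
    dist2 = np.sum(P ** 2, axis=1)
    fd = np.sqrt(np.maximum.reduceat(dist2, starts))
    pd = counts / (4.0 / 3.0 * np.pi * radius ** 3)
    z = P[:, 2]
    zmax = np.maximum.reduceat(z, starts)
    zmin = np.minimum.reduceat(z, starts)
    zsd = np.sqrt(np.maximum(m2[:, 5] - mean[:, 2] ** 2, 0.0))
    feats.update({"FD": fd, "PD": pd, "HMax": zmax - zmin, "HSD": zsd})
    return feats, counts


def compute_local(
    mesh: trimesh.Trimesh, spec: NeighborhoodSpec | None = None
) -> LocalFeatures:
    """Mean of each pointwise local feature over all mesh vertices.

    Vertices with fewer than ``spec.min_neighbors`` neighbors are skipped
    from the averages and reported in ``n_skipped``.
    """
    spec = spec or NeighborhoodSpec()
    pts = mesh.vertices.view(np.ndarray).astype(float)
    med_edge = default_radius(mesh, factor=1.0)
    radius = spec.radius if spec.radius is not None else 4.0 * med_edge
    neighbors = radius_neighbors(pts, NeighborhoodSpec(radius=radius,
                                                       min_neighbors=spec.min_neighbors))
    feats, counts = _batched_local(pts, neighbors, radius)
    keep = counts >= spec.min_neighbors
    if not keep.any():
        raise ValueError("no vertex has enough neighbors at this radius")
    values = {k: float(np.mean(v[keep])) for k, v in feats.items()}
    return LocalFeatures(
        values=values,
        radius=float(radius),
        median_edge_length=float(med_edge),
        n_skipped=int((~keep).sum()),
    )
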