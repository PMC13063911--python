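"""Whole-mesh (global) shape features.

Eleven descriptors of overall ventricular form: asphericity (As) and
asphericity error (AsE) from a least-squares sphere fit, surface area (SA),
enclosed volume (V) and their ratio (SAVR), integral mean curvature (IMC),
and five convex-hull quantities (CHSA, CHV, CHSAR, CHVR, CHSAVR).

Units follow world millimetres: SA/CHSA in mm^2, V/CHV in mm^3, IMC in mm,
SAVR/CHSAVR in 1/mm; As, AsE, CHSAR, CHVR are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "SphereFit",
    "GlobalFeatures",
    "fit_sphere",
    "asphericity",
    "surface_area_volume",
    "integral_mean_curvature",
    "convex_hull_features",
    "compute_global",
    "GLOBAL_FEATURE_NAMES",
]

GLOBAL_FEATURE_NAMES = (
    "As", "AsE", "CHSA", "CHSAR", "CHSAVR", "CHV", "CHVR", "IMC",
    "SA", "SAVR", "V",
)


@dataclass
class SphereFit:
    """Least-squares sphere through a point cloud."""

    center: np.ndarray  # (3,) mm
    radius: float       # mm
    residuals: np.ndarray  # d_i - R per point, mm


@dataclass
class GlobalFeatures:
    As: float
    AsE: float
    SA: float
    V: float
    SAVR: float
    IMC: float
    CHSA: float
    CHSAR: float
    CHV: float
    CHVR: float
    CHSAVR: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in GLOBAL_FEATURE_NAMES}


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Least-squares sphere fit.

    Algebraic (Pratt-style) linear fit followed by Gauss–Newton refinement
    of the geometric objective sum((|p_i - c| - R)^2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need an (N>=4, 3) point array")
    # coplanarity check via covariance rank
    cov = np.cov(pts.T)
    if np.linalg.eigvalsh(cov)[0] < 1e-12 * max(np.linalg.eigvalsh(cov)[-1], 1e-30):
        raise ValueError("points are (nearly) coplanar; sphere fit is degenerate")

    # algebraic: |p|^2 = 2 c.p + (R^2 - |c|^2)
    A = np.c_[2.0 * pts, np.ones(len(pts))]
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    r = float(np.sqrt(max(sol[3] + c @ c, 0.0)))

    # Gauss-Newton refinement of the geometric distance
    for _ in range(20):
        d = np.linalg.norm(pts - c, axis=1)
        d = np.where(d < 1e-300, 1e-300, d)
        r_new = d.mean()
        J = np.c_[(c - pts) / d[:, None], -np.ones(len(pts))]
        resid = d - r_new
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        c = c + step[:3]
        r_new = r_new + step[3]
        if np.linalg.norm(step) < 1e-12 * max(r_new, 1.0):
            r = float(r_new)
            break
        r = float(r_new)
    d = np.linalg.norm(pts - c, axis=1)
    return SphereFit(center=c, radius=r, residuals=d - r)


def asphericity(fit: SphereFit) -> tuple[float, float]:
    """(As, AsE): relative mean-absolute and RMS radial deviation from the
    fitted sphere. Zero iff the points lie exactly on a sphere."""
    if fit.radius <= 0:
        raise ValueError("sphere fit has non-positive radius")
    res = fit.residuals
    As = float(np.mean(np.abs(res)) / fit.radius)
    AsE = float(np.sqrt(np.mean(res ** 2)) / fit.radius)
    return As, AsE


def surface_area_volume(mesh: trimesh.Trimesh) -> tuple[float, float, float]:
    """(SA, V, SAVR) of a watertight, outward-oriented mesh."""
    if not mesh.is_watertight:
        raise ValueError("volume is undefined for a non-watertight mesh")
    sa = float(mesh.area)
    v = float(abs(mesh.volume))
    return sa, v, sa / v


def integral_mean_curvature(mesh: trimesh.Trimesh) -> float:
    """IMC = sum over edges of length(e)/2 * signed dihedral angle.

    Convex edges (relative to outward normals) contribute positively; a
    sphere yields 4*pi*r in the refinement limit, a unit cube exactly 3*pi.
    """
    if not mesh.is_watertight:
        raise ValueError("IMC requires a closed mesh (no boundary edges)")
    angles = mesh.face_adjacency_angles  # unsigned angle between face normals
    sign = np.where(mesh.face_adjacency_convex, 1.0, -1.0)
    edges = mesh.face_adjacency_edges
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    return float(np.sum(0.5 * lengths * sign * angles))


def convex_hull_features(mesh: trimesh.Trimesh) -> tuple[float, float, float, float, float]:
    """(CHSA, CHV, CHSAR, CHVR, CHSAVR) from the convex hull of the mesh
    vertices (equals the hull of the surface for piecewise-linear meshes)."""
    hull = mesh.convex_hull
    chsa = float(hull.area)
    chv = float(abs(hull.volume))
    sa, v, _ = surface_area_volume(mesh)
    return chsa, chv, chsa / sa, chv / v, chsa / chv


def compute_global(mesh: trimesh.Trimesh) -> GlobalFeatures:
    """All eleven global features of a standardized mesh."""
    fit = fit_sphere(mesh.vertices.view(np.ndarray))
    As, AsE = asphericity(fit)
    sa, v, savr = surface_area_volume(mesh)
    imc = integral_mean_curvature(mesh)
    chsa, chv, chsar, chvr, chsavr = convex_hull_features(mesh)
    out = GlobalFeatures(
        As=As, AsE=AsE, SA=sa, V=v, SAVR=savr, IMC=imc,
        CHSA=chsa, CHSAR=chsar, CHV=chv, CHVR=chvr, CHSAVR=chsavr,
    )
    vals = out.as_dict()
    if not all(np.isfinite(list(vals.values()))):
        raise ValueError(f"non-finite global features: {vals}")
    return out
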