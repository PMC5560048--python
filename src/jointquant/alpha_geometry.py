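"""3D alpha shapes over point clouds and their volumes.

The alpha complex here is the subset of the Delaunay tetrahedralisation
whose tetrahedra have circumradius at most ``alpha``; its volume is the sum
of the retained tetrahedra volumes.  At ``alpha → ∞`` the complex is the
full Delaunay tetrahedralisation, i.e. the convex hull.

The "auto" radius is the *critical alpha*: the smallest alpha at which
every input point is a vertex of at least one retained tetrahedron, found
by scanning the sorted distinct circumradii.  This mirrors the behaviour of
automatic radius selection in common alpha-shape implementations, where the
chosen radius is the tightest one that still uses all the data.

Only the tetrahedron circumradius enters the criterion (no per-face test):
the single downstream consumer is a volume measurement, which depends only
on the retained tetrahedra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import DomainError, GeometryError

__all__ = ["AlphaShape3D", "critical_alpha", "build_alpha_shape", "shape_volume"]


def _validated_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if len(pts) < 4:
        raise GeometryError(f"alpha shape needs >= 4 points, got {len(pts)}")
    if np.linalg.matrix_rank(pts - pts[0], tol=1e-9 * max(1.0, np.abs(pts).max())) < 3:
        raise GeometryError("points are coplanar or collinear")
    return pts


def _tetra_circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron, vectorised.

    The circumcenter c solves 2 (v_i - v_0) · (c - v_0) = |v_i - v_0|² for
    i = 1..3.  Near-flat tetrahedra (singular system) get radius +inf so
    they are never retained at any finite alpha.
    """
    tets = points[simplices]  # (m, 4, 3)
    a = tets[:, 0]
    m = tets[:, 1:] - a[:, None, :]  # (m, 3, 3) rows v_i - v_0
    rhs = 0.5 * np.einsum("mij,mij->mi", m, m)
    det = np.linalg.det(m)
    radii = np.full(len(tets), np.inf)
    ok = np.abs(det) > np.finfo(float).tiny
    if ok.any():
        center_rel = np.linalg.solve(m[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(center_rel, axis=1)
    return radii


def _tetra_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    tets = points[simplices]
    m = tets[:, 1:] - tets[:, 0][:, None, :]
    return np.abs(np.linalg.det(m)) / 6.0


@dataclass(frozen=True)
class AlphaShape3D:
    """An alpha complex: points, the radius, and the retained tetrahedra.

    ``tetrahedra`` is an (m, 4) array of indices into ``points``; every
    retained tetrahedron has circumradius <= ``alpha``.
    """

    points: np.ndarray
    alpha: float
    tetrahedra: np.ndarray
    circumradii: np.ndarray

    @property
    def is_empty(self) -> bool:
        return len(self.tetrahedra) == 0

    def uses_all_points(self) -> bool:
        """True iff every input point is a vertex of some retained tetrahedron."""
        return len(np.unique(self.tetrahedra)) == len(self.points)


def _delaunay(points: np.ndarray) -> Delaunay:
    try:
        return Delaunay(points)
    except QhullError as exc:
        raise GeometryError(f"degenerate point configuration: {exc}") from None


def critical_alpha(points: np.ndarray) -> float:
    """Smallest alpha whose complex has every input point as a vertex.

    Scans the sorted distinct tetrahedron circumradii; coverage of the
    point set is monotone in alpha, so the first radius whose complex
    touches all points is the critical one.
    """
    pts = _validated_points(points)
    tri = _delaunay(pts)
    radii = _tetra_circumradii(pts, tri.simplices)
    finite = np.isfinite(radii)
    if not finite.any():
        raise GeometryError("all Delaunay tetrahedra are degenerate")
    n = len(pts)
    order = np.argsort(radii)
    covered = np.zeros(n, dtype=bool)
    n_covered = 0
    for k in order:
        if not np.isfinite(radii[k]):
            break
        for v in tri.simplices[k]:
            if not covered[v]:
                covered[v] = True
                n_covered += 1
        if n_covered == n:
            # all tets with radius <= radii[k] are in; this is the threshold
            return float(radii[k])
    raise GeometryError("no finite alpha covers all points")


def build_alpha_shape(points: np.ndarray, alpha: float | str = "auto") -> AlphaShape3D:
    """Alpha complex of ``points`` at radius ``alpha`` (µm), or the critical
    radius when ``alpha="auto"``."""
    pts = _validated_points(points)
    if alpha == "auto":
        alpha_val = critical_alpha(pts)
    else:
        alpha_val = float(alpha)
        if alpha_val <= 0:
            raise DomainError(f"alpha must be > 0, got {alpha_val}")
    tri = _delaunay(pts)
    radii = _tetra_circumradii(pts, tri.simplices)
    keep = radii <= alpha_val
    return AlphaShape3D(
        points=pts,
        alpha=alpha_val,
        tetrahedra=tri.simplices[keep],
        circumradii=radii[keep],
    )


def shape_volume(shape: AlphaShape3D) -> float:
    """Volume in µm³: Σ |det([b−a, c−a, d−a])| / 6 over retained tetrahedra."""
    if shape.is_empty:
        return 0.0
    return float(_tetra_volumes(shape.points, shape.tetrahedra).sum())
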