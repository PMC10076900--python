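"""Low-level geometric primitives shared by the measurement methods.

Everything here works in physical coordinates (mm).  The two non-trivial
pieces are the UV-sphere tessellation that defines the ray bundle of the
ray-tracing method and a first-hit ray/mesh intersector (Möller–Trumbore
with a KD-tree candidate prefilter) used by the mesh-normal method.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "uv_sphere_directions",
    "uv_sphere_vertex_count",
    "fit_sphere",
    "first_ray_mesh_hits",
    "column_runs",
]


def uv_sphere_vertex_count(n_polar: int, n_azimuthal: int) -> int:
    """Number of distinct surface vertices of a UV sphere.

    ``n_polar`` vertex subdivisions along the polar direction include the two
    poles; each of the ``n_polar - 2`` interior latitude rings carries
    ``n_azimuthal`` vertices, so the count is ``2 + n_azimuthal*(n_polar-2)``.
    """
    if n_polar < 3 or n_azimuthal < 3:
        raise ValueError("sphere subdivisions must be >= 3")
    return 2 + n_azimuthal * (n_polar - 2)


def uv_sphere_directions(n_polar: int = 60, n_azimuthal: int = 60) -> np.ndarray:
    """Outward unit directions at the vertices of a UV-sphere tessellation.

    Returns an array of shape ``(2 + n_azimuthal*(n_polar-2), 3)``: the two
    poles plus the interior latitude rings.  Each vertex direction doubles as
    the outward surface normal of the sphere, i.e. one ray direction.
    """
    n = uv_sphere_vertex_count(n_polar, n_azimuthal)
    theta = np.pi * np.arange(1, n_polar - 1) / (n_polar - 1)  # interior rings
    phi = 2.0 * np.pi * np.arange(n_azimuthal) / n_azimuthal
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.empty((n, 3), dtype=float)
    dirs[0] = (0.0, 0.0, 1.0)
    dirs[1] = (0.0, 0.0, -1.0)
    ring = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    )
    dirs[2:] = ring.reshape(-1, 3)
    return dirs


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit.

    Solves ``|x|^2 = 2 c.x + (R^2 - |c|^2)`` as a linear system.  Returns
    ``(center, radius)``.  Raises ``numpy.linalg.LinAlgError`` for degenerate
    (e.g. coplanar) point sets with no stable solution; callers provide a
    fallback.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise np.linalg.LinAlgError("need >= 4 points for a sphere fit")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if not np.isfinite(r2) or r2 <= 0:
        raise np.linalg.LinAlgError("degenerate sphere fit")
    # Guard against near-flat data where the normal equations are ill posed.
    radius = float(np.sqrt(r2))
    spread = pts.max(axis=0) - pts.min(axis=0)
    if radius > 50.0 * max(spread.max(), 1e-9):
        raise np.linalg.LinAlgError("sphere fit radius implausibly large")
    return center, radius


def _moller_trumbore(origin, direction, tri):
    """Ray/triangle intersection distances for one ray against many triangles.

    ``tri`` has shape (F, 3, 3).  Returns an array of ray parameters t (>= 0
    where a hit exists, +inf otherwise).
    """
    eps = 1e-12
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol) & (t > eps)
    return np.where(hit, t, np.inf)


def first_ray_mesh_hits(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    max_dist: float,
) -> np.ndarray:
    """First-hit distances of rays against a triangle mesh.

    For every ray (unit ``directions``) the nearest intersection parameter t
    in ``(0, max_dist]`` is returned, or ``nan`` for a miss.  Candidate
    triangles are preselected with a KD-tree over face centroids queried at
    coarse samples along each ray, which keeps the exact Möller–Trumbore test
    to a handful of faces per ray.
    """
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    tri = vertices[faces]  # (F, 3, 3)
    centroids = tri.mean(axis=1)
    # circumradius bound: max distance centroid -> own vertices
    face_r = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)

    step = max(face_r, 0.5)
    n_samples = int(np.ceil(max_dist / step)) + 1
    s = np.linspace(0.0, max_dist, n_samples)
    # (n_rays, n_samples, 3) coarse sample points
    pts = origins[:, None, :] + s[None, :, None] * directions[:, None, :]
    radius = face_r + 0.6 * step
    neighborhoods = tree.query_ball_point(pts.reshape(-1, 3), r=radius)
    neighborhoods = np.reshape(np.asarray(neighborhoods, dtype=object), (len(origins), n_samples))

    out = np.full(len(origins), np.nan)
    for i in range(len(origins)):
        cand: set[int] = set()
        for lst in neighborhoods[i]:
            cand.update(lst)
        if not cand:
            continue
        idx = np.fromiter(cand, dtype=np.intp)
        t = _moller_trumbore(origins[i], directions[i], tri[idx])
        tmin = t.min()
        if np.isfinite(tmin) and tmin <= max_dist:
            out[i] = tmin
    return out


def column_runs(sorted_k: np.ndarray) -> int:
    """Number of disjoint contiguous runs in a sorted 1-D integer array."""
    if len(sorted_k) == 0:
        return 0
    return int(1 + np.count_nonzero(np.diff(sorted_k) > 1))
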