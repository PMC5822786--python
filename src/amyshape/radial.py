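"""PCA alignment and radial surface sampling.

Each smoothed mesh is centred at its center of inertia (COI), rotated so its
principal axes of vertex covariance map to x > y > z by descending eigenvalue
(with a deterministic third-moment sign rule), and then sampled at a fixed
lattice of unit directions: the radius along direction ``d`` is the distance
from the COI to the farthest ray-surface intersection.  Sampling along a
shared direction lattice is what gives point correspondence across subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionSet",
    "RadialShape",
    "make_directions",
    "pca_align",
    "compute_radii",
    "ray_cast",
]


@dataclass(frozen=True)
class DirectionSet:
    """A fixed, deterministically ordered set of unit direction vectors."""

    directions: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) >= 1e-12):
            raise ValueError("directions must be unit-norm")
        object.__setattr__(self, "directions", d)

    def __len__(self) -> int:
        return len(self.directions)


@dataclass
class RadialShape:
    """Per-direction radii (mm) of one hemisphere surface from its COI."""

    subject_id: str
    side: str
    coi: np.ndarray  # world-space COI, mm
    radii: np.ndarray  # mm, one per direction
    alignment: np.ndarray  # 4x4 world -> aligned frame transform

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("radii must be finite and positive")
        self.radii = r

    def surface_points(self) -> np.ndarray:
        """Surface point coordinates in the aligned frame."""
        return self.radii[:, None] * _shared_directions(len(self.radii))


_direction_cache: dict = {}


def _shared_directions(n: int) -> np.ndarray:
    if n not in _direction_cache:
        _direction_cache[n] = make_directions(n).directions
    return _direction_cache[n]


def make_directions(n: int) -> DirectionSet:
    """Spherical Fibonacci lattice of ``n`` near-equal-area unit directions."""
    if n < 12:
        raise ValueError("need at least 12 directions")
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    d = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return DirectionSet(directions=d)


def pca_align(mesh: trimesh.Trimesh) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Centre a mesh at its COI and rotate principal axes onto x > y > z.

    The COI is the unweighted mean of the vertex coordinates.  Axis signs are
    fixed so the third central moment of the vertex coordinates along each of
    the first two axes is >= 0, and the third axis completes a right-handed
    frame; this replaces manual alignment inspection with a deterministic
    rule.  Returns the aligned mesh and the 4x4 world->aligned transform.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    coi = V.mean(axis=0)
    X = V - coi
    C = (X.T @ X) / len(X)
    evals, evecs = np.linalg.eigh(C)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[-1] <= 1e-10 * evals[0]:
        raise ValueError("degenerate vertex covariance: points are coplanar/collinear")
    ratios = evals[:-1] / evals[1:]
    if np.any(ratios < 1.01):
        warnings.warn(
            "near-equal covariance eigenvalues (ratio < 1.01): principal-axis "
            "alignment is unstable for this shape"
        )

    axes = []
    for k in range(3):
        a = evecs[:, k]
        proj = X @ a
        skew = np.mean(proj**3)
        if abs(skew) < 1e-9 * max(evals[k] ** 1.5, 1e-30):
            # symmetric along this axis: fall back to a fixed component rule
            if a[np.argmax(np.abs(a))] < 0:
                a = -a
        elif skew < 0:
            a = -a
        axes.append(a)
    R = np.array(axes)
    if np.linalg.det(R) < 0:
        # restore a proper rotation by flipping the most symmetric axis
        skews = [abs(np.mean((X @ R[k]) ** 3)) for k in range(3)]
        R[int(np.argmin(skews))] *= -1.0

    Y = X @ R.T
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = -R @ coi
    out = trimesh.Trimesh(vertices=Y, faces=mesh.faces.copy(), process=False)
    if out.volume < 0:
        out.invert()
    return out, T


# ---------------------------------------------------------------------------
# Ray casting (Moller-Trumbore), the radial sampling primitive
# ---------------------------------------------------------------------------

try:  # jitted kernel; the numpy fallback below is semantically identical
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _ray_cast_kernel(v0, e1, e2, dirs, origin):  # pragma: no cover
        n_rays = dirs.shape[0]
        n_tri = v0.shape[0]
        far = np.full(n_rays, -1.0)
        hits = np.zeros(n_rays, dtype=np.int64)
        for i in range(n_rays):
            dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
            for j in range(n_tri):
                e2x, e2y, e2z = e2[j, 0], e2[j, 1], e2[j, 2]
                hx = dy * e2z - dz * e2y
                hy = dz * e2x - dx * e2z
                hz = dx * e2y - dy * e2x
                a = e1[j, 0] * hx + e1[j, 1] * hy + e1[j, 2] * hz
                if -1e-12 < a < 1e-12:
                    continue
                f = 1.0 / a
                sx = origin[0] - v0[j, 0]
                sy = origin[1] - v0[j, 1]
                sz = origin[2] - v0[j, 2]
                u = f * (sx * hx + sy * hy + sz * hz)
                if u < -1e-9 or u > 1.0 + 1e-9:
                    continue
                qx = sy * e1[j, 2] - sz * e1[j, 1]
                qy = sz * e1[j, 0] - sx * e1[j, 2]
                qz = sx * e1[j, 1] - sy * e1[j, 0]
                v = f * (dx * qx + dy * qy + dz * qz)
                if v < -1e-9 or u + v > 1.0 + 1e-9:
                    continue
                t = f * (e2x * qx + e2y * qy + e2z * qz)
                if t > 1e-9:
                    hits[i] += 1
                    if t > far[i]:
                        far[i] = t
        return far, hits

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _ray_cast_numpy(v0, e1, e2, dirs, origin):
    n_rays = len(dirs)
    far = np.full(n_rays, -1.0)
    hits = np.zeros(n_rays, dtype=int)
    s = origin - v0  # (M, 3)
    q = np.cross(s, e1)  # (M, 3)
    t_num = np.einsum("mk,mk->m", e2, q)  # (M,)
    chunk = 64
    for lo in range(0, n_rays, chunk):
        D = dirs[lo : lo + chunk]  # (k, 3)
        h = np.cross(D[:, None, :], e2[None, :, :])  # (k, M, 3)
        a = np.einsum("mk,cmk->cm", e1, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(np.abs(a) > 1e-12, 1.0 / a, 0.0)
            u = f * np.einsum("mk,cmk->cm", s, h)
            v = f * (D @ q.T)
            t = f * t_num[None, :]
        ok = (
            (np.abs(a) > 1e-12)
            & (u >= -1e-9)
            & (v >= -1e-9)
            & (u + v <= 1.0 + 1e-9)
            & (t > 1e-9)
        )
        hits[lo : lo + chunk] = ok.sum(axis=1)
        t_masked = np.where(ok, t, -1.0)
        far[lo : lo + chunk] = t_masked.max(axis=1)
    return far, hits


def ray_cast(
    vertices: np.ndarray,
    faces: np.ndarray,
    directions: np.ndarray,
    origin: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Farthest ray-triangle intersection distance per direction.

    Returns ``(distances, hit_counts)``; a distance is NaN where the ray never
    crosses the surface.
    """
    v = np.ascontiguousarray(vertices, dtype=np.float64)
    f = np.asarray(faces)
    d = np.ascontiguousarray(directions, dtype=np.float64)
    o = np.zeros(3) if origin is None else np.asarray(origin, dtype=np.float64)
    v0 = v[f[:, 0]]
    e1 = np.ascontiguousarray(v[f[:, 1]] - v0)
    e2 = np.ascontiguousarray(v[f[:, 2]] - v0)
    if _HAVE_NUMBA:
        far, hits = _ray_cast_kernel(v0, e1, e2, d, o)
    else:
        far, hits = _ray_cast_numpy(v0, e1, e2, d, o)
    far = np.asarray(far, dtype=float)
    far[far < 0] = np.nan
    return far, np.asarray(hits)


def compute_radii(
    mesh: trimesh.Trimesh,
    directions: DirectionSet,
    subject_id: str = "",
    side: str = "left",
    alignment: np.ndarray | None = None,
    coi: np.ndarray | None = None,
) -> RadialShape:
    """Sample radii from the COI (frame origin) along every direction.

    The mesh must already be aligned and centred; the radius along each
    direction is the distance to the farthest surface crossing, so mild
    non-star-shapedness resolves to the outer surface (multi-crossing rays
    are counted and logged).
    """
    dist, hits = ray_cast(mesh.vertices, mesh.faces, directions.directions)
    missing = np.flatnonzero(~np.isfinite(dist))
    if len(missing):
        raise ValueError(
            f"ray {int(missing[0])} has no surface intersection: the mesh does "
            "not enclose the COI"
        )
    multi = int(np.count_nonzero(hits > 1))
    if multi:
        logger.info(
            "%s/%s: %d of %d rays cross the surface more than once",
            subject_id, side, multi, len(directions),
        )
    return RadialShape(
        subject_id=subject_id,
        side=side,
        coi=np.zeros(3) if coi is None else np.asarray(coi, dtype=float),
        radii=dist,
        alignment=np.eye(4) if alignment is None else np.asarray(alignment, dtype=float),
    )
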