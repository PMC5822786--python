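"""Binary mask -> smoothed closed triangle mesh in world (mm) coordinates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import sparse
from skimage import measure

__all__ = ["BinaryVolume", "extract_surface", "smooth_surface", "mask_volume_mm3"]


@dataclass
class BinaryVolume:
    """A subject's hemisphere mask with a voxel->world affine.

    Voxel index (i, j, k) maps to the world position of the voxel *centre*
    via ``affine @ (i, j, k, 1)``.
    """

    grid: np.ndarray
    affine: np.ndarray
    side: str = "left"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def n_foreground(self) -> int:
        return int(np.count_nonzero(self.grid))


def mask_volume_mm3(volume: BinaryVolume) -> float:
    """Structure volume: foreground voxel count times voxel volume."""
    voxel_vol = abs(np.linalg.det(volume.affine[:3, :3]))
    return volume.n_foreground * voxel_vol


def extract_surface(volume: BinaryVolume) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a binary volume at level 0.5, in world mm.

    The grid is zero-padded so structures touching the array edge still close.
    The largest connected component is kept and orientation is fixed so the
    enclosed volume is positive.  Raises if the mask is empty or the resulting
    mesh is not watertight.
    """
    if volume.n_foreground == 0:
        raise ValueError("empty mask: no foreground voxels")
    padded = np.pad(volume.grid.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding; still voxel-index coordinates
    verts = verts @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda m: len(m.vertices))
    if not mesh.is_watertight:
        raise ValueError("extracted surface is not closed")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _umbrella_operator(mesh: trimesh.Trimesh) -> sparse.csr_matrix:
    """Row-stochastic vertex adjacency (uniform neighbour weights)."""
    e = mesh.edges_unique
    n = len(mesh.vertices)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    W = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    deg = np.asarray(W.sum(axis=1)).ravel()
    if np.any(deg == 0):
        raise ValueError("mesh has isolated vertices")
    return sparse.diags(1.0 / deg) @ W


def smooth_surface(
    mesh: trimesh.Trimesh, iterations: int = 10, lam: float = 0.5
) -> trimesh.Trimesh:
    """Laplacian (umbrella) smoothing: each iteration moves every vertex by
    ``lam * (mean of topological neighbours - vertex)``.

    Connectivity is untouched; vertex and face counts are preserved.
    """
    if not 0 < lam <= 1:
        raise ValueError("lam must be in (0, 1]")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mesh.copy()
    W = _umbrella_operator(mesh)
    V = mesh.vertices.copy()
    for _ in range(iterations):
        V = V + lam * (W @ V - V)
    out = trimesh.Trimesh(vertices=V, faces=mesh.faces.copy(), process=False)
    if out.volume < 0:
        out.invert()
    return out
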