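"""Probabilistic subregion atlas projection onto surface points.

A subregion atlas is a set of probability volumes (laterobasal LB,
superficial SF, centromedial CM) in its own space.  Each subject's surface
points are mapped from native space into atlas space, the three probabilities
are sampled at the mapped coordinates, and each point is labelled with the
most probable subregion.  Any atlas with this NIfTI layout can be used; a
synthetic azimuthal-wedge atlas is provided so no external download is
required for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage

from .radial import RadialShape
from .surface import BinaryVolume

SUBREGIONS = ("LB", "SF", "CM")  # argmax tie precedence is this order

__all__ = [
    "SUBREGIONS",
    "SubregionAtlas",
    "SurfaceSubregionMap",
    "invert_affine",
    "estimate_affine_by_moments",
    "map_subregions",
    "template_subregion_map",
    "make_wedge_atlas",
]


@dataclass
class SubregionAtlas:
    """Per-subregion probability volumes sharing one atlas-space affine."""

    probabilities: Dict[str, np.ndarray]
    affine: np.ndarray
    side: str = "left"

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        vols = [np.asarray(self.probabilities[k], dtype=float) for k in SUBREGIONS]
        for k, v in zip(SUBREGIONS, vols):
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError(f"{k} probabilities outside [0, 1]")
            self.probabilities[k] = np.clip(v, 0.0, 1.0)
        total = sum(self.probabilities[k] for k in SUBREGIONS)
        if np.any(total > 1 + 1e-6):
            raise ValueError("subregion probabilities sum above 1 at some voxel")


@dataclass
class SurfaceSubregionMap:
    """Per-surface-point subregion probabilities, labels and composition."""

    probabilities: np.ndarray  # (n_points, 3) in SUBREGIONS order
    labels: np.ndarray  # strings in SUBREGIONS or "none"
    composition: Dict[str, float]
    n_outside: int = 0

    @property
    def n_points(self) -> int:
        return len(self.labels)


def invert_affine(native_to_atlas: np.ndarray) -> np.ndarray:
    """Exact inverse of a 4x4 affine; raises on singular input."""
    A = np.asarray(native_to_atlas, dtype=float)
    if A.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("affine is singular")
    return np.linalg.inv(A)


def _mask_moments(volume: BinaryVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World-space centroid, principal axes (sign-fixed) and axis SDs of a mask."""
    idx = np.argwhere(volume.grid > 0)
    if len(idx) == 0:
        raise ValueError("empty mask")
    pts = idx @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    c = pts.mean(axis=0)
    X = pts - c
    C = (X.T @ X) / len(X)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-10 * evals[0]:
        raise ValueError("degenerate mask moments")
    axes = []
    for k in range(3):
        a = evecs[:, k]
        skew = np.mean((X @ a) ** 3)
        if (abs(skew) < 1e-9 and a[np.argmax(np.abs(a))] < 0) or skew < 0:
            a = -a
        axes.append(a)
    R = np.array(axes)
    if np.linalg.det(R) < 0:
        skews = [abs(np.mean((X @ R[k]) ** 3)) for k in range(3)]
        R[int(np.argmin(skews))] *= -1.0
    return c, R, np.sqrt(evals)


def estimate_affine_by_moments(
    subject_mask: BinaryVolume, atlas_mask: BinaryVolume
) -> np.ndarray:
    """Native->atlas affine matching centroids and principal second moments.

    A deterministic stand-in for an external volumetric registration: rotation
    from matched principal axes, per-axis scale from the moment SD ratios,
    translation from the centroids.
    """
    c_s, R_s, s_s = _mask_moments(subject_mask)
    c_a, R_a, s_a = _mask_moments(atlas_mask)
    scale = np.diag(s_a / s_s)
    M = R_a.T @ scale @ R_s
    A = np.eye(4)
    A[:3, :3] = M
    A[:3, 3] = c_a - M @ c_s
    return A


def _sample_volume(
    vol: np.ndarray,
    atlas_affine: np.ndarray,
    points_world: np.ndarray,
    interpolation: str,
) -> tuple[np.ndarray, np.ndarray]:
    inv = np.linalg.inv(atlas_affine)
    vox = points_world @ inv[:3, :3].T + inv[:3, 3]
    shape = np.asarray(vol.shape)
    outside = np.any((vox < -0.5) | (vox > shape - 0.5), axis=1)
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    vals = ndimage.map_coordinates(
        vol, vox.T, order=order, mode="constant", cval=0.0
    )
    vals[outside] = 0.0
    return np.clip(vals, 0.0, 1.0), outside


def _label_and_compose(
    probs: np.ndarray,
) -> tuple[np.ndarray, Dict[str, float]]:
    labels = np.full(len(probs), "none", dtype=object)
    has_prob = probs.max(axis=1) > 0
    # np.argmax takes the first maximum, which encodes the LB > SF > CM tie rule
    winner = np.argmax(probs, axis=1)
    labels[has_prob] = np.array(SUBREGIONS, dtype=object)[winner[has_prob]]
    n_labeled = int(has_prob.sum())
    if n_labeled == 0:
        warnings.warn("no surface point received a nonzero subregion probability")
        composition = {}
    else:
        composition = {
            k: float(np.count_nonzero(labels == k)) / n_labeled for k in SUBREGIONS
        }
    return labels.astype(str), composition


def map_subregions(
    shape: RadialShape,
    atlas: SubregionAtlas,
    native_to_atlas: Optional[np.ndarray] = None,
    interpolation: str = "trilinear",
) -> SurfaceSubregionMap:
    """Sample subregion probabilities at a subject's surface points.

    Surface points are taken in the shape's registered frame, mapped back to
    native space through the inverse of the stored alignment, and then into
    atlas voxel coordinates through ``native_to_atlas`` and the atlas affine.
    Points landing outside the atlas volume get probability 0 everywhere.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError("interpolation must be 'trilinear' or 'nearest'")
    pts = shape.surface_points()
    native = pts @ np.linalg.inv(shape.alignment[:3, :3]).T
    native = native + np.linalg.inv(shape.alignment)[:3, 3]
    if native_to_atlas is not None:
        native = native @ np.asarray(native_to_atlas)[:3, :3].T + np.asarray(
            native_to_atlas
        )[:3, 3]
    probs = np.zeros((len(pts), 3))
    outside = np.zeros(len(pts), dtype=bool)
    for j, k in enumerate(SUBREGIONS):
        vals, out = _sample_volume(
            atlas.probabilities[k], atlas.affine, native, interpolation
        )
        probs[:, j] = vals
        outside |= out
    labels, composition = _label_and_compose(probs)
    return SurfaceSubregionMap(
        probabilities=probs,
        labels=labels,
        composition=composition,
        n_outside=int(outside.sum()),
    )


def template_subregion_map(maps: List[SurfaceSubregionMap]) -> SurfaceSubregionMap:
    """Average per-point probabilities across subjects; relabel from the mean."""
    if not maps:
        raise ValueError("need at least one subregion map")
    n = maps[0].n_points
    for m in maps:
        if m.n_points != n:
            raise ValueError("mismatched surface point counts across maps")
    probs = np.mean([m.probabilities for m in maps], axis=0)
    labels, composition = _label_and_compose(probs)
    return SurfaceSubregionMap(
        probabilities=probs,
        labels=labels,
        composition=composition,
        n_outside=0,
    )


def make_wedge_atlas(
    extent_mm: float = 20.0,
    voxel_size: float = 1.0,
    side: str = "left",
    lb_deg: tuple[float, float] = (-90.0, 90.0),
    sf_deg: tuple[float, float] = (90.0, 240.0),
) -> SubregionAtlas:
    """Synthetic three-wedge atlas splitting space by azimuth around +z.

    Probability-1 wedges: LB on ``lb_deg`` (default the +x half-space), SF on
    ``sf_deg``, CM on the remainder; the affine centres the volume on the
    origin.  The default split mimics the roughly 50/40/10 subregion makeup
    of an amygdala surface.
    """
    n = int(np.ceil(2 * extent_mm / voxel_size)) + 1
    coords = (np.arange(n) - (n - 1) / 2) * voxel_size
    x, y, _ = np.meshgrid(coords, coords, coords, indexing="ij")
    phi = np.degrees(np.arctan2(y, x))  # [-180, 180)

    def in_wedge(lo: float, hi: float) -> np.ndarray:
        lo_w = (lo + 180.0) % 360.0 - 180.0
        hi_w = (hi + 180.0) % 360.0 - 180.0
        if lo_w <= hi_w:
            return (phi >= lo_w) & (phi < hi_w)
        return (phi >= lo_w) | (phi < hi_w)

    lb = in_wedge(*lb_deg)
    sf = in_wedge(*sf_deg) & ~lb
    cm = ~(lb | sf)
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -(n - 1) / 2 * voxel_size
    return SubregionAtlas(
        probabilities={
            "LB": lb.astype(float),
            "SF": sf.astype(float),
            "CM": cm.astype(float),
        },
        affine=affine,
        side=side,
    )
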