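"""Synthetic cohort generation: subject tables and behavior-coupled masks.

This module emulates a preseason cohort of 30 collegiate football players:
POMS mood subscales, total mood disturbance (TMD), post-concussion symptom
scale (PCSS) totals, concussion history, age and estimated total intracranial
volume (eTIV), plus amygdala-like binary masks whose local surface radii are
linearly coupled to a chosen mood score within a chosen patch of the surface.

The mask generator is a star-shaped superellipsoid defined by a closed-form
radial function ``r(d)`` over unit directions ``d``: a superellipsoid base with
a fixed mild skew (so principal-axis alignment has a deterministic sign), a
flat-topped cosine-tapered bump whose amplitude is ``beta_true`` millimetres
per point of the coupled score, and a smooth Gaussian random field with exact
per-direction marginal standard deviation ``noise_sd``.  Because the shape is
given radially, the ground-truth surface is known in closed form at every
direction, which is what the downstream geometric accuracy checks rely on.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

__all__ = [
    "POMS_SUBSCALE_MAX",
    "PCSS_MAX",
    "SubjectRecord",
    "CohortConfig",
    "compute_tmd",
    "tmd_from_subscales",
    "generate_subject_table",
    "generate_mask",
    "subject_table_to_frame",
    "frame_to_subject_table",
    "surface_radius",
    "base_radius",
    "bump_weight",
    "effect_direction_indices",
]

# Standard 65-item POMS subscale item counts x the 0-4 item scale.
POMS_SUBSCALE_MAX: Dict[str, int] = {
    "poms_tension": 36,      # 9 items
    "poms_depression": 60,   # 15 items
    "poms_anger": 48,        # 12 items
    "poms_fatigue": 28,      # 7 items
    "poms_confusion": 28,    # 7 items
    "poms_vigor": 32,        # 8 items
}
NEGATIVE_SCALES = (
    "poms_tension",
    "poms_depression",
    "poms_anger",
    "poms_fatigue",
    "poms_confusion",
)
PCSS_MAX = 132  # 22 items x max 6


@dataclass
class SubjectRecord:
    """One subject's demographic, mood and symptom data."""

    subject_id: str
    age: int
    etiv: float  # cm^3
    poms_tension: int
    poms_depression: int
    poms_anger: int
    poms_fatigue: int
    poms_confusion: int
    poms_vigor: int
    poms_tmd: int
    pcss_total: Optional[int]
    concussion_count: int
    followup_poms: Optional[Dict[str, int]] = None

    def poms(self) -> Dict[str, int]:
        return {name: getattr(self, name) for name in POMS_SUBSCALE_MAX}


def tmd_from_subscales(
    tension: float,
    depression: float,
    anger: float,
    fatigue: float,
    confusion: float,
    vigor: float,
) -> float:
    """Total mood disturbance: the five negative subscales summed minus vigor."""
    return tension + depression + anger + fatigue + confusion - vigor


def compute_tmd(record: SubjectRecord) -> int:
    """TMD of a subject record from its six POMS subscales."""
    values = []
    for name in POMS_SUBSCALE_MAX:
        v = getattr(record, name, None)
        if v is None:
            raise ValueError(f"missing POMS subscale {name!r}")
        values.append(v)
    t, d, a, f, c, v = values
    return int(tmd_from_subscales(t, d, a, f, c, v))


# Distributional defaults follow the published cohort description: subscale
# means/SDs of the baseline table, age 21.69 (1.58) truncated to 18-25 years,
# eTIV 1466.89 (200.74) cm^3, concussion counts 0/1/2 with frequencies
# 19/6/5 of 30, PCSS zero-inflated around a low mean.
DEFAULT_SCORE_PARAMS: Dict[str, Tuple[float, float]] = {
    "poms_tension": (8.70, 4.84),
    "poms_depression": (5.90, 5.37),
    "poms_anger": (7.87, 6.94),
    "poms_fatigue": (6.67, 4.79),
    "poms_confusion": (6.10, 4.39),
    "poms_vigor": (17.63, 5.57),
}


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    ``beta_true`` is the radial deformation in mm per point of
    ``coupled_scale`` applied over the effect patch on the ``effect_side``
    surface; ``noise_sd`` is the per-direction SD of the smooth shape noise
    field in mm.  The effect patch is a spherical cap around
    ``effect_center``: full amplitude inside ``plateau_deg``, cosine taper to
    zero at ``taper_deg``.
    """

    n_subjects: int = 30
    seed: int = 0
    score_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_PARAMS)
    )
    coupled_scale: str = "poms_depression"
    beta_true: float = 0.08  # mm per score point
    noise_sd: float = 0.2  # mm
    base_axes: Tuple[float, float, float] = (10.0, 7.0, 5.5)  # mm semi-axes
    base_exponent: float = 2.2
    base_skew: Tuple[float, float, float] = (0.08, 0.06, 0.05)
    effect_side: str = "left"
    effect_center: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    plateau_deg: float = 35.0
    taper_deg: float = 55.0
    voxel_size: float = 1.0  # mm, isotropic (matches 1.0 mm acquisition slices)
    age_params: Tuple[float, float, int, int] = (21.69, 1.58, 18, 25)
    etiv_params: Tuple[float, float] = (1466.89, 200.74)  # cm^3
    concussion_probs: Tuple[float, ...] = (19 / 30, 6 / 30, 5 / 30)
    pcss_zero_prob: float = 0.5
    pcss_params: Tuple[float, float] = (5.0, 5.0)
    n_followup: int = 14
    followup_shift_sd: float = 4.0
    noise_n_basis: int = 48
    noise_width_rad: float = 0.5

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3: downstream statistics are undefined")
        if self.beta_true < 0:
            raise ValueError("beta_true must be >= 0")
        if not 0 < self.plateau_deg < self.taper_deg <= 180:
            raise ValueError("need 0 < plateau_deg < taper_deg <= 180")
        if self.coupled_scale not in set(POMS_SUBSCALE_MAX) | {"poms_tmd", "pcss_total"}:
            raise ValueError(f"unknown coupled_scale {self.coupled_scale!r}")
        if min(self.base_axes) <= 0 or self.voxel_size <= 0:
            raise ValueError("base_axes and voxel_size must be positive")


def _truncnorm_ints(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int, size: int
) -> np.ndarray:
    """Rounded truncated-normal draws on [lo, hi]; degenerate when sd == 0."""
    if sd == 0:
        return np.full(size, int(np.clip(round(mean), lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.rint(draws).astype(int), lo, hi)


def generate_subject_table(config: CohortConfig) -> List[SubjectRecord]:
    """Draw a cohort of subject records; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0x5C07])
    n = config.n_subjects

    scores = {
        name: _truncnorm_ints(rng, m, sd, 0, POMS_SUBSCALE_MAX[name], n)
        for name, (m, sd) in config.score_params.items()
    }
    age_m, age_sd, age_lo, age_hi = config.age_params
    ages = _truncnorm_ints(rng, age_m, age_sd, age_lo, age_hi, n)
    etiv_m, etiv_sd = config.etiv_params
    if etiv_sd == 0:
        etivs = np.full(n, etiv_m)
    else:
        a = (etiv_m * 0.3 - etiv_m) / etiv_sd  # keep volumes physiologic (> 30% of mean)
        etivs = truncnorm.rvs(a, np.inf, loc=etiv_m, scale=etiv_sd, size=n, random_state=rng)

    zero = rng.random(n) < config.pcss_zero_prob
    pcss = _truncnorm_ints(rng, *config.pcss_params, 0, PCSS_MAX, n)
    pcss[zero] = 0
    concussions = rng.choice(
        len(config.concussion_probs), size=n, p=np.asarray(config.concussion_probs)
    )

    records = []
    for i in range(n):
        sub = {name: int(scores[name][i]) for name in POMS_SUBSCALE_MAX}
        followup = None
        if i < config.n_followup:
            followup = {}
            for name in POMS_SUBSCALE_MAX:
                shift = rng.normal(0.0, config.followup_shift_sd)
                followup[name] = int(
                    np.clip(round(sub[name] + shift), 0, POMS_SUBSCALE_MAX[name])
                )
            followup["poms_tmd"] = int(
                tmd_from_subscales(*(followup[s] for s in NEGATIVE_SCALES),
                                   followup["poms_vigor"])
            )
        rec = SubjectRecord(
            subject_id=f"sub-{i + 1:03d}",
            age=int(ages[i]),
            etiv=float(etivs[i]),
            **sub,
            poms_tmd=int(tmd_from_subscales(*(sub[s] for s in NEGATIVE_SCALES),
                                            sub["poms_vigor"])),
            pcss_total=int(pcss[i]),
            concussion_count=int(concussions[i]),
            followup_poms=followup,
        )
        records.append(rec)
    # One of 30 subjects did not complete the PCSS in the emulated cohort.
    if n >= 30:
        records[-1].pcss_total = None
    return records


# ---------------------------------------------------------------------------
# Continuous radial shape model
# ---------------------------------------------------------------------------

def base_radius(directions: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Closed-form base radius (mm) of the skewed superellipsoid along unit directions."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    a = np.asarray(config.base_axes)
    p = config.base_exponent
    r0 = np.sum(np.abs(d / a) ** p, axis=1) ** (-1.0 / p)
    s = np.asarray(config.base_skew)
    skew = 1.0 + (d**3 * s).sum(axis=1)
    return r0 * skew


def bump_weight(directions: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Flat-top cosine-taper cap weight in [0, 1] around ``effect_center``."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    c = np.asarray(config.effect_center, dtype=float)
    c = c / np.linalg.norm(c)
    theta = np.degrees(np.arccos(np.clip(d @ c, -1.0, 1.0)))
    t0, t1 = config.plateau_deg, config.taper_deg
    w = np.zeros(len(d))
    w[theta <= t0] = 1.0
    ramp = (theta > t0) & (theta < t1)
    w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (theta[ramp] - t0) / (t1 - t0)))
    return w


def effect_direction_indices(config: CohortConfig, directions: np.ndarray) -> np.ndarray:
    """Indices of directions carrying the full (plateau) deformation amplitude."""
    return np.flatnonzero(bump_weight(directions, config) >= 1.0)


def _noise_basis(directions: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Smooth cap basis, row-normalised so iid N(0,1) coefficients give unit
    marginal variance at every direction."""
    from .radial import make_directions

    centers = make_directions(max(config.noise_n_basis, 12)).directions
    d = np.atleast_2d(directions)
    ang = np.arccos(np.clip(d @ centers.T, -1.0, 1.0))
    B = np.exp(-0.5 * (ang / config.noise_width_rad) ** 2)
    norms = np.sqrt((B**2).sum(axis=1, keepdims=True))
    return B / norms


def _subject_rng(config: CohortConfig, subject_id: str, side: str) -> np.random.Generator:
    h = hashlib.sha256(f"{subject_id}|{side}".encode()).digest()
    key = int.from_bytes(h[:4], "big") % (2**31)
    return np.random.default_rng([config.seed, key, 0x3A5E])


def surface_radius(
    directions: np.ndarray,
    record: SubjectRecord,
    config: CohortConfig,
    side: str = "left",
    noise_coeffs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Ground-truth continuous radius (mm) of a subject's surface.

    The deformation couples to ``config.coupled_scale`` only on
    ``config.effect_side``; pass ``noise_coeffs=None`` to draw the subject's
    own reproducible noise field, or a zero array for the noiseless shape.
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    r = base_radius(d, config)
    if side == config.effect_side and config.beta_true > 0:
        score = getattr(record, config.coupled_scale)
        if score is None:
            raise ValueError(f"coupled scale {config.coupled_scale!r} missing "
                             f"for {record.subject_id}")
        r = r + config.beta_true * float(score) * bump_weight(d, config)
    if config.noise_sd > 0:
        if noise_coeffs is None:
            rng = _subject_rng(config, record.subject_id, side)
            noise_coeffs = rng.standard_normal(max(config.noise_n_basis, 12))
        r = r + config.noise_sd * (_noise_basis(d, config) @ noise_coeffs)
    return r


def continuous_radii_about(
    point: np.ndarray,
    directions: np.ndarray,
    record: SubjectRecord,
    config: CohortConfig,
    side: str = "left",
    noise_coeffs: Optional[np.ndarray] = None,
    n_bisect: int = 60,
) -> np.ndarray:
    """Exact radii of the continuous star body about an interior ``point``.

    Solves ``|q + t d| = r(unit(q + t d))`` for each direction by bisection on
    the closed-form radial function, giving the ground truth the discrete
    pipeline (which measures from the mesh COI) can be compared against.
    """
    q = np.asarray(point, dtype=float)
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if config.noise_sd > 0 and noise_coeffs is None:
        noise_coeffs = _subject_rng(config, record.subject_id, side).standard_normal(
            max(config.noise_n_basis, 12)
        )

    def f(t: np.ndarray) -> np.ndarray:
        p = q + t[:, None] * d
        dist = np.linalg.norm(p, axis=1)
        u = p / np.where(dist > 0, dist, 1.0)[:, None]
        return dist - surface_radius(u, record, config, side, noise_coeffs)

    hi_val = max(config.base_axes) * 2.0 + np.linalg.norm(q) + 10.0
    lo = np.zeros(len(d))
    hi = np.full(len(d), hi_val)
    if np.any(f(hi) <= 0):
        raise ValueError("bisection bracket too small: point outside the body?")
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        inside = f(mid) < 0
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    return 0.5 * (lo + hi)


def _check_star_shaped(config: CohortConfig, record: SubjectRecord, side: str,
                       noise_coeffs: Optional[np.ndarray]) -> None:
    """Numeric star-shapedness check w.r.t. the shape's own centroid.

    Triangulates the continuous surface on a direction lattice and casts rays
    from the estimated solid centroid; more than one forward crossing along
    any direction means some surface patch occludes another.
    """
    from .radial import make_directions, ray_cast
    from .stats import _hull_faces

    dirs = make_directions(1000).directions
    r = surface_radius(dirs, record, config, side, noise_coeffs)
    if np.any(r <= 0.5 * config.voxel_size):
        raise ValueError(
            f"{record.subject_id}/{side}: radial function collapses below half a "
            "voxel; deformation amplitude or noise too large for the base shape"
        )
    pts = r[:, None] * dirs
    # solid centroid of a star body from its radial function
    c = 0.75 * (r[:, None] ** 4 * dirs).sum(0) / (r**3).sum()
    faces = _hull_faces(dirs)
    dist, n_hits = ray_cast(pts, faces, dirs, origin=c)
    if np.any(n_hits != 1) or np.any(~np.isfinite(dist)):
        bad = int(np.flatnonzero((n_hits != 1) | ~np.isfinite(dist))[0])
        raise ValueError(
            f"{record.subject_id}/{side}: surface is not star-shaped w.r.t. its "
            f"centroid (direction index {bad}); reduce beta_true or noise_sd"
        )


def generate_mask(
    record: SubjectRecord,
    config: CohortConfig,
    side: str = "left",
) -> "BinaryVolume":
    """Rasterize the subject's continuous radial surface to a binary volume.

    Voxels are foreground when their centre lies inside the star body
    ``{t * d : 0 <= t <= r(d)}``.  The returned affine maps voxel indices to
    world mm with the shape centred at the world origin.
    """
    from .surface import BinaryVolume

    config.validate()
    noise_coeffs = None
    if config.noise_sd > 0:
        rng = _subject_rng(config, record.subject_id, side)
        noise_coeffs = rng.standard_normal(max(config.noise_n_basis, 12))

    score = getattr(record, config.coupled_scale, 0) or 0
    amp = config.beta_true * float(score) if side == config.effect_side else 0.0
    if amp > 0.25 * min(config.base_axes):
        _check_star_shaped(config, record, side, noise_coeffs)

    vs = config.voxel_size
    margin = amp + 5.0 * config.noise_sd + 2.0 * vs
    skew_pad = 1.0 + sum(abs(s) for s in config.base_skew)
    halves = [int(np.ceil((a * skew_pad + margin) / vs)) for a in config.base_axes]
    axes_coords = [(np.arange(2 * h + 1) - h) * vs for h in halves]
    xg, yg, zg = np.meshgrid(*axes_coords, indexing="ij")
    pts = np.column_stack([xg.ravel(), yg.ravel(), zg.ravel()])
    dist = np.linalg.norm(pts, axis=1)

    # bound the surface radius on a coarse lattice, then evaluate the exact
    # radial function only on the shell of undecided voxels
    from .radial import make_directions

    probe = make_directions(1000).directions
    r_probe = surface_radius(probe, record, config, side, noise_coeffs)
    if np.any(r_probe <= 0.5 * vs):
        raise ValueError(
            f"{record.subject_id}/{side}: radial function collapses below half a voxel"
        )
    pad = 1.0 + vs  # covers radial variation between probe directions
    r_lo, r_hi = r_probe.min() - pad, r_probe.max() + pad
    inside = dist < r_lo
    shell = (dist >= r_lo) & (dist <= r_hi) & (dist > 0)
    dirs = pts[shell] / dist[shell, None]
    r = surface_radius(dirs, record, config, side, noise_coeffs)
    inside[shell] = dist[shell] <= r
    grid = inside.reshape(xg.shape).astype(np.uint8)

    labels, n_comp = ndimage.label(grid)
    if n_comp > 1:  # vanishingly rare; keep the dominant body
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n_comp + 1))
        grid = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
        warnings.warn(
            f"{record.subject_id}/{side}: rasterization produced {n_comp} "
            "components; kept the largest"
        )
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = [-h * vs for h in halves]
    return BinaryVolume(grid=grid, affine=affine, side=side)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "subject_id", "age", "etiv",
    *POMS_SUBSCALE_MAX, "poms_tmd", "pcss_total", "concussion_count",
]


def subject_table_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records (follow-up subscales as ``followup_*`` columns)."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _CSV_COLUMNS}
        if r.followup_poms is not None:
            for k, v in r.followup_poms.items():
                row[f"followup_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_subject_table(df: pd.DataFrame) -> List[SubjectRecord]:
    records = []
    fu_cols = [c for c in df.columns if c.startswith("followup_")]
    for _, row in df.iterrows():
        followup = None
        if fu_cols and not any(pd.isna(row[c]) for c in fu_cols):
            followup = {c[len("followup_"):]: int(row[c]) for c in fu_cols}
        pcss = row["pcss_total"]
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=int(row["age"]),
                etiv=float(row["etiv"]),
                **{k: int(row[k]) for k in POMS_SUBSCALE_MAX},
                poms_tmd=int(row["poms_tmd"]),
                pcss_total=None if pd.isna(pcss) else int(pcss),
                concussion_count=int(row["concussion_count"]),
                followup_poms=followup,
            )
        )
    return records
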