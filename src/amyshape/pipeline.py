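"""End-to-end orchestration: masks + subject table -> vertex statistics.

The per-hemisphere chain is extract -> smooth -> PCA align -> radial sampling
-> group template -> ICP -> (optional) atlas mapping -> vertex-wise GLM with
FDR and cluster-extent filtering -> cluster-level adjusted-mean regression.
`run_cohort_analysis` does this in memory (used by the calibration studies);
`run_pipeline` is the file-based driver behind the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__
from .atlas import SubregionAtlas, SurfaceSubregionMap, map_subregions, template_subregion_map
from .cohort import SubjectRecord, POMS_SUBSCALE_MAX
from .radial import DirectionSet, RadialShape, compute_radii, make_directions, pca_align
from .registration import ShapeTemplate, build_template, register_to_template
from .stats import (
    ClusterResult,
    VertexStats,
    build_adjacency,
    cluster_adjusted_regression,
    find_clusters,
    mann_whitney_u,
    paired_mixed_model,
    pearson_matrix,
    vertexwise_glm,
    volume_regression,
)
from .surface import BinaryVolume, extract_surface, mask_volume_mm3, smooth_surface

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(POMS_SUBSCALE_MAX) + ("poms_tmd", "pcss_total")


@dataclass
class RunConfig:
    """Paths and analysis settings for a pipeline run."""

    masks_dir: Optional[str] = None
    subject_csv: Optional[str] = None
    atlas_dir: Optional[str] = None
    affine_dir: Optional[str] = None
    output_dir: str = "amyshape_output"
    n_directions: int = 1000
    smooth_iterations: int = 10
    smooth_lambda: float = 0.5
    alpha: float = 0.05
    extent_min: int = 15
    seed: int = 0
    sides: Tuple[str, ...] = ("left", "right")
    scales: Tuple[str, ...] = DEFAULT_SCALES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sides", "scales"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class HemisphereResult:
    """Everything computed for one hemisphere of one cohort."""

    side: str
    template: ShapeTemplate
    registered: List[RadialShape]
    radii_matrix: np.ndarray  # subjects x points, post-ICP, mm
    volumes_mm3: np.ndarray
    subregion_maps: Optional[List[SurfaceSubregionMap]] = None
    template_map: Optional[SurfaceSubregionMap] = None
    vertex_stats: Dict[str, VertexStats] = field(default_factory=dict)
    clusters: Dict[str, List[ClusterResult]] = field(default_factory=dict)


def parameterize_hemisphere(
    volume: BinaryVolume,
    directions: DirectionSet,
    subject_id: str = "",
    smooth_iterations: int = 10,
    smooth_lambda: float = 0.5,
) -> tuple[RadialShape, trimesh.Trimesh]:
    """Mask -> smoothed mesh -> PCA-aligned radial shape (plus aligned mesh)."""
    mesh = extract_surface(volume)
    mesh = smooth_surface(mesh, iterations=smooth_iterations, lam=smooth_lambda)
    aligned, T = pca_align(mesh)
    coi_world = np.linalg.inv(T)[:3, 3]
    shape = compute_radii(
        aligned, directions, subject_id=subject_id, side=volume.side,
        alignment=T, coi=coi_world,
    )
    return shape, aligned


def analyze_hemisphere(
    volumes: Sequence[BinaryVolume],
    records: Sequence[SubjectRecord],
    directions: DirectionSet,
    side: str,
    scales: Sequence[str] = ("poms_depression",),
    alpha: float = 0.05,
    extent_min: int = 15,
    atlas: Optional[SubregionAtlas] = None,
    native_to_atlas: Optional[Sequence[np.ndarray]] = None,
    smooth_iterations: int = 10,
    smooth_lambda: float = 0.5,
    adjacency=None,
) -> HemisphereResult:
    """The full shape-statistics chain for one hemisphere of a cohort."""
    if len(volumes) != len(records):
        raise ValueError("one mask per subject record is required")
    shapes, meshes = [], []
    for rec, vol in zip(records, volumes):
        shape, mesh = parameterize_hemisphere(
            vol, directions, subject_id=rec.subject_id,
            smooth_iterations=smooth_iterations, smooth_lambda=smooth_lambda,
        )
        shapes.append(shape)
        meshes.append(mesh)
    template = build_template(shapes, side, directions)
    registered = []
    for shape, mesh in zip(shapes, meshes):
        reg, info = register_to_template(mesh, shape, template)
        if not info.converged:
            logger.warning("ICP did not converge for %s/%s", shape.subject_id, side)
        registered.append(reg)
    result = HemisphereResult(
        side=side,
        template=template,
        registered=registered,
        radii_matrix=np.stack([s.radii for s in registered]),
        volumes_mm3=np.array([mask_volume_mm3(v) for v in volumes]),
    )

    if atlas is not None:
        mats = native_to_atlas if native_to_atlas is not None else [None] * len(registered)
        result.subregion_maps = [
            map_subregions(s, atlas, m) for s, m in zip(registered, mats)
        ]
        result.template_map = template_subregion_map(result.subregion_maps)

    if adjacency is None:
        adjacency = build_adjacency(directions)
    age = np.array([r.age for r in records], dtype=float)
    etiv = np.array([r.etiv for r in records], dtype=float)
    for scale in scales:
        values = np.array(
            [np.nan if getattr(r, scale) is None else getattr(r, scale) for r in records],
            dtype=float,
        )
        keep = np.isfinite(values)
        vs = vertexwise_glm(
            result.radii_matrix[keep], values[keep], age[keep], etiv[keep], scale=scale
        ).apply_fdr(alpha)
        result.vertex_stats[scale] = vs
        clusters = find_clusters(vs.significant, adjacency, extent_min)
        for cl in clusters:
            cluster_adjusted_regression(
                cl, result.radii_matrix[keep], values[keep], age[keep], etiv[keep]
            )
            if result.template_map is not None:
                labels = result.template_map.labels[cl.indices]
                named, counts = np.unique(labels, return_counts=True)
                top = int(np.argmax(counts))
                cl.dominant_subregion = str(named[top])
                cl.subregion_fraction = counts[top] / cl.size
        result.clusters[scale] = clusters
    return result


def run_cohort_analysis(
    records: Sequence[SubjectRecord],
    masks: Dict[str, Sequence[BinaryVolume]],
    config: RunConfig,
    atlas_by_side: Optional[Dict[str, SubregionAtlas]] = None,
) -> Dict[str, HemisphereResult]:
    """In-memory analysis of a cohort given per-side mask lists."""
    directions = make_directions(config.n_directions)
    adjacency = build_adjacency(directions)
    results = {}
    for side in config.sides:
        atlas = (atlas_by_side or {}).get(side)
        results[side] = analyze_hemisphere(
            masks[side], records, directions, side,
            scales=config.scales, alpha=config.alpha, extent_min=config.extent_min,
            atlas=atlas, smooth_iterations=config.smooth_iterations,
            smooth_lambda=config.smooth_lambda, adjacency=adjacency,
        )
    return results


def behavioural_statistics(records: Sequence[SubjectRecord]) -> dict:
    """Score-level analyses: correlations, group tests, follow-up stability."""
    from .cohort import subject_table_to_frame

    df = subject_table_to_frame(records)
    scale_cols = list(POMS_SUBSCALE_MAX) + ["poms_tmd", "pcss_total"]
    r, p, n = pearson_matrix(df[scale_cols])

    out = {"pearson_r": r, "pearson_p": p, "pearson_n": n}
    conc = df["concussion_count"] >= 1
    pcss = df["pcss_total"]
    if conc.any() and (~conc).any():
        a = pcss[conc].dropna().to_numpy()
        b = pcss[~conc].dropna().to_numpy()
        U, pu = mann_whitney_u(a, b)
        out["pcss_by_concussion"] = {"U": U, "p": pu, "n_concussed": len(a),
                                     "n_nonconcussed": len(b)}
    fu_records = [rec for rec in records if rec.followup_poms is not None]
    if len(fu_records) >= 2:
        stability = {}
        for scale in list(POMS_SUBSCALE_MAX) + ["poms_tmd"]:
            base = [getattr(rec, scale) for rec in fu_records]
            fu = [rec.followup_poms[scale] for rec in fu_records]
            effect, t, pval = paired_mixed_model(base, fu)
            stability[scale] = {"effect": effect, "t": t, "p": pval,
                                "n_pairs": len(fu_records)}
        out["followup_stability"] = stability
    return out


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: read masks and scores, write tables and a report.

    Re-running with an identical config reproduces identical outputs: every
    stage after data generation is deterministic.
    """
    from . import io as aio
    from .cohort import frame_to_subject_table

    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    caught: List[str] = []

    if config.subject_csv is None or config.masks_dir is None:
        raise ValueError("run_pipeline requires subject_csv and masks_dir")
    records = frame_to_subject_table(pd.read_csv(config.subject_csv))
    masks_dir = Path(config.masks_dir)
    masks: Dict[str, List[BinaryVolume]] = {}
    for side in config.sides:
        masks[side] = []
        for rec in records:
            path = masks_dir / f"{rec.subject_id}_{side}.nii.gz"
            if not path.exists():
                raise FileNotFoundError(f"stage extract, subject {rec.subject_id}: {path}")
            masks[side].append(aio.read_mask(path, side))

    atlas_by_side = None
    if config.atlas_dir is not None:
        atlas_by_side = {
            side: aio.read_atlas(config.atlas_dir, side) for side in config.sides
        }

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        results = run_cohort_analysis(records, masks, config, atlas_by_side)
        behaviour = behavioural_statistics(records)
    caught.extend(f"{w.category.__name__}: {w.message}" for w in wlist)

    # --- persist ---
    cluster_rows = []
    for side, res in results.items():
        aio.write_radial_shapes(res.registered, outdir / f"radii_{side}.csv")
        aio.write_template(res.template, outdir / f"template_{side}.csv")
        for scale, vs in res.vertex_stats.items():
            vs.to_frame().to_csv(outdir / f"vertexstats_{side}_{scale}.csv", index=False)
        for scale, clusters in res.clusters.items():
            for ci, cl in enumerate(clusters):
                cluster_rows.append(
                    {
                        "side": side, "scale": scale, "cluster": ci,
                        "size": cl.size, "beta": cl.beta, "t": cl.t, "p": cl.p,
                        "dominant_subregion": cl.dominant_subregion,
                        "subregion_fraction": cl.subregion_fraction,
                        "indices": " ".join(map(str, cl.indices)),
                    }
                )
    pd.DataFrame(
        cluster_rows,
        columns=["side", "scale", "cluster", "size", "beta", "t", "p",
                 "dominant_subregion", "subregion_fraction", "indices"],
    ).to_csv(outdir / "clusters.csv", index=False)
    behaviour["pearson_r"].to_csv(outdir / "correlations_r.csv")
    behaviour["pearson_p"].to_csv(outdir / "correlations_p.csv")

    report = {
        "software_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_subjects": len(records),
        "sides": list(config.sides),
        "n_directions": config.n_directions,
        "per_stage_counts": {
            side: {
                "subjects": len(res.registered),
                "points_per_subject": int(res.radii_matrix.shape[1]),
                "clusters": {s: len(c) for s, c in res.clusters.items()},
            }
            for side, res in results.items()
        },
        "defaults_in_force": {
            "smoothing": {"iterations": config.smooth_iterations,
                          "lambda": config.smooth_lambda},
            "alpha": config.alpha,
            "extent_min": config.extent_min,
            "coi": "unweighted vertex mean",
            "icp": "rigid, point-to-point, radii re-sampled after registration",
            "fdr_family": "one hemisphere x one scale",
        },
        "warnings": caught,
        "behavioural": {
            k: v for k, v in behaviour.items()
            if k in ("pcss_by_concussion", "followup_stability")
        },
        "runtime_s": round(time.time() - t0, 2),
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
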