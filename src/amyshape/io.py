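"""File formats: NIfTI masks and atlases, CSV/JSON shape tables, mesh export."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .atlas import SUBREGIONS, SubregionAtlas
from .radial import RadialShape
from .registration import ShapeTemplate
from .surface import BinaryVolume


def write_mask(volume: BinaryVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.grid.astype(np.uint8), volume.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, side: str) -> BinaryVolume:
    img = nib.load(str(path))
    grid = (np.asanyarray(img.dataobj) > 0.5).astype(np.uint8)
    return BinaryVolume(grid=grid, affine=img.affine, side=side)


def write_atlas(atlas: SubregionAtlas, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in SUBREGIONS:
        img = nib.Nifti1Image(atlas.probabilities[k].astype(np.float32), atlas.affine)
        nib.save(img, str(directory / f"{atlas.side}_{k}.nii.gz"))


def read_atlas(directory: str | Path, side: str) -> SubregionAtlas:
    directory = Path(directory)
    probs: Dict[str, np.ndarray] = {}
    affine = None
    for k in SUBREGIONS:
        img = nib.load(str(directory / f"{side}_{k}.nii.gz"))
        probs[k] = np.asanyarray(img.dataobj).astype(float)
        affine = img.affine
    return SubregionAtlas(probabilities=probs, affine=affine, side=side)


def write_affine(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(matrix, dtype=float), fmt="%.12g")


def read_affine(path: str | Path) -> np.ndarray:
    A = np.loadtxt(str(path))
    if A.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 affine, got {A.shape}")
    return A


def write_radial_shapes(shapes: Sequence[RadialShape], csv_path: str | Path) -> None:
    """Long-form radii CSV plus a JSON sidecar of COIs and transforms."""
    rows = []
    meta = {}
    for s in shapes:
        for j, r in enumerate(s.radii):
            rows.append((s.subject_id, s.side, j, r))
        meta[f"{s.subject_id}_{s.side}"] = {
            "coi_mm": list(map(float, s.coi)),
            "alignment": np.asarray(s.alignment).tolist(),
        }
    df = pd.DataFrame(rows, columns=["subject_id", "side", "direction_index", "radius_mm"])
    df.to_csv(csv_path, index=False)
    Path(str(csv_path)).with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_radial_shapes(csv_path: str | Path) -> List[RadialShape]:
    df = pd.read_csv(csv_path)
    sidecar = Path(str(csv_path)).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    shapes = []
    for (sid, side), grp in df.groupby(["subject_id", "side"], sort=False):
        grp = grp.sort_values("direction_index")
        m = meta.get(f"{sid}_{side}", {})
        shapes.append(
            RadialShape(
                subject_id=str(sid),
                side=str(side),
                coi=np.asarray(m.get("coi_mm", [0.0, 0.0, 0.0])),
                radii=grp["radius_mm"].to_numpy(),
                alignment=np.asarray(m.get("alignment", np.eye(4).tolist())),
            )
        )
    return shapes


def write_template(template: ShapeTemplate, csv_path: str | Path) -> None:
    pd.DataFrame(
        {
            "direction_index": np.arange(len(template.mean_radii)),
            "mean_radius_mm": template.mean_radii,
        }
    ).to_csv(csv_path, index=False)
    Path(str(csv_path)).with_suffix(".json").write_text(
        json.dumps({"side": template.side, "n_subjects": template.n_subjects,
                    "n_directions": len(template.directions)})
    )


def export_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """PLY (binary little-endian) or OBJ export, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() not in (".ply", ".obj"):
        raise ValueError("mesh export supports .ply and .obj")
    mesh.export(str(path))
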