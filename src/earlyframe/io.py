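"""Readers and writers for the package's on-disk formats.

Surface geometry and maps use GIFTI (via nibabel); volumes use NIfTI-1;
tables are CSV with a header; configs are YAML; patch definitions travel
in a JSON sidecar next to the surface file (documented fallback for label
files, since patches may overlap).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .mesh import Mesh

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_surface_map",
    "load_surface_map",
    "save_volume",
    "load_volume",
    "save_table",
    "load_table",
    "save_config",
    "load_config",
]


def save_mesh(mesh: Mesh, prefix: str | Path) -> list[Path]:
    """Write surf/shape GIFTI files plus a JSON patch sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    surf = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    surf_path = prefix.with_suffix(".surf.gii")
    nib.save(surf, surf_path)

    shape = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.thickness.astype(np.float32),
                                 intent="NIFTI_INTENT_SHAPE"),
        nib.gifti.GiftiDataArray(mesh.normals.astype(np.float32),
                                 intent="NIFTI_INTENT_VECTOR"),
    ])
    shape_path = prefix.with_suffix(".shape.gii")
    nib.save(shape, shape_path)

    patches = {name: np.flatnonzero(mask).tolist()
               for name, mask in mesh.patches.items()}
    patch_path = prefix.with_suffix(".patches.json")
    patch_path.write_text(json.dumps(patches))
    return [surf_path, shape_path, patch_path]


def load_mesh(prefix: str | Path) -> Mesh:
    prefix = Path(prefix)
    surf = nib.load(prefix.with_suffix(".surf.gii"))
    verts = surf.darrays[0].data.astype(float)
    faces = surf.darrays[1].data.astype(np.intp)
    shape = nib.load(prefix.with_suffix(".shape.gii"))
    thickness = shape.darrays[0].data.astype(float)
    normals = shape.darrays[1].data.astype(float)
    patches_raw = json.loads(prefix.with_suffix(".patches.json").read_text())
    patches = {}
    for name, idx in patches_raw.items():
        m = np.zeros(len(verts), dtype=bool)
        m[np.asarray(idx, dtype=int)] = True
        patches[name] = m
    return Mesh(verts, faces, normals, thickness, patches)


def save_surface_map(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                                 intent="NIFTI_INTENT_NONE"),
    ])
    nib.save(img, path)
    return path


def load_surface_map(path: str | Path) -> np.ndarray:
    return nib.load(Path(path)).darrays[0].data.astype(float)


def save_volume(volume: np.ndarray, voxel_mm: float, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), path)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(Path(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj, dtype=float), voxel


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
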