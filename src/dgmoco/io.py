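"""NIfTI / CSV / JSON / YAML readers and writers.

All volumes are written RAS with the voxel spacing on the affine diagonal;
world coordinates are mm, voxel indices 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = ["save_nifti", "load_nifti", "save_mask", "save_field",
           "load_field", "save_json", "load_json", "save_yaml", "load_yaml"]


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.broadcast_to(
        np.asarray(spacing_mm, dtype=float), (3,))
    return aff


def save_nifti(volume: np.ndarray, path, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(spacing_mm))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, path, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj).astype(float), spacing


def save_field(field_mm: np.ndarray, path, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    """Displacement field as 4D NIfTI, last axis = (x, y, z) components in mm."""
    img = nib.Nifti1Image(np.asarray(field_mm, dtype=np.float32), _affine(spacing_mm))
    nib.save(img, str(path))


def load_field(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(float)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2))


def load_json(path):
    return json.loads(Path(path).read_text())


def save_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
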