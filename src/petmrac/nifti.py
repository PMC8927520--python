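"""Thin NIfTI I/O helpers (nibabel) for volumes, masks and ROI label maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path, data: np.ndarray, spacing, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def save_rois(path_nii, path_json, rois: dict[str, np.ndarray], spacing) -> None:
    """ROIs as one labeled int16 volume plus a name -> label JSON table.

    Overlapping ROIs are written in sorted-name order (later wins).
    """
    names = sorted(rois)
    labels = np.zeros(next(iter(rois.values())).shape, dtype=np.int16)
    table = {}
    for i, name in enumerate(names, start=1):
        labels[np.asarray(rois[name], dtype=bool)] = i
        table[name] = i
    save_volume(path_nii, labels, spacing, dtype=np.int16)
    Path(path_json).write_text(json.dumps(table, indent=2, sort_keys=True))


def load_rois(path_nii, path_json) -> dict[str, np.ndarray]:
    labels, _ = load_volume(path_nii)
    table = json.loads(Path(path_json).read_text())
    return {name: labels == lab for name, lab in table.items()}
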