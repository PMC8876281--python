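"""Volume and table I/O.

Volumes use axis order ``(slice, row, col)`` with per-axis spacing in mm,
0-based voxel-center coordinates.  NIfTI files written here carry the spacing
in a diagonal affine; orientation metadata beyond spacing is not interpreted.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml


def save_volume(data: np.ndarray, spacing, path) -> None:
    """Write a 3D array as NIfTI (.nii or .nii.gz); integer dtypes are
    preserved as unsigned labels, floats as float32."""
    import nibabel as nib

    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    affine = np.diag([float(spacing[0]), float(spacing[1]), float(spacing[2]), 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, spacing in mm per axis)."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), (float(zooms[0]), float(zooms[1]), float(zooms[2]))


def load_png_slices(paths) -> np.ndarray:
    """Stack per-slice palette-indexed PNG label maps into a (S, R, C) array.

    Each file holds one axial slice; the palette index is the label value.
    """
    from PIL import Image

    slices = []
    for i, p in enumerate(paths):
        with Image.open(p) as im:
            if im.mode not in ("P", "L", "I", "I;16"):
                raise ValueError(f"slice {i} ({p}): expected indexed/grayscale PNG, got mode {im.mode}")
            arr = np.asarray(im)
        if slices and arr.shape != slices[0].shape:
            raise ValueError(f"slice {i} ({p}): shape {arr.shape} != {slices[0].shape}")
        slices.append(arr)
    if not slices:
        raise ValueError("no slices given")
    return np.stack(slices).astype(np.int64)


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
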