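"""NIfTI and tabular I/O plus YAML configuration round-tripping."""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .relaxometry import DIRSequenceParams, IRSequenceParams

__all__ = [
    "read_volume",
    "write_volume",
    "load_sequence_params",
    "save_yaml",
    "load_yaml",
]


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a 3D NIfTI volume; returns (data, voxel sizes in mm).

    4D or higher-dimensional inputs are an explicit error, never silently
    squeezed.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), voxel_size


def write_volume(volume: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a 3D array as NIfTI-1 with a diagonal affine from voxel sizes."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(voxel_size)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_sequence_params(path=None) -> tuple[IRSequenceParams, DIRSequenceParams]:
    """FLAIR/DIR timings from YAML, defaulting to the standard clinical set.

    Expected layout::

        flair: {tr: 15000, te: 90, ti: 3100}
        dir:   {tr: 15000, te: 100, ti_long: 3800, ti_short: 470}
    """
    from .relaxometry import DEFAULT_DIR, DEFAULT_FLAIR

    if path is None:
        return DEFAULT_FLAIR, DEFAULT_DIR
    cfg = load_yaml(path)
    f = {**asdict(DEFAULT_FLAIR), **cfg.get("flair", {})}
    d = {**asdict(DEFAULT_DIR), **cfg.get("dir", {})}
    return IRSequenceParams(**f), DIRSequenceParams(**d)


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=False)
    return path


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
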