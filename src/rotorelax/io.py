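"""NIfTI / text I/O helpers shared by the pipeline stages."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_motion",
    "load_motion",
    "save_censor",
    "load_censor",
]


def save_nifti(path, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size_mm[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_size_mm[:3]) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def save_motion(path, motion: np.ndarray) -> None:
    """Six whitespace-delimited columns, one row per frame."""
    np.savetxt(str(path), np.asarray(motion), fmt="%.8f")


def load_motion(path) -> np.ndarray:
    m = np.loadtxt(str(path), ndmin=2)
    if m.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {m.shape[1]}")
    return m


def save_censor(path, keep: np.ndarray) -> None:
    """One 0/1 flag per frame (1 = kept)."""
    np.savetxt(str(path), np.asarray(keep, dtype=int), fmt="%d")


def load_censor(path) -> np.ndarray:
    return np.loadtxt(str(path), dtype=int, ndmin=1).astype(bool)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
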