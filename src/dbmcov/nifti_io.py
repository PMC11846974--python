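"""NIfTI and tabular I/O for the pipeline.

NIfTI-1 (plain or gzipped) is the on-disk image standard; the affine of the
mask defines the analysis space and must match every image.  Component and
statistic maps computed on the masked voxel vector are written back into the
full grid through the recorded voxel index.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .prep import JacobianImage

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_mask",
    "vector_to_volume",
    "write_map",
    "scan_filename",
]


def scan_filename(subject_id: str, dpi: float) -> str:
    return f"{subject_id}_{int(dpi)}.nii.gz"


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    return nib.load(str(path))


def read_nifti(
    path,
    flavor: str = "relative",
    subject_id: str = "",
    dpi: float = np.nan,
    is_log: bool = True,
) -> JacobianImage:
    """Read one 3D (log-)Jacobian volume; errors on non-3D input."""
    img = _load(path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return JacobianImage(
        data=data,
        voxel_size_mm=voxel_size,
        flavor=flavor,
        subject_id=subject_id,
        dpi=dpi,
        is_log=is_log,
        affine=np.asarray(img.affine),
    )


def write_nifti(img, path) -> Path:
    """Write a JacobianImage or (array, affine) pair; round-trips exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(img, JacobianImage):
        data, affine = img.data, img.affine
    else:
        data, affine = img
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.asarray(affine)), str(path))
    return path


def read_mask(path, reference_affine: np.ndarray | None = None) -> np.ndarray:
    """Read the brain mask; errors if its affine disagrees with the reference."""
    img = _load(path)
    if reference_affine is not None and not np.allclose(
        img.affine, reference_affine, atol=1e-6
    ):
        raise ValueError(f"mask affine at {path} does not match the image affine")
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D")
    return data > 0.5


def vector_to_volume(
    values: np.ndarray, voxel_index: np.ndarray, grid_shape, fill: float = 0.0
) -> np.ndarray:
    """Scatter a masked voxel vector back into the full grid (row-major)."""
    vol = np.full(int(np.prod(grid_shape)), fill, dtype=float)
    vol[voxel_index] = values
    return vol.reshape(grid_shape)


def write_map(values, voxel_index, grid_shape, affine, path, fill: float = 0.0) -> Path:
    return write_nifti((vector_to_volume(values, voxel_index, grid_shape, fill), affine), path)
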