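"""Preprocessing of log-Jacobian volumes into an analysis-ready voxel x scan matrix.

Deformation-based morphometry produces one Jacobian-determinant volume per
subject-timepoint: the local volume expansion (>1) or contraction (<1) needed
to map that scan onto the study template.  For statistics the determinants are
log-transformed (so 0 means no change and contraction is negative) and blurred
with a small Gaussian kernel.  Two flavors exist: "relative" Jacobians encode
only the nonlinear deformations (used for longitudinal trajectory models) while
"absolute" Jacobians also carry the residual global scaling (used for the
cross-sectional covariance decomposition).

For the matrix decomposition the in-mask voxels of each scan are loaded as a
column, the sign is inverted so atrophy is positive, each voxel row is z-scored
across scans, and the whole matrix is shifted by a single scalar so its minimum
is zero (non-negativity for NMF without clipping).  All of these steps are
invertible and the offsets are recorded on the returned :class:`DataMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "JacobianImage",
    "DataMatrix",
    "log_transform",
    "gaussian_blur",
    "stack_images",
    "assemble_matrix",
    "FWHM_TO_SIGMA",
]

logger = logging.getLogger(__name__)

#: fwhm = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class JacobianImage:
    """One subject-timepoint Jacobian (or log-Jacobian) field on a voxel grid."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    flavor: str  # "relative" | "absolute"
    subject_id: str
    dpi: float
    is_log: bool = True
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.flavor not in ("relative", "absolute"):
            raise ValueError(f"unknown Jacobian flavor {self.flavor!r}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class DataMatrix:
    """Non-negative voxel x scan matrix ready for the covariance decomposition.

    ``values[i, j]`` is the shifted z-score of (optionally inverted) log-Jacobian
    at in-mask voxel ``voxel_index[i]`` for scan ``column_meta.iloc[j]``.
    ``row_mean``/``row_sd`` hold the per-voxel statistics removed by z-scoring
    and ``zshift`` the global non-negativity offset, so the blurred inverted
    log-Jacobians can be reconstructed exactly.
    """

    values: np.ndarray
    voxel_index: np.ndarray  # indices into the row-major flattened mask grid
    column_meta: pd.DataFrame  # one row per scan: subject_id, dpi, ...
    zshift: float
    inverted: bool
    zscored: bool
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    row_mean: np.ndarray | None = None
    row_sd: np.ndarray | None = None
    dropped_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    flavor: str = "absolute"

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_scans(self) -> int:
        return self.values.shape[1]

    def unshift(self) -> np.ndarray:
        """Undo the non-negativity shift (and z-scoring if applied).

        Returns the matrix of (inverted, if ``inverted``) blurred log-Jacobians.
        """
        out = self.values - self.zshift
        if self.zscored:
            out = out * self.row_sd[:, None] + self.row_mean[:, None]
        return out


def log_transform(img: JacobianImage) -> JacobianImage:
    """Natural-log transform a raw Jacobian-determinant volume.

    Raises if the image is already log-transformed or contains non-positive
    values (a Jacobian determinant of a diffeomorphism is strictly positive).
    """
    if img.is_log:
        raise ValueError("image is already log-transformed")
    bad = np.argwhere(img.data <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive Jacobian value {img.data[tuple(bad[0])]:g} "
            f"at voxel {tuple(int(i) for i in bad[0])}"
        )
    return replace(img, data=np.log(img.data), is_log=True)


def gaussian_blur(img: JacobianImage, fwhm_mm: float) -> JacobianImage:
    """Separable Gaussian smoothing with the kernel given as FWHM in mm.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel units.
    Reflective boundary handling conserves the volume mean.  A kernel narrower
    than 0.1 voxel is a no-op (warning logged): it would round to the identity.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in img.voxel_size_mm]
    if max(sigma_vox) * (2.0 / FWHM_TO_SIGMA) < 0.1:  # fwhm in voxels < 0.1
        logger.warning(
            "FWHM %.4g mm is below 0.1 voxel on every axis; returning input unchanged",
            fwhm_mm,
        )
        return img
    blurred = ndimage.gaussian_filter(img.data, sigma=sigma_vox, mode="reflect")
    return replace(img, data=blurred)


def _check_compatible(images: Sequence[JacobianImage]) -> None:
    first = images[0]
    flavors = {im.flavor for im in images}
    if len(flavors) > 1:
        raise ValueError(f"mixed Jacobian flavors in one matrix: {sorted(flavors)}")
    for im in images:
        if im.shape != first.shape:
            raise ValueError("images do not share a voxel grid")
        if not im.is_log:
            raise ValueError(f"image {im.subject_id}@{im.dpi} is not log-transformed")


def stack_images(
    images: Iterable[JacobianImage], mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack in-mask voxels of each image as columns.

    Returns ``(matrix, voxel_index, column_meta)`` where ``voxel_index`` are
    row-major flat indices of the mask's True voxels and ``column_meta`` has one
    row per image (subject_id, dpi, flavor).  Order of columns follows the
    input order.
    """
    images = list(images)
    if not images:
        raise ValueError("no images given")
    _check_compatible(images)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != images[0].shape:
        raise ValueError("mask grid does not match image grid")
    voxel_index = np.flatnonzero(mask.ravel(order="C"))
    cols = [im.data.ravel(order="C")[voxel_index] for im in images]
    matrix = np.column_stack(cols)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite values inside the mask")
    meta = pd.DataFrame(
        {
            "subject_id": [im.subject_id for im in images],
            "dpi": [im.dpi for im in images],
            "flavor": [im.flavor for im in images],
        }
    )
    return matrix, voxel_index, meta


def assemble_matrix(
    images: Iterable[JacobianImage],
    mask: np.ndarray,
    invert: bool = True,
    zscore: bool = True,
) -> DataMatrix:
    """Build the non-negative voxel x scan matrix for the decomposition.

    Steps: stack in-mask voxels as columns; multiply by -1 if ``invert`` (so
    contraction/atrophy becomes positive); z-score each voxel row across scans
    (rows with zero variance are dropped and counted); shift the whole matrix
    by its minimum so min(values) == 0.
    """
    images = list(images)
    matrix, voxel_index, meta = stack_images(images, mask)
    if matrix.shape[1] < 3:
        raise ValueError(f"need at least 3 scans, got {matrix.shape[1]}")
    if invert:
        matrix = -matrix
    dropped = np.array([], dtype=int)
    row_mean = row_sd = None
    if zscore:
        row_mean = matrix.mean(axis=1)
        row_sd = matrix.std(axis=1)  # population SD
        keep = row_sd > 0
        dropped = voxel_index[~keep]
        if dropped.size:
            logger.info("dropping %d zero-variance voxels", dropped.size)
        if not np.any(keep):
            raise ValueError("no variable voxels: all rows have zero variance")
        matrix = (matrix[keep] - row_mean[keep, None]) / row_sd[keep, None]
        voxel_index = voxel_index[keep]
        row_mean, row_sd = row_mean[keep], row_sd[keep]
    zshift = -float(matrix.min())
    matrix = matrix + zshift
    # guard against negative round-off at the minimum
    np.clip(matrix, 0.0, None, out=matrix)
    return DataMatrix(
        values=matrix,
        voxel_index=voxel_index,
        column_meta=meta,
        zshift=zshift,
        inverted=invert,
        zscored=zscore,
        grid_shape=images[0].shape,
        affine=np.asarray(images[0].affine),
        row_mean=row_mean,
        row_sd=row_sd,
        dropped_voxels=dropped,
        flavor=images[0].flavor,
    )
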