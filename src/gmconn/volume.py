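"""Gray-matter volume container and NIfTI I/O.

The pipeline consumes modulated, spatially normalized gray-matter maps:
3-D volumes whose voxel intensities encode local gray-matter volume after
warping to a standard (MNI-like) template frame.  Voxel values are
non-negative; background (non-brain) voxels are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["GrayMatterVolume", "load_volume", "save_volume"]


@dataclass
class GrayMatterVolume:
    """A single subject's modulated gray-matter map.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative gray-matter volume per voxel.
    affine : ndarray, shape (4, 4)
        Voxel-index → world (mm) transform.
    subject_id : str
        Identifier used in error messages and output file names.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"volume for {self.subject_id!r} must be 3-D, got {self.values.ndim}-D"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"volume for {self.subject_id!r} contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError(f"volume for {self.subject_id!r} contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the affine's linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


def load_volume(path: str | Path, subject_id: str | None = None) -> GrayMatterVolume:
    """Read a gray-matter map from a NIfTI file (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.load(str(path))
    sid = subject_id or path.name.removesuffix(".gz").removesuffix(".nii")
    return GrayMatterVolume(
        values=np.asarray(img.get_fdata(), dtype=float),
        affine=np.asarray(img.affine, dtype=float),
        subject_id=sid,
    )


def save_volume(volume: GrayMatterVolume, path: str | Path) -> Path:
    """Write a gray-matter map as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine)
    nib.save(img, str(path))
    return path
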