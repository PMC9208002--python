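"""In-memory container for one subject's masked fMRI data.

A :class:`MaskedDataset` holds the voxels-in-mask x time matrix for one
subject together with acquisition metadata (TR), six rigid-body motion
parameters, and phenotype fields used downstream by the group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class MaskedDataset:
    """One subject's voxels x time matrix inside a brain mask.

    ``data`` is stored as given; the decomposition stage expects per-voxel
    z-scored input, obtained with :meth:`zscore` (idempotent up to float
    error).  ``mask`` is a boolean 3-D array defining the voxel order
    (C-order scan of ``True`` entries) and ``affine`` the voxel-to-world
    transform used when writing NIfTI.
    """

    subject_id: str
    data: np.ndarray  # voxels x time
    tr_seconds: float
    mask: np.ndarray | None = None  # boolean 3-D grid
    affine: np.ndarray | None = None
    motion: np.ndarray | None = None  # time x 6 (3 translations mm, 3 rotations rad)
    site: str = "site0"
    diagnosis: str = "CT"  # CT or SZ
    sex: str = "male"
    age: float = 0.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be voxels x time")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite voxel values")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.data.shape[1], 6):
                raise ValueError("motion must be time x 6")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def zscore(self) -> "MaskedDataset":
        """Return a copy with each voxel time course z-scored (variance
        normalized); zero-variance voxels raise."""
        mu = self.data.mean(axis=1, keepdims=True)
        sd = self.data.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError(
                f"subject {self.subject_id}: {int((sd == 0).sum())} zero-variance voxels"
            )
        return replace(self, data=(self.data - mu) / sd)

    # -- I/O ---------------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        """Render the masked matrix back to a 4-D volume (zeros off-mask)."""
        if self.mask is None:
            raise ValueError("dataset has no mask; cannot render volumes")
        affine = self.affine if self.affine is not None else np.eye(4)
        vol = np.zeros(self.mask.shape + (self.n_timepoints,), dtype=np.float32)
        vol[self.mask, :] = self.data
        return nib.Nifti1Image(vol, affine)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write 4-D NIfTI, mask, and SPM-style rp_*.txt motion file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        img = self.to_nifti()
        paths["bold"] = directory / f"{self.subject_id}_bold.nii"
        img.to_filename(paths["bold"])
        affine = self.affine if self.affine is not None else np.eye(4)
        paths["mask"] = directory / f"{self.subject_id}_mask.nii"
        nib.Nifti1Image(self.mask.astype(np.uint8), affine).to_filename(paths["mask"])
        if self.motion is not None:
            paths["motion"] = directory / f"rp_{self.subject_id}.txt"
            np.savetxt(paths["motion"], self.motion, fmt="%.10e")
        return paths


def read_motion(path: str | Path) -> np.ndarray:
    """Read a 6-column whitespace-delimited motion parameter file."""
    motion = np.loadtxt(path)
    if motion.ndim == 1:
        motion = motion[None, :]
    if motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {motion.shape[1]}")
    return motion
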