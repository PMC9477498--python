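"""Voxel-matrix container for a cohort of co-registered 3D maps.

An :class:`ImageMatrix` holds one modality (grey-matter probability, "GMV",
or normalised glucose uptake, "FDG") for a whole cohort as a dense
``subjects x voxels`` matrix restricted to an in-brain mask, together with
the voxel->world affine needed to move between voxel indices and
millimetre coordinates.  NIfTI reading/writing goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = ["ImageMatrix"]


@dataclass
class ImageMatrix:
    """Subjects x voxels data matrix for one imaging modality.

    Parameters
    ----------
    values
        Array of shape ``(n_subjects, n_voxels)`` where columns follow the
        C-order enumeration of ``True`` voxels in ``mask``.
    affine
        4x4 voxel-to-world (mm) transform; must be invertible.
    mask
        3D boolean array marking in-brain voxels.
    modality
        ``"GMV"`` or ``"FDG"`` (free-form strings are allowed for tests).
    subject_ids
        Optional row labels, aligned with ``values``.
    """

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    modality: str = "GMV"
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D subjects x voxels array")
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} voxels"
            )
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.subject_ids and len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match values rows")

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    def voxel_indices(self) -> np.ndarray:
        """``(n_voxels, 3)`` integer indices of mask voxels, C order."""
        return np.argwhere(self.mask)

    def voxel_coordinates(self) -> np.ndarray:
        """World (mm) coordinates of the mask voxel centers."""
        return nib.affines.apply_affine(self.affine, self.voxel_indices())

    # ------------------------------------------------------------------
    def to_3d(self, row: np.ndarray) -> np.ndarray:
        """Scatter a length-``n_voxels`` vector back onto the 3D grid."""
        row = np.asarray(row, dtype=float)
        if row.shape != (self.n_voxels,):
            raise ValueError("row length does not match the mask")
        vol = np.zeros(self.mask.shape, dtype=float)
        vol[self.mask] = row
        return vol

    def columns_for(self, submask: np.ndarray) -> np.ndarray:
        """Column indices of ``values`` covered by a 3D boolean ``submask``.

        ``submask`` must be contained in the image mask.
        """
        submask = np.asarray(submask, dtype=bool)
        if submask.shape != self.mask.shape:
            raise ValueError("submask shape mismatch")
        if np.any(submask & ~self.mask):
            raise ValueError("submask is not contained in the image mask")
        flat = np.zeros(self.mask.shape, dtype=bool)
        flat[submask] = True
        return np.flatnonzero(flat[self.mask])

    def subset(self, rows: Sequence[int] | np.ndarray) -> "ImageMatrix":
        rows = np.asarray(rows)
        ids = [self.subject_ids[i] for i in rows] if self.subject_ids else []
        return ImageMatrix(
            values=self.values[rows],
            affine=self.affine,
            mask=self.mask,
            modality=self.modality,
            subject_ids=ids,
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_volumes(
        cls,
        volumes: Sequence[np.ndarray],
        affine: np.ndarray,
        mask: np.ndarray,
        modality: str = "GMV",
        subject_ids: Sequence[str] | None = None,
    ) -> "ImageMatrix":
        mask = np.asarray(mask, dtype=bool)
        values = np.stack([np.asarray(v, dtype=float)[mask] for v in volumes])
        return cls(values, np.asarray(affine), mask, modality,
                   list(subject_ids) if subject_ids is not None else [])

    def save_subject(self, row: int, path: str | Path) -> None:
        """Write one subject's map as a NIfTI-1 image."""
        img = nib.Nifti1Image(self.to_3d(self.values[row]), self.affine)
        nib.save(img, str(path))

    def save_map(self, vector_or_volume: np.ndarray, path: str | Path) -> None:
        """Write a statistic map (masked vector or full volume) as NIfTI."""
        arr = np.asarray(vector_or_volume, dtype=float)
        vol = self.to_3d(arr) if arr.ndim == 1 else arr
        nib.save(nib.Nifti1Image(vol, self.affine), str(path))

    @classmethod
    def from_nifti_files(
        cls,
        paths: Sequence[str | Path],
        mask: np.ndarray | None = None,
        modality: str = "GMV",
        subject_ids: Sequence[str] | None = None,
    ) -> "ImageMatrix":
        if not paths:
            raise ValueError("no input files")
        imgs = [nib.load(str(p)) for p in paths]
        affine = imgs[0].affine
        vols = [np.asarray(i.dataobj, dtype=float) for i in imgs]
        if mask is None:
            mask = np.ones(vols[0].shape, dtype=bool)
        ids = list(subject_ids) if subject_ids is not None else [
            Path(p).name.split(".")[0] for p in paths
        ]
        return cls.from_volumes(vols, affine, mask, modality, ids)
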