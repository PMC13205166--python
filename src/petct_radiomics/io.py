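"""NIfTI volume I/O, alignment validation, and in-plane resampling.

The only geometric preprocessing in the pipeline is a dataset-level resize
of rows and columns to the median in-plane grid observed across the cohort;
the slice count is never changed.  CT and PET are assumed co-registered
(hybrid-scanner acquisition), so one mask applies to both and all three
grids of a patient are resampled identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize

__all__ = ["VolumePair", "RoiMask", "read_patient", "median_grid", "resample_inplane"]


@dataclass
class VolumePair:
    """Co-registered CT and PET intensity grids for one patient.

    CT is on the scanner's 12-bit intensity scale [0, 4095]; PET is in SUV
    (dimensionless, nonnegative).  ``spacing_mm`` is the voxel size (dx, dy,
    dz) in millimetres.
    """

    ct: np.ndarray
    pet: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        self.pet = np.asarray(self.pet, dtype=float)
        if self.ct.ndim != 3 or self.pet.ndim != 3:
            raise ValueError("CT and PET must be 3D arrays")
        if self.ct.shape != self.pet.shape:
            raise ValueError(
                f"CT/PET alignment error: CT shape {self.ct.shape} "
                f"!= PET shape {self.pet.shape}"
            )
        if not (np.isfinite(self.ct).all() and np.isfinite(self.pet).all()):
            raise ValueError("volumes contain non-finite values")
        if (self.pet < 0).any():
            raise ValueError("PET volume contains negative SUV values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"invalid voxel spacing {self.spacing_mm}")
        self.spacing_mm = spacing


@dataclass
class RoiMask:
    """Binary tumor mask aligned to a :class:`VolumePair`."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.voxels = (vox != 0).astype(np.uint8)
        if not self.voxels.any():
            raise ValueError("mask is empty (no voxel set)")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _load(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def read_patient(ct_path, pet_path, mask_path, patient_id: str | None = None):
    """Load and validate one patient's CT/PET/mask NIfTI triplet.

    Returns ``(VolumePair, RoiMask)``.  Shapes and spacings must agree
    across the three files; the mask is binarized (any nonzero -> 1) and
    must be nonempty.
    """
    ct, sp_ct = _load(ct_path)
    pet, sp_pet = _load(pet_path)
    mask, sp_mask = _load(mask_path)
    for name, shape in (("PET", pet.shape), ("mask", mask.shape)):
        if shape != ct.shape:
            raise ValueError(
                f"alignment error: CT shape {ct.shape} != {name} shape {shape}"
            )
    for name, sp in (("PET", sp_pet), ("mask", sp_mask)):
        if not np.allclose(sp, sp_ct, rtol=1e-4, atol=1e-4):
            raise ValueError(
                f"alignment error: CT spacing {sp_ct} != {name} spacing {sp}"
            )
    if patient_id is None:
        patient_id = Path(str(ct_path)).name.split(".")[0]
    pair = VolumePair(ct=ct, pet=pet, spacing_mm=sp_ct, patient_id=patient_id)
    return pair, RoiMask(voxels=mask)


def median_grid(shapes: list[tuple[int, int]]) -> tuple[int, int]:
    """Component-wise median in-plane grid over the dataset.

    For an even count the lower of the two middle values is taken, so the
    result is always one of the observed sizes.
    """
    if not shapes:
        raise ValueError("cannot take the median grid of an empty list")
    rows = sorted(int(s[0]) for s in shapes)
    cols = sorted(int(s[1]) for s in shapes)
    mid = (len(shapes) - 1) // 2
    return rows[mid], cols[mid]


def _resize_slices(vol: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    rows, cols = target
    out = np.empty((rows, cols, vol.shape[2]), dtype=float)
    for z in range(vol.shape[2]):
        out[:, :, z] = resize(
            vol[:, :, z],
            (rows, cols),
            order=order,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return out


def resample_inplane(pair: VolumePair, mask: RoiMask, target: tuple[int, int]):
    """Resample rows/columns of CT, PET and mask to ``target``; slices kept.

    Intensities use bilinear interpolation, the mask nearest-neighbor (then
    re-binarized); in-plane spacing is rescaled by the size ratio.  Returns
    a new ``(VolumePair, RoiMask)``.
    """
    rows, cols = int(target[0]), int(target[1])
    if rows < 2 or cols < 2:
        raise ValueError(f"target grid must be at least 2x2, got {target}")
    src_rows, src_cols, _ = pair.ct.shape
    if (src_rows, src_cols) == (rows, cols):
        new_pair = VolumePair(
            ct=pair.ct.copy(),
            pet=pair.pet.copy(),
            spacing_mm=pair.spacing_mm,
            patient_id=pair.patient_id,
        )
        return new_pair, RoiMask(voxels=mask.voxels.copy())
    ct = _resize_slices(pair.ct, (rows, cols), order=1)
    pet = np.clip(_resize_slices(pair.pet, (rows, cols), order=1), 0.0, None)
    m = _resize_slices(mask.voxels.astype(float), (rows, cols), order=0) > 0.5
    dx, dy, dz = pair.spacing_mm
    spacing = (dx * src_rows / rows, dy * src_cols / cols, dz)
    new_pair = VolumePair(
        ct=ct, pet=pet, spacing_mm=spacing, patient_id=pair.patient_id
    )
    return new_pair, RoiMask(voxels=m)
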