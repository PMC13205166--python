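"""Semiquantitative PET metrics inside the tumor mask.

SUVmax is the maximum SUV over the masked voxels.  The metabolic tumor
volume (MTV) is the volume of masked voxels with uptake at or above a
fraction (default 40%) of SUVmax, in cm^3.  Total lesion glycolysis (TLG)
is SUVmean over the MTV voxel set times MTV.  The threshold comparison is
inclusive (>=), so a single-voxel mask always has MTV equal to one voxel
volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PetMetrics", "suvmax", "mtv", "tlg", "compute_metrics"]


@dataclass(frozen=True)
class PetMetrics:
    suvmax: float
    mtv_cc: float
    tlg: float


def _masked(pet, mask) -> np.ndarray:
    mask = np.asarray(getattr(mask, "voxels", mask)).astype(bool)
    pet = np.asarray(pet, dtype=float)
    if pet.shape != mask.shape:
        raise ValueError(f"PET shape {pet.shape} != mask shape {mask.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    return pet[mask]


def _voxel_cc(spacing_mm) -> float:
    dx, dy, dz = (float(s) for s in spacing_mm)
    return dx * dy * dz / 1000.0


def suvmax(pet, mask) -> float:
    """Maximum SUV over the masked voxels."""
    return float(_masked(pet, mask).max())


def mtv(pet, mask, spacing_mm, threshold_frac: float = 0.40) -> float:
    """Metabolic tumor volume (cm^3) at a fractional SUVmax threshold."""
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    x = _masked(pet, mask)
    thr = threshold_frac * x.max()
    return float((x >= thr).sum()) * _voxel_cc(spacing_mm)


def tlg(pet, mask, spacing_mm, threshold_frac: float = 0.40) -> float:
    """Total lesion glycolysis: SUVmean over the MTV voxel set times MTV."""
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    x = _masked(pet, mask)
    thr = threshold_frac * x.max()
    sel = x[x >= thr]
    mtv_cc = float(sel.size) * _voxel_cc(spacing_mm)
    return float(sel.mean()) * mtv_cc


def compute_metrics(pet, mask, spacing_mm, threshold_frac: float = 0.40) -> PetMetrics:
    """All three PET metrics in one pass."""
    return PetMetrics(
        suvmax=suvmax(pet, mask),
        mtv_cc=mtv(pet, mask, spacing_mm, threshold_frac),
        tlg=tlg(pet, mask, spacing_mm, threshold_frac),
    )
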