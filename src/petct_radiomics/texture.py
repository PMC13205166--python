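"""Radiomic texture features from a masked 3D volume.

Three feature families are extracted per imaging modality:

* 12 first-order statistics of the intensity histogram inside the ROI,
* 182 gray-level co-occurrence (GLCM) features: 14 Haralick statistics for
  each of the 13 unique symmetric voxel offsets of the 26-neighborhood
  (offsets d and -d contribute to the same symmetric matrix),
* 48 LBP-TOP features: a 16-bin local-binary-pattern code histogram
  (P = 4 axis-aligned neighbors, R = 1) on each of the three orthogonal
  plane families (xy, xz, yz) of the volume stack.

Co-occurrence is accumulated globally over the ROI: for each offset, every
voxel pair with both ends inside the mask contributes one count.  Gray
levels are obtained by equal-width quantization of the ROI intensity range.

Statistics that are analytically forced for a degenerate (constant) region
are returned as their limits (skewness, kurtosis, entropy -> 0); statistics
that are genuinely undefined (e.g. GLCM correlation when a marginal variance
is zero, or an offset with no valid voxel pair) are returned as NaN and are
expected to be handled by downstream imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantizedRoi",
    "first_order",
    "quantize",
    "glcm_features",
    "glcm_pair_counts",
    "lbp_top_features",
    "extract_all",
    "feature_names",
    "FIRST_ORDER_NAMES",
    "GLCM_OFFSETS",
    "HARALICK_NAMES",
    "LBP_PLANES",
]

FIRST_ORDER_NAMES = (
    "mean",
    "median",
    "variance",
    "skewness",
    "kurtosis",
    "minimum",
    "maximum",
    "range",
    "energy",
    "entropy",
    "p10",
    "p90",
)

#: the 13 unique symmetric offsets of the 26-neighborhood (d and -d pooled),
#: ordered axis offsets first, then face diagonals, then space diagonals.
GLCM_OFFSETS = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "diff_variance",
    "diff_entropy",
    "imc1",
    "imc2",
    "mcc",
)

#: plane name -> the two volume axes spanning it (row axis, col axis)
LBP_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}

_ENTROPY_BINS = 64


@dataclass(frozen=True)
class QuantizedRoi:
    """Gray-level indices on {0..ng-1} for a quantized ROI.

    ``levels`` covers the full grid (values outside the mask are clipped into
    range but carry no meaning); ``mask`` marks the ROI voxels.
    """

    levels: np.ndarray
    mask: np.ndarray
    ng: int


def _check_mask(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    volume = np.asarray(volume)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def first_order(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """12 first-order statistics of the masked intensity distribution.

    Variance is the population variance; kurtosis is Fisher (excess);
    entropy is Shannon entropy (base 2) of a 64-bin histogram over the ROI
    min-max range.  For a constant region skewness, kurtosis and entropy
    are defined as 0.
    """
    mask = _check_mask(volume, mask)
    x = np.asarray(volume, dtype=float)[mask]
    mu = float(x.mean())
    var = float(x.var())
    lo = float(x.min())
    hi = float(x.max())
    if var > 0.0:
        z = (x - mu) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
        counts, _ = np.histogram(x, bins=_ENTROPY_BINS, range=(lo, hi))
        p = counts[counts > 0] / x.size
        ent = float(-(p * np.log2(p)).sum())
    else:
        skew = kurt = ent = 0.0
    return {
        "mean": mu,
        "median": float(np.median(x)),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "minimum": lo,
        "maximum": hi,
        "range": hi - lo,
        "energy": float(np.sum(x.astype(float) ** 2)),
        "entropy": ent,
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


def quantize(volume: np.ndarray, mask: np.ndarray, ng: int = 32) -> QuantizedRoi:
    """Equal-width quantization of the ROI intensity range into ``ng`` levels.

    The ROI minimum maps to level 0 and the ROI maximum to level ``ng - 1``;
    a constant region maps entirely to level 0.
    """
    mask = _check_mask(volume, mask)
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")
    vol = np.asarray(volume, dtype=float)
    lo = vol[mask].min()
    hi = vol[mask].max()
    if hi > lo:
        width = (hi - lo) / ng
        levels = np.floor((vol - lo) / width).astype(np.int64)
    else:
        levels = np.zeros(vol.shape, dtype=np.int64)
    np.clip(levels, 0, ng - 1, out=levels)
    return QuantizedRoi(levels=levels, mask=mask, ng=ng)


def _offset_slices(offset: tuple[int, int, int]) -> tuple[tuple, tuple]:
    """Slices (anchor, shifted) such that anchor + offset = shifted, in-bounds."""
    a, b = [], []
    for d in offset:
        if d == 0:
            a.append(slice(None))
            b.append(slice(None))
        elif d > 0:
            a.append(slice(None, -d))
            b.append(slice(d, None))
        else:
            a.append(slice(-d, None))
            b.append(slice(None, d))
    return tuple(a), tuple(b)


def glcm_pair_counts(qroi: QuantizedRoi, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset, both voxels in-mask.

    Each ordered pair (v, v + offset) contributes one count at (level(v),
    level(v+offset)) and one at the transposed cell, so the returned matrix
    equals the count matrix of the pooled +-offset direction pair.
    """
    sa, sb = _offset_slices(offset)
    valid = qroi.mask[sa] & qroi.mask[sb]
    i = qroi.levels[sa][valid]
    j = qroi.levels[sb][valid]
    ng = qroi.ng
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
    return counts + counts.T


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _haralick(p: np.ndarray) -> dict[str, float]:
    """The 14 Haralick statistics of a normalized symmetric GLCM."""
    ng = p.shape[0]
    idx = np.arange(ng, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    i = idx[:, None]
    j = idx[None, :]

    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    var_x = float(((idx - mu_x) ** 2 * px).sum())
    var_y = float(((idx - mu_y) ** 2 * py).sum())

    asm = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i * j * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = np.nan
    variance = float(((i - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())

    # distributions of i+j (0 .. 2ng-2) and |i-j| (0 .. ng-1)
    ii, jj = np.meshgrid(np.arange(ng), np.arange(ng), indexing="ij")
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)
    ks = np.arange(2 * ng - 1, dtype=float)
    kd = np.arange(ng, dtype=float)

    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = float(-_xlog2(p_sum).sum())
    entropy = float(-_xlog2(p).sum())
    mu_d = float((kd * p_diff).sum())
    diff_variance = float(((kd - mu_d) ** 2 * p_diff).sum())
    diff_entropy = float(-_xlog2(p_diff).sum())

    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = px[:, None] * py[None, :]
    marg_nz = pxy > 0
    hxy1 = float(-(p[marg_nz] * np.log2(pxy[marg_nz])).sum())
    hxy2 = float(-(pxy[marg_nz] * np.log2(pxy[marg_nz])).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else np.nan
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    support = px > 0
    if support.sum() >= 2:
        ps = p[np.ix_(support, support)]
        pxs = px[support]
        pys = py[support]
        q = (ps[:, None, :] * ps[None, :, :] / (pxs[:, None, None] * pys[None, None, :])).sum(
            axis=2
        )
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0)))
    else:
        mcc = np.nan

    return {
        "asm": asm,
        "contrast": contrast,
        "correlation": correlation,
        "variance": variance,
        "idm": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "diff_variance": diff_variance,
        "diff_entropy": diff_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "mcc": mcc,
    }


def glcm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """13 directions x 14 Haralick statistics = 182 GLCM features.

    A direction with no valid in-mask voxel pair yields NaN for its 14
    statistics.
    """
    if not qroi.mask.any():
        raise ValueError("mask is empty")
    out: dict[str, float] = {}
    for d, offset in enumerate(GLCM_OFFSETS):
        counts = glcm_pair_counts(qroi, offset)
        total = counts.sum()
        prefix = f"glcm_d{d:02d}_"
        if total == 0:
            for name in HARALICK_NAMES:
                out[prefix + name] = np.nan
            continue
        stats = _haralick(counts / total)
        for name in HARALICK_NAMES:
            out[prefix + name] = stats[name]
    return out


def lbp_top_features(volume: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """LBP code histograms on three orthogonal planes (3 x 16 = 48 features).

    Per masked voxel and plane, a 4-bit code compares the four axis-aligned
    in-plane neighbors at distance 1 to the center (neighbor >= center sets
    the bit; bit order +row, +col, -row, -col within the plane).  Voxels whose
    four neighbors are not all inside the grid are skipped.  Each plane's
    16-bin code histogram is normalized to sum 1.
    """
    mask = _check_mask(volume, mask)
    vol = np.asarray(volume, dtype=float)
    out: dict[str, float] = {}
    degenerate = []
    for plane, (ax_r, ax_c) in LBP_PLANES.items():
        interior = np.ones(vol.shape, dtype=bool)
        for ax in (ax_r, ax_c):
            sl = [slice(None)] * 3
            sl[ax] = 0
            interior[tuple(sl)] = False
            sl[ax] = vol.shape[ax] - 1
            interior[tuple(sl)] = False
        sel = mask & interior
        if not sel.any():
            for b in range(16):
                out[f"lbp_{plane}_b{b:02d}"] = np.nan
            degenerate.append(plane)
            continue
        codes = np.zeros(vol.shape, dtype=np.int64)
        for bit, (dr, dc) in enumerate(((1, 0), (0, 1), (-1, 0), (0, -1))):
            offset = [0, 0, 0]
            offset[ax_r] = dr
            offset[ax_c] = dc
            neighbor = np.roll(vol, shift=(-offset[0], -offset[1], -offset[2]), axis=(0, 1, 2))
            codes += (neighbor >= vol).astype(np.int64) << bit
        hist = np.bincount(codes[sel], minlength=16).astype(float)
        hist /= hist.sum()
        for b in range(16):
            out[f"lbp_{plane}_b{b:02d}"] = float(hist[b])
    if degenerate:
        warnings.warn(
            "LBP-TOP: no interior ROI voxels for plane(s) "
            + ", ".join(degenerate)
            + "; features set to NaN",
            stacklevel=2,
        )
    return out


def _family_features(volume: np.ndarray, mask: np.ndarray, ng: int) -> dict[str, float]:
    feats: dict[str, float] = {}
    for name, value in first_order(volume, mask).items():
        feats[f"fo_{name}"] = value
    feats.update(glcm_features(quantize(volume, mask, ng=ng)))
    feats.update(lbp_top_features(volume, mask))
    return feats


def feature_names(modality: str | None = None) -> list[str]:
    """The stable per-modality feature-name registry (242 names).

    With ``modality`` given, names are prefixed ``CT_`` / ``PET_``.
    """
    names = [f"fo_{n}" for n in FIRST_ORDER_NAMES]
    names += [
        f"glcm_d{d:02d}_{s}" for d in range(len(GLCM_OFFSETS)) for s in HARALICK_NAMES
    ]
    names += [f"lbp_{plane}_b{b:02d}" for plane in LBP_PLANES for b in range(16)]
    if modality is not None:
        names = [f"{modality}_{n}" for n in names]
    return names


def extract_all(pair, mask, ng: int = 32) -> pd.Series:
    """Extract all 2 x 242 radiomic features of a patient.

    Parameters
    ----------
    pair : VolumePair
        Co-registered CT and PET grids.
    mask : RoiMask or ndarray
        Binary tumor mask aligned to the volumes.
    ng : int
        Gray-level count for GLCM quantization.

    Returns
    -------
    pandas.Series
        484 features named ``CT_*`` then ``PET_*`` in registry order.
    """
    mask_arr = getattr(mask, "voxels", mask)
    values: dict[str, float] = {}
    for modality, vol in (("CT", pair.ct), ("PET", pair.pet)):
        for name, value in _family_features(vol, mask_arr, ng=ng).items():
            values[f"{modality}_{name}"] = value
    order = feature_names("CT") + feature_names("PET")
    return pd.Series([values[n] for n in order], index=order, dtype=float)
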