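"""PET radiomics on SUV volumes with VOI masks.

Implements the preprocessing used throughout the pipeline — resampling to
2 mm isotropic voxels with B-spline interpolation and fixed-bin-width
discretization at 0.3 SUV — plus conventional SUV metrics (SUVmin/max/mean/
peak, PSMA-TV, TL-PSMA), an IBSI-convention first-order feature set and a
gray-level co-occurrence (GLCM) feature set (distance 1, 13 unique 3D
directions, symmetric matrices, features averaged over directions).

A pluggable hook (`register_full_set_extractor`) lets an external
IBSI-compliant engine supply the complete texture-family catalog behind the
same ``rad::<family>::<name>`` column contract; the in-repo extractor covers
the result-critical features (first-order Maximum, GLCM Joint Energy, SUV
metrics) independently.

Arrays are indexed (z, y, x); `spacing` is mm per axis in the same order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "SuvVolume",
    "VoiMask",
    "resample_isotropic",
    "suv_metrics",
    "discretize_fixed_bin_width",
    "glcm_features",
    "first_order_features",
    "extract_features",
    "register_full_set_extractor",
]


@dataclass
class SuvVolume:
    """Body-weight-normalized SUV grid with voxel spacing in mm (z, y, x)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("SUV volume must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SUV volume contains non-finite values")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0  # mm^3 -> ml


@dataclass
class VoiMask:
    """Binary lesion mask aligned to a SuvVolume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("VOI mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def resample_isotropic(
    volume: SuvVolume, mask: VoiMask, target_spacing: float = 2.0
) -> tuple[SuvVolume, VoiMask]:
    """Resample to isotropic voxels: cubic B-spline for the SUV grid,
    nearest-neighbor (re-binarized) for the mask."""
    import SimpleITK as sitk

    if mask.data.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume shape")
    img = sitk.GetImageFromArray(volume.data)
    img.SetSpacing(tuple(reversed(volume.spacing)))  # sitk spacing is (x, y, z)
    msk = sitk.GetImageFromArray(mask.data.astype(np.uint8))
    msk.SetSpacing(img.GetSpacing())

    new_size = [
        max(1, int(round(sz * sp / target_spacing)))
        for sz, sp in zip(img.GetSize(), img.GetSpacing())
    ]
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing((target_spacing,) * 3)
    rs.SetSize(new_size)
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetOutputDirection(img.GetDirection())
    rs.SetInterpolator(sitk.sitkBSpline)
    vol_out = sitk.GetArrayFromImage(rs.Execute(img))
    rs.SetInterpolator(sitk.sitkNearestNeighbor)
    msk_out = sitk.GetArrayFromImage(rs.Execute(msk)) > 0

    if not msk_out.any():
        raise ValueError("VOI mask is empty after resampling")
    return (
        SuvVolume(vol_out, (target_spacing,) * 3),
        VoiMask(msk_out),
    )


def _sphere_mean_map(volume: SuvVolume, radius_mm: float) -> np.ndarray:
    """Mean SUV within a sphere of `radius_mm` centered at every voxel;
    spheres truncated at the grid boundary average over the valid part."""
    half = [int(math.floor(radius_mm / s)) for s in volume.spacing]
    zz, yy, xx = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, volume.spacing)],
        indexing="ij",
    )
    kernel = (zz**2 + yy**2 + xx**2 <= radius_mm**2).astype(float)
    num = ndimage.convolve(volume.data, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(volume.data), kernel, mode="constant", cval=0.0)
    return num / den


def suv_metrics(
    volume: SuvVolume, mask: VoiMask, peak_sphere_ml: float = 1.0
) -> dict[str, float]:
    """Conventional SUV metrics over the VOI.

    SUVpeak follows the PERCIST convention: the maximum, over in-mask voxel
    centers, of the mean SUV inside a 1 ml sphere centered on the voxel.
    PSMA-TV is the mask volume in ml; TL-PSMA = SUVmean x PSMA-TV.
    """
    if mask.data.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume shape")
    if mask.n_voxels == 0:
        raise ValueError("empty VOI mask")
    vals = volume.data[mask.data]
    radius = (3.0 * peak_sphere_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    peak = float(_sphere_mean_map(volume, radius)[mask.data].max())
    tv = mask.n_voxels * volume.voxel_volume_ml
    mean = float(vals.mean())
    return {
        "SUVmin": float(vals.min()),
        "SUVmax": float(vals.max()),
        "SUVmean": mean,
        "SUVpeak": peak,
        "PSMA_TV": tv,
        "TL_PSMA": mean * tv,
    }


def discretize_fixed_bin_width(
    volume: SuvVolume, mask: VoiMask, bin_width: float = 0.3
) -> np.ndarray:
    """Fixed-bin-width gray levels for in-mask voxels:
    bin(x) = floor((x - min_in_mask) / width) + 1, so labels start at 1 and
    are invariant to a uniform SUV shift."""
    if mask.n_voxels == 0:
        raise ValueError("empty VOI mask")
    vals = volume.data[mask.data]
    return np.floor((vals - vals.min()) / bin_width).astype(int) + 1


def _discretized_grid(volume: SuvVolume, mask: VoiMask, bin_width: float) -> np.ndarray:
    grid = np.zeros(volume.data.shape, dtype=int)  # 0 = outside mask
    grid[mask.data] = discretize_fixed_bin_width(volume, mask, bin_width)
    return grid


# the 13 unique 3D direction vectors (half of the 26-neighborhood)
_DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _glcm_one_direction(grid: np.ndarray, offset: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix for one offset over in-mask pairs."""
    dz, dy, dx = offset
    nz, ny, nx = grid.shape
    a = grid[
        max(0, -dz): nz - max(0, dz),
        max(0, -dy): ny - max(0, dy),
        max(0, -dx): nx - max(0, dx),
    ]
    b = grid[
        max(0, dz): nz - max(0, -dz),
        max(0, dy): ny - max(0, -dy),
        max(0, dx): nx - max(0, -dx),
    ]
    valid = (a > 0) & (b > 0)
    i, j = a[valid] - 1, b[valid] - 1
    mat = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(mat, (i, j), 1.0)
    return mat + mat.T  # symmetrize


def _glcm_feature_dict(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    levels = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    px = p.sum(axis=1)
    mu = float((levels * px).sum())
    sigma2 = float(((levels - mu) ** 2 * px).sum())
    eps = np.finfo(float).tiny
    diff = np.abs(ii - jj)
    feats = {
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": float(-(p * np.log2(p + eps)).sum()),
        "JointMaximum": float(p.max()),
        "JointAverage": float((ii * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "InverseDifference": float((p / (1.0 + diff)).sum()),
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
    }
    # difference/sum margins
    pd_ = np.array([p[diff == k].sum() for k in range(n)])
    ks = np.arange(n, dtype=float)
    feats["DifferenceAverage"] = float((ks * pd_).sum())
    feats["DifferenceEntropy"] = float(-(pd_ * np.log2(pd_ + eps)).sum())
    ps = np.array([p[(ii + jj) == s].sum() for s in range(2, 2 * n + 1)])
    ss = np.arange(2, 2 * n + 1, dtype=float)
    feats["SumAverage"] = float((ss * ps).sum())
    feats["SumEntropy"] = float(-(ps * np.log2(ps + eps)).sum())
    if sigma2 > 0:
        feats["Correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        feats["Correlation"] = 1.0  # homogeneous VOI convention
    return feats


def glcm_features(
    volume: SuvVolume, mask: VoiMask, bin_width: float = 0.3, distance: int = 1
) -> dict[str, float]:
    """GLCM features: distance-1 co-occurrences over in-mask voxel pairs,
    13 unique 3D directions, symmetric matrices normalized to probabilities,
    features averaged over directions with >= 1 pair."""
    if mask.n_voxels < 2:
        log.warning("GLCM undefined on a single-voxel VOI; features missing")
        return {}
    grid = _discretized_grid(volume, mask, bin_width)
    n_levels = int(grid.max())
    per_dir: list[dict[str, float]] = []
    for direction in _DIRECTIONS:
        offset = tuple(distance * d for d in direction)
        mat = _glcm_one_direction(grid, offset, n_levels)
        total = mat.sum()
        if total == 0:
            continue
        per_dir.append(_glcm_feature_dict(mat / total))
    if not per_dir:
        log.warning("no in-mask voxel pairs in any direction; GLCM missing")
        return {}
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def first_order_features(
    volume: SuvVolume, mask: VoiMask, bin_width: float = 0.3
) -> dict[str, float]:
    """IBSI-style first-order statistics of the in-mask SUV distribution.

    Entropy and Uniformity use the same fixed-bin-width discretization as
    the texture features.  On a zero-variance VOI, Skewness and Kurtosis are
    reported as 0 (with a warning) so the feature table stays numeric.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty VOI mask")
    x = volume.data[mask.data].astype(float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population moments, IBSI convention
    sd = math.sqrt(var)
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / var**2)
    else:
        log.warning("zero-variance VOI: skewness/kurtosis reported as 0")
        skew, kurt = 0.0, 0.0
    labels = np.floor((x - x.min()) / bin_width).astype(int)
    p = np.bincount(labels).astype(float)
    p = p[p > 0] / n
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    return {
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "P10": float(p10),
        "P90": float(p90),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "Energy": float((x**2).sum()),
        "RootMeanSquared": float(math.sqrt((x**2).mean())),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Uniformity": float((p**2).sum()),
    }


_FULL_SET_EXTRACTOR: Callable[[SuvVolume, VoiMask], dict[str, float]] | None = None


def register_full_set_extractor(fn: Callable[[SuvVolume, VoiMask], dict[str, float]]) -> None:
    """Register an external IBSI-compliant engine for the complete texture
    catalog; it must return ``rad::<family>::<name>`` keyed values."""
    global _FULL_SET_EXTRACTOR
    _FULL_SET_EXTRACTOR = fn


def extract_features(
    volume: SuvVolume,
    mask: VoiMask,
    bin_width: float = 0.3,
    resample: bool = True,
    target_spacing: float = 2.0,
) -> dict[str, float]:
    """Run the standard preprocessing + extraction chain on one lesion.

    Returns ``rad::suv::*``, ``rad::firstorder::*`` and ``rad::glcm::*``
    columns, plus whatever a registered full-set extractor adds.
    """
    if resample:
        volume, mask = resample_isotropic(volume, mask, target_spacing)
    out: dict[str, float] = {}
    for k, v in suv_metrics(volume, mask).items():
        out[f"rad::suv::{k}"] = v
    for k, v in first_order_features(volume, mask, bin_width).items():
        out[f"rad::firstorder::{k}"] = v
    for k, v in glcm_features(volume, mask, bin_width).items():
        out[f"rad::glcm::{k}"] = v
    if _FULL_SET_EXTRACTOR is not None:
        out.update(_FULL_SET_EXTRACTOR(volume, mask))
    return out
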