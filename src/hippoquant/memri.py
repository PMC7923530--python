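"""Voxel-wise manganese-enhanced MRI (MEMRI) activity quantification.

Mn2+ enters active neurons through voltage-gated Ca2+ channels and shortens
T1, so voxels that brighten between a pre-injection (PreMn) and a
post-injection (PostMn) T1-weighted scan mark active tissue.  The enhanced
hippocampal volume (eVol) is quantified by comparing each PostMn voxel in the
hippocampus mask against the mean of its six face-adjacent neighbors on the
PreMn scan, standardizing by a robust global noise SD, converting to
one-sided normal p-values and keeping the voxels that survive
Benjamini-Hochberg FDR control.  eVol is the surviving voxel count times the
voxel volume.

Only voxel size is honored from any input affine; arrays are indexed 0-based
in (section, row, column) order.  Registration, bias-field correction and
mask segmentation are upstream concerns: masks are inputs here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.stats import norm

__all__ = [
    "MemriPair",
    "EnhancementMap",
    "neighborhood_mean",
    "neighborhood_mean_grid",
    "estimate_noise_sd",
    "bh_fdr",
    "enhancement_test",
    "hippocampal_volume",
    "InsufficientReferenceError",
]

#: Minimum noise SD before the degenerate-SD guard engages.
SIGMA_FLOOR = 1e-12

#: Fewer valid face neighbors than this excludes a voxel from testing.
MIN_VALID_NEIGHBORS = 3

_FACE_OFFSETS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


class InsufficientReferenceError(ValueError):
    """Raised when too few reference voxels exist to estimate the noise SD."""


@dataclass
class MemriPair:
    """A registered PreMn/PostMn scan pair with brain and hippocampus masks."""

    pre: np.ndarray
    post: np.ndarray
    brain_mask: np.ndarray
    hippo_mask: np.ndarray
    voxel_mm: float

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        self.hippo_mask = np.asarray(self.hippo_mask).astype(bool)
        shapes = {self.pre.shape, self.post.shape,
                  self.brain_mask.shape, self.hippo_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"all grids must share one shape, got {shapes}")
        if self.pre.ndim != 3:
            raise ValueError("grids must be 3-D")
        if np.any(self.hippo_mask & ~self.brain_mask):
            raise ValueError("hippocampus mask must be nested inside the brain mask")
        if not (np.isfinite(self.pre).all() and np.isfinite(self.post).all()):
            raise ValueError("intensities must be finite")
        if not self.voxel_mm > 0:
            raise ValueError("voxel_mm must be > 0")


@dataclass
class EnhancementMap:
    """Per-voxel enhancement statistics and the surviving-voxel volume."""

    z: np.ndarray
    p: np.ndarray
    reject: np.ndarray
    tested: np.ndarray
    evol_mm3: float
    q_level: float
    sigma_hat: float
    sigma_degenerate: bool = False
    n_tested: int = 0
    n_reject: int = 0


def neighborhood_mean(volume: np.ndarray, mask: np.ndarray,
                      voxel: Tuple[int, int, int]) -> Tuple[float, int]:
    """Mean of the face-adjacent neighbors of ``voxel`` that lie inside
    ``mask`` and the grid.

    Returns ``(mean, count)``; with zero valid neighbors the voxel is
    untestable and ``(nan, 0)`` is returned rather than raising.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask).astype(bool)
    i, j, k = (int(x) for x in voxel)
    if not (0 <= i < volume.shape[0] and 0 <= j < volume.shape[1]
            and 0 <= k < volume.shape[2]):
        raise IndexError(f"voxel {voxel} outside grid of shape {volume.shape}")
    total, count = 0.0, 0
    for di, dj, dk in _FACE_OFFSETS:
        ni, nj, nk = i + di, j + dj, k + dk
        if (0 <= ni < volume.shape[0] and 0 <= nj < volume.shape[1]
                and 0 <= nk < volume.shape[2] and mask[ni, nj, nk]):
            total += float(volume[ni, nj, nk])
            count += 1
    if count == 0:
        return float("nan"), 0
    return total / count, count


def neighborhood_mean_grid(volume: np.ndarray,
                           mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`neighborhood_mean` over the full grid.

    Returns ``(mean, count)`` arrays; ``mean`` is NaN where no valid neighbor
    exists.  Neighbors outside the grid or outside ``mask`` are dropped, not
    imputed.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    total = np.zeros_like(volume)
    count = np.zeros(volume.shape, dtype=np.int32)
    valid = np.where(mask, volume, 0.0)
    for axis in range(3):
        for shift in (1, -1):
            total += _shift(valid, axis, shift)
            count += _shift(mask.astype(np.int32), axis, shift)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean, count


def _shift(a: np.ndarray, axis: int, shift: int) -> np.ndarray:
    """Shift with zero fill (values rolling in from outside the grid are 0)."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if shift > 0:
        src[axis] = slice(shift, None)
        dst[axis] = slice(None, -shift)
    else:
        src[axis] = slice(None, shift)
        dst[axis] = slice(-shift, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _difference_grid(pair: MemriPair) -> Tuple[np.ndarray, np.ndarray]:
    """d(v) = Post(v) − mean of the valid Pre face-neighbors, plus counts."""
    mean, count = neighborhood_mean_grid(pair.pre, pair.brain_mask)
    return pair.post - mean, count


def estimate_noise_sd(pair: MemriPair, min_reference: int = 100) -> Tuple[float, bool]:
    """Robust SD of d(v) = Post(v) − neighborhood mean of Pre over the
    reference region brain ∖ hippocampus.

    Uses 1.4826 x median absolute deviation, which tolerates a small fraction
    of genuinely enhanced or artifactual reference voxels.  Returns
    ``(sigma_hat, degenerate)``; a zero spread trips a floor of 1e-12 and the
    degenerate flag instead of dividing by zero downstream.
    """
    d, count = _difference_grid(pair)
    ref = pair.brain_mask & ~pair.hippo_mask & (count >= MIN_VALID_NEIGHBORS)
    values = d[ref]
    values = values[np.isfinite(values)]
    if values.size < min_reference:
        raise InsufficientReferenceError(
            f"only {values.size} reference voxels (need >= {min_reference})")
    mad = np.median(np.abs(values - np.median(values)))
    sigma = 1.4826 * float(mad)
    if sigma < SIGMA_FLOOR:
        return SIGMA_FLOOR, True
    return sigma, False


def bh_fdr(p_values, q_level: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, in the input order.

    Sorts p ascending, finds the largest k with p(k) <= k*q/m and rejects
    every hypothesis with p <= p(k).  Empty input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if not 0.0 < q_level < 1.0:
        raise ValueError("q_level must lie in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = q_level * np.arange(1, m + 1) / m
    below = sorted_p <= thresholds
    if not below.any():
        return np.zeros(m, dtype=bool)
    k = int(np.nonzero(below)[0].max())
    return p <= sorted_p[k]


def enhancement_test(pair: MemriPair, q_level: float = 0.05) -> EnhancementMap:
    """Run the full per-voxel enhancement test on a scan pair.

    For every hippocampus voxel with at least three valid face neighbors:
    z(v) = (Post(v) − mean of Pre neighbors) / sigma_hat, one-sided upper-tail
    normal p, BH step-up at ``q_level`` over all tested voxels.  The test is
    one-sided because Mn2+ uptake only increases signal.
    """
    if not pair.hippo_mask.any():
        raise ValueError("hippocampus mask is empty")
    sigma, degenerate = estimate_noise_sd(pair)
    d, count = _difference_grid(pair)
    tested = pair.hippo_mask & (count >= MIN_VALID_NEIGHBORS)

    z = np.full(pair.pre.shape, np.nan)
    p = np.full(pair.pre.shape, np.nan)
    z[tested] = d[tested] / sigma
    p[tested] = norm.sf(z[tested])

    reject = np.zeros(pair.pre.shape, dtype=bool)
    reject[tested] = bh_fdr(p[tested], q_level)

    n_reject = int(reject.sum())
    return EnhancementMap(
        z=z, p=p, reject=reject, tested=tested,
        evol_mm3=n_reject * pair.voxel_mm ** 3,
        q_level=q_level, sigma_hat=sigma, sigma_degenerate=degenerate,
        n_tested=int(tested.sum()), n_reject=n_reject)


def hippocampal_volume(mask: np.ndarray, voxel_mm: float) -> float:
    """Mask volume in mm^3: voxel count x voxel_mm^3."""
    mask = np.asarray(mask).astype(bool)
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be > 0")
    return float(mask.sum()) * float(voxel_mm) ** 3
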