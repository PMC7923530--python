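"""Synthetic PreMn/PostMn scan-pair phantom.

The phantom is a brain ellipsoid containing two mirrored hippocampal
ellipsoids.  PreMn is a gently tilted baseline field plus Gaussian noise;
PostMn repeats the noise-free baseline, adds the Mn enhancement
(``effect_size x noise_sd``) at a Bernoulli-selected fraction of hippocampal
voxels, and adds an independent noise draw.  The baseline is planar so the
six-neighbor mean is exactly unbiased in the interior; Rician noise at the
SNRs of interest is approximately Gaussian, which also keeps the null of the
downstream z-test exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hippoquant.memri import MemriPair
from hippoquant.presets import MemriPreset

__all__ = ["MemriTruth", "gen_memri_pair"]

#: Hippocampal ellipsoid semi-axes for the control mask, in voxels on a 64^3
#: grid (scaled proportionally for other grid sizes).  Two mirrored
#: ellipsoids of this size hold ~4,800 voxels total.
_HIPPO_SEMI_VOX = np.array([6.0, 12.0, 8.0])
_HIPPO_OFFSET_VOX = 14.0   # lateral offset of each hippocampus from midline
_BRAIN_FRACTION = 0.44     # brain semi-axes as a fraction of grid extent


@dataclass
class MemriTruth:
    """Ground truth for one synthetic scan pair."""

    enhanced_mask: np.ndarray
    table: pd.DataFrame


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, s in zip(grids, center, semi):
        acc = acc + ((g - c) / s) ** 2
    return acc <= 1.0


def gen_memri_pair(preset: MemriPreset, seed: int):
    """Generate one (MemriPair, MemriTruth) for ``preset``.

    The hippocampus mask volume equals the control mask volume times
    ``preset.hippocampus_scale``, realized by isotropic rescaling of the
    ellipsoid semi-axes; per-subject anatomical variability is a small seeded
    jitter of the centers and semi-axes.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in preset.grid_shape)
    scale_vox = min(shape) / 64.0
    center = np.array([(n - 1) / 2.0 for n in shape])

    brain_semi = np.array([n * _BRAIN_FRACTION for n in shape])
    brain = _ellipsoid(shape, center, brain_semi)

    # Semi-axes scale with the grid but are floored at half the nominal
    # size: below that the phantom anatomy cannot be represented and the
    # grid is rejected as too small.
    base_semi = np.maximum(_HIPPO_SEMI_VOX * scale_vox, _HIPPO_SEMI_VOX / 2.0)
    semi = base_semi * preset.hippocampus_scale ** (1.0 / 3.0)
    # Mild per-subject anatomy: +/-1 voxel center jitter, ~1% axis jitter.
    jitter_axes = rng.normal(1.0, 0.01, size=(2, 3))
    jitter_center = rng.uniform(-1.0, 1.0, size=(2, 3))
    offset = max(_HIPPO_OFFSET_VOX * scale_vox, _HIPPO_OFFSET_VOX / 2.0)
    hippo = np.zeros(shape, dtype=bool)
    for side, sign in enumerate((-1.0, 1.0)):
        c = center + np.array([0.0, 0.0, sign * offset]) + jitter_center[side]
        s = semi * jitter_axes[side]
        if np.any(c - s < 1) or np.any(c + s > np.array(shape) - 2):
            raise ValueError(
                f"grid {shape} too small to contain the hippocampus ellipsoids")
        hippo |= _ellipsoid(shape, c, s)
    if not (hippo & ~brain).sum() == 0:
        raise ValueError("hippocampus ellipsoids fall outside the brain ellipsoid")

    # Planar baseline: zero Laplacian, so the 6-neighbor mean is unbiased.
    grids = np.indices(shape, dtype=float)
    gradient = 0.05 * preset.noise_sd
    baseline = 100.0 + gradient * sum(g - c for g, c in zip(grids, center))

    pre = baseline + rng.normal(0.0, preset.noise_sd, shape)
    enhanced = hippo & (rng.random(shape) < preset.enhanced_fraction)
    if preset.enhanced_fraction >= 1.0:
        enhanced = hippo.copy()
    post = baseline + rng.normal(0.0, preset.noise_sd, shape)
    post[enhanced] += preset.effect_size * preset.noise_sd

    pair = MemriPair(pre=pre, post=post, brain_mask=brain, hippo_mask=hippo,
                     voxel_mm=preset.voxel_mm)
    table = pd.DataFrame([{
        "preset": preset.name,
        "seed": int(seed),
        "n_hippo_voxels": int(hippo.sum()),
        "n_enhanced_voxels": int(enhanced.sum()),
        "enhanced_fraction": preset.enhanced_fraction,
        "effect_size": preset.effect_size,
        "noise_sd": preset.noise_sd,
        "hippocampus_scale": preset.hippocampus_scale,
        "voxel_mm": preset.voxel_mm,
    }])
    return pair, MemriTruth(enhanced_mask=enhanced, table=table)
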