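"""Synthetic serial-section EM dendrite phantom.

A labeled voxel stack (20 nm in-plane, 75 nm sections by default) containing
a cylindrical dendritic shaft along the y axis with Poisson-placed spines of
four geometric archetypes:

* thin       - long narrow neck, small head (head/neck ~ 1.3)
* mushroom   - large head on a narrow neck (head/neck >= 2.6)
* stubby     - short cylinder, no neck constriction
* filamentous- long (>2 um) headless protrusion, no synapse

Every non-filamentous spine carries a flat postsynaptic-density (PSD) patch
at its tip (a solid disc for macular PSDs, an annulus for perforated ones),
an apposed presynaptic bouton, and - for a preset-controlled fraction of
synapses - a perisynaptic astrocyte arc touching the cleft border, whose
angular coverage increases with spine head size (the tripartite-synapse
coupling seen in tissue).

Spine placement: the spine count is Poisson(density x length) truncated at
the geometric packing capacity, and positions are drawn from the exact
hard-rod conditional distribution with a 0.19 um minimum axial spacing.
Spines cycle through four azimuths (+x, +z, -x, -z), which makes every 3-D
base-to-base separation at least 0.4 um and every same-azimuth axial
separation at least four spacings, so distinct spines never merge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from hippoquant.presets import DendritePreset, SPINE_CLASSES
from hippoquant.spines import (LABEL_ASTRO, LABEL_BOUTON, LABEL_PSD,
                               LABEL_SHAFT, LABEL_SPINE, LabeledStack)

__all__ = ["DendriteTruth", "gen_dendrite_stack", "PlacementError"]

#: Minimum axial (along-shaft) spacing between spine bases, in um.
MIN_AXIAL_GAP_UM = 0.19

_PSD_THICK_UM = 0.05
_BOUTON_THICK_UM = 0.30
_BOUTON_EXTRA_R_UM = 0.10
_ASTRO_BAND_UM = 0.13
_MARGIN_Y_UM = 0.55


class PlacementError(RuntimeError):
    """Raised when spines cannot be packed onto the shaft."""


@dataclass
class DendriteTruth:
    """Per-spine ground truth for one phantom dendrite."""

    table: pd.DataFrame
    shaft_length_um: float


def _axis_coords(stack_shape, spacing_um):
    """Physical voxel-center coordinates (um) along (z, y, x)."""
    return [np.arange(n) * s for n, s in zip(stack_shape, spacing_um)]


def _sample_positions(rng, length_um: float, density_per_um: float):
    """Poisson count (truncated at packing capacity) + hard-rod positions."""
    capacity = int(math.floor(length_um / MIN_AXIAL_GAP_UM)) + 1
    n = int(rng.poisson(density_per_um * length_um))
    n = min(n, capacity)
    if n == 0:
        return np.zeros(0)
    free = length_um - (n - 1) * MIN_AXIAL_GAP_UM
    if free < 0:
        raise PlacementError(
            f"cannot place {n} spines with {MIN_AXIAL_GAP_UM} um spacing "
            f"on a {length_um} um shaft")
    u = np.sort(rng.uniform(0.0, free, size=n))
    return u + MIN_AXIAL_GAP_UM * np.arange(n)


def _balanced_classes(rng, n: int, mixture: np.ndarray) -> np.ndarray:
    """Class labels with balanced (largest-remainder) counts.

    Counts are floor(n*p) plus a weighted random allocation of the
    remainder, so every dendrite's realized class composition is
    representative of the preset mixture (expected counts are exact); the
    order along the shaft is a random permutation.
    """
    if n == 0:
        return np.zeros(0, dtype=int)
    base = np.floor(n * mixture).astype(int)
    frac = n * mixture - base
    remainder = n - int(base.sum())
    if remainder > 0:
        if frac.sum() <= 0:
            extra = rng.choice(mixture.size, size=remainder, replace=False)
        else:
            extra = rng.choice(mixture.size, size=remainder, replace=False,
                               p=frac / frac.sum())
        base[extra] += 1
    return rng.permutation(np.repeat(np.arange(mixture.size), base))


def _sample_geometry(rng, preset: DendritePreset, cls: str):
    lo, hi = preset.neck_len_um[cls]
    axis_len = float(rng.uniform(lo, hi))
    lo, hi = preset.neck_diam_um[cls]
    neck_diam = float(rng.uniform(lo, hi))
    lo, hi = preset.head_over_neck[cls]
    ratio = float(rng.uniform(lo, hi))
    if cls in ("thin", "mushroom"):
        head_diam = neck_diam * ratio
        length = axis_len + head_diam
    else:  # stubby / filamentous: single cylinder, no separate head
        head_diam = neck_diam
        length = axis_len
    return length, axis_len, neck_diam, head_diam


def gen_dendrite_stack(preset: DendritePreset, shaft_length_um: float, seed: int,
                       fixed_astro_coverage: Optional[float] = None):
    """Generate one ``(LabeledStack, DendriteTruth)`` phantom dendrite.

    Parameters
    ----------
    shaft_length_um : analyzed shaft length (>= 10 um, the study's minimum).
    fixed_astro_coverage : if given, every contacted synapse receives exactly
        this angular coverage fraction instead of the head-size-coupled draw
        (used to build known geometries in tests).
    """
    if shaft_length_um < 10.0:
        raise ValueError("shaft_length_um must be >= 10 um")
    rng = np.random.default_rng(seed)
    sx, sy, sz = preset.voxel_nm  # (x, y, z-section) in nm
    spacing = (sz / 1000.0, sy / 1000.0, sx / 1000.0)  # (z, y, x) in um

    max_neck = max(hi for hi in (preset.neck_len_um[c][1] for c in SPINE_CLASSES))
    max_reach = (preset.shaft_radius_um + max_neck
                 + max(preset.neck_diam_um[c][1] * preset.head_over_neck[c][1]
                       for c in SPINE_CLASSES)
                 + _PSD_THICK_UM + _BOUTON_THICK_UM + 0.25)
    nz = int(math.ceil(2 * max_reach / spacing[0])) + 3
    ny = int(math.ceil((shaft_length_um + 2 * _MARGIN_Y_UM) / spacing[1])) + 1
    nx = int(math.ceil(2 * max_reach / spacing[2])) + 3
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    zc, xc = (nz - 1) / 2.0 * spacing[0], (nx - 1) / 2.0 * spacing[2]

    coords = _axis_coords(labels.shape, spacing)
    zz = coords[0][:, None, None] - zc
    yy = coords[1][None, :, None] - _MARGIN_Y_UM
    xx = coords[2][None, None, :] - xc

    # Shaft: cylinder along y.
    shaft_sel = ((zz ** 2 + xx ** 2) <= preset.shaft_radius_um ** 2) & \
                (yy >= 0) & (yy <= shaft_length_um)
    labels[shaft_sel] = LABEL_SHAFT

    positions = _sample_positions(rng, shaft_length_um, preset.density_per_um)
    n = positions.size
    classes = _balanced_classes(rng, n, np.asarray(preset.mixture_tuple))
    directions = ["+x", "+z", "-x", "-z"]
    dir_start = int(rng.integers(0, 4))

    records = []
    for i in range(n):
        cls = SPINE_CLASSES[int(classes[i])]
        direction = directions[(dir_start + i) % 4]
        length, axis_len, neck_diam, head_diam = _sample_geometry(rng, preset, cls)
        has_psd = cls != "filamentous"
        perforated = bool(has_psd and rng.random() < preset.perforated_fraction)
        records.append({
            "spine_id": i, "position_um": float(positions[i]),
            "direction": direction, "spine_class": cls,
            "length_um": length, "axis_len_um": axis_len,
            "neck_diam_um": neck_diam, "head_diam_um": head_diam,
            "psd_type": ("perforated" if perforated else "macular") if has_psd
                        else "none",
        })
    truth = pd.DataFrame(records, columns=[
        "spine_id", "position_um", "direction", "spine_class", "length_um",
        "axis_len_um", "neck_diam_um", "head_diam_um", "psd_type"])

    # Astrocyte participation: contacted synapses are drawn with probability
    # weights proportional to head size, and coverage grows with head size.
    if n:
        syn = truth.index[truth.psd_type != "none"].to_numpy()
        k = int(round(preset.astro_contact_fraction * syn.size))
        contacted = np.zeros(n, dtype=bool)
        coverage = np.zeros(n)
        if k > 0:
            heads = truth.loc[syn, "head_diam_um"].to_numpy()
            w = heads / heads.sum()
            chosen = rng.choice(syn, size=k, replace=False, p=w)
            contacted[chosen] = True
            if fixed_astro_coverage is not None:
                coverage[chosen] = float(fixed_astro_coverage)
            else:
                h = truth.loc[chosen, "head_diam_um"].to_numpy()
                span = max(h.max() - h.min(), 1e-9)
                coverage[chosen] = np.clip(
                    0.35 + 0.5 * (h - h.min()) / span + rng.normal(0, 0.07, k),
                    0.12, 1.0)
        truth["astro_contact"] = contacted
        truth["astro_coverage"] = coverage
    else:
        truth["astro_contact"] = pd.Series(dtype=bool)
        truth["astro_coverage"] = pd.Series(dtype=float)

    for rec in truth.itertuples():
        _paint_spine(labels, rec, preset, spacing, zc, xc, rng)

    volumes = []
    for rec in truth.itertuples():
        r_n = rec.neck_diam_um / 2.0
        r_h = rec.head_diam_um / 2.0
        if rec.spine_class in ("thin", "mushroom"):
            volumes.append(math.pi * r_n ** 2 * rec.axis_len_um
                           + 4.0 / 3.0 * math.pi * r_h ** 3)
        else:
            volumes.append(math.pi * r_n ** 2 * rec.axis_len_um)
    truth["volume_um3"] = volumes

    stack = LabeledStack(labels=labels, voxel_nm=(sx, sy, sz))
    return stack, DendriteTruth(table=truth, shaft_length_um=shaft_length_um)


def _paint_spine(labels, rec, preset, spacing, zc, xc, rng) -> None:
    """Paint one spine (plus PSD / bouton / astrocyte) into ``labels``.

    Painting only writes background voxels, so the shaft keeps its label in
    the overlap region and each voxel carries exactly one label.
    """
    nz, ny, nx = labels.shape
    axis = "x" if rec.direction in ("+x", "-x") else "z"
    sign = 1.0 if rec.direction[0] == "+" else -1.0
    a_idx = 2 if axis == "x" else 0          # array axis of the spine axis
    a_spacing = spacing[a_idx]
    a_center = xc if axis == "x" else zc
    b_idx = 0 if axis == "x" else 2          # transverse non-y axis
    b_spacing = spacing[b_idx]
    b_center = zc if axis == "x" else xc

    r_shaft = preset.shaft_radius_um
    r_neck = rec.neck_diam_um / 2.0
    r_head = rec.head_diam_um / 2.0
    headed = rec.spine_class in ("thin", "mushroom")
    u_tip = r_shaft + rec.axis_len_um + (rec.head_diam_um if headed else 0.0)
    r_psd = max(0.40 * rec.head_diam_um, 0.06)
    r_hole = max(0.35 * r_psd, 0.025)
    reach = u_tip + _PSD_THICK_UM + _BOUTON_THICK_UM + 0.15
    r_max = max(r_head, r_psd + _ASTRO_BAND_UM) + 0.1

    # Local bounding box.
    def rng_idx(center_um, extent_um, step, nmax):
        lo = max(int(math.floor((center_um - extent_um) / step)), 0)
        hi = min(int(math.ceil((center_um + extent_um) / step)) + 1, nmax)
        return lo, hi

    y_um = rec.position_um + _MARGIN_Y_UM
    ylo, yhi = rng_idx(y_um, r_max, spacing[1], ny)
    alo, ahi = rng_idx(a_center + sign * reach / 2.0, reach / 2.0 + 0.1,
                       a_spacing, nz if a_idx == 0 else nx)
    blo, bhi = rng_idx(b_center, r_max, b_spacing, nz if b_idx == 0 else nx)

    if a_idx == 2:
        box = (slice(blo, bhi), slice(ylo, yhi), slice(alo, ahi))
        a_axis_len = ahi - alo
        a_coords = (np.arange(alo, ahi) * a_spacing)[None, None, :]
        b_coords = (np.arange(blo, bhi) * b_spacing)[:, None, None]
    else:
        box = (slice(alo, ahi), slice(ylo, yhi), slice(blo, bhi))
        a_axis_len = ahi - alo
        a_coords = (np.arange(alo, ahi) * a_spacing)[:, None, None]
        b_coords = (np.arange(blo, bhi) * b_spacing)[None, None, :]
    y_coords = (np.arange(ylo, yhi) * spacing[1])[None, :, None]

    sub = labels[box]
    u = sign * (a_coords - a_center)              # axial coordinate, um
    dy = y_coords - y_um
    db = b_coords - b_center
    r_perp2 = dy ** 2 + db ** 2

    def paint(mask, label):
        sub[mask & (sub == 0)] = label

    # Neck / body cylinder, rooted slightly inside the shaft for adjacency.
    if headed:
        u_hc = r_shaft + rec.axis_len_um + r_head
        # neck reaches the head centre so the two always connect on the grid
        body = (u >= r_shaft - 0.05) & (u <= u_hc) & (r_perp2 <= r_neck ** 2)
        head = ((u - u_hc) ** 2 + r_perp2) <= r_head ** 2
        paint(body | head, LABEL_SPINE)
    else:
        body = (u >= r_shaft - 0.05) & (u <= u_tip) & (r_perp2 <= r_neck ** 2)
        paint(body, LABEL_SPINE)

    if rec.psd_type == "none":
        return

    # PSD: flat disc (or annulus) in the first axial voxel layers beyond the
    # tip; layer counts are at least one so coarse sectioning cannot erase it.
    u_axis = sign * ((np.arange(alo, ahi) * a_spacing) - a_center)
    beyond = np.nonzero(u_axis > u_tip)[0]
    beyond = alo + beyond[np.argsort(u_axis[beyond])]
    n_psd = max(1, int(round(_PSD_THICK_UM / a_spacing)))
    n_bout = max(1, int(round(_BOUTON_THICK_UM / a_spacing)))
    psd_layers = beyond[:n_psd]
    bout_layers = beyond[n_psd:n_psd + n_bout]

    disc = r_perp2 <= r_psd ** 2
    if rec.psd_type == "perforated":
        disc = disc & (r_perp2 >= r_hole ** 2)
    ring = (r_perp2 > r_psd ** 2) & (r_perp2 <= (r_psd + _ASTRO_BAND_UM) ** 2)
    if rec.astro_contact:
        theta = np.arctan2(db, dy)  # angle in the transverse plane
        theta0 = rng.uniform(-math.pi, math.pi)
        arc = np.mod(theta - theta0, 2 * math.pi) <= \
            2 * math.pi * rec.astro_coverage
        ring = ring & arc
    else:
        ring = np.zeros_like(disc)

    def layer_slice(idx):
        s = [slice(None)] * 3
        s[0 if a_idx == 0 else 2] = slice(idx - alo, idx - alo + 1)
        return tuple(s)

    for idx in psd_layers:
        ls = layer_slice(idx)
        lsub = sub[ls]
        sel = np.broadcast_to(disc, sub.shape)[ls] & (lsub == 0)
        lsub[sel] = LABEL_PSD
        if rec.astro_contact:
            sel = np.broadcast_to(ring, sub.shape)[ls] & (lsub == 0)
            lsub[sel] = LABEL_ASTRO
    full = r_perp2 <= (r_psd + _BOUTON_EXTRA_R_UM) ** 2
    for idx in bout_layers:
        ls = layer_slice(idx)
        lsub = sub[ls]
        sel = np.broadcast_to(full, sub.shape)[ls] & (lsub == 0)
        lsub[sel] = LABEL_BOUTON
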