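"""Built-in study-condition presets for the synthetic phantom generators.

The three conditions (myelinated control, demyelinated, remyelinated) are
encoded as ground-truth parameter sets whose *ratios* match the printed group
contrasts of the cuprizone hippocampal demyelination model: a 54% drop in
Mn-enhanced volume, an 11.1% drop in hippocampal volume, a 40% rise in
mushroom-class spines at the expense of thin spines, a reversal of the 2:1
macular:perforated PSD ratio, a doubling of astrocyte-contacted synapses, a
complete loss of the field EPSP with preserved afferent volley, and a ~1.6x
LTP of the EPSP slope.  Control-side absolute baselines (the 0.60 enhanced
fraction, the myelinated class mixture) are not printed anywhere and are this
package's documented free choices; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

__all__ = [
    "MemriPreset",
    "DendritePreset",
    "EphysPreset",
    "MEMRI_PRESETS",
    "DENDRITE_PRESETS",
    "EPHYS_PRESETS",
    "PPF_INTERVALS_MS",
    "get_preset",
]

#: Inter-stimulus intervals (ms) at which paired-pulse facilitation is probed.
PPF_INTERVALS_MS = (10.0, 50.0, 100.0, 200.0, 400.0)

SPINE_CLASSES = ("thin", "mushroom", "stubby", "filamentous")


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class MemriPreset:
    """Ground-truth parameters for one synthetic PreMn/PostMn subject.

    Parameters
    ----------
    enhanced_fraction : fraction of hippocampus-mask voxels that receive the
        Mn enhancement in the PostMn scan (0-1).
    effect_size : enhancement amplitude in units of the voxel noise SD.
    noise_sd : additive Gaussian intensity noise SD (arbitrary units).
    hippocampus_scale : hippocampal volume multiplier relative to the control
        mask (realized by isotropic rescaling of the mask ellipsoids).
    grid_shape : voxel counts per (section, row, column) axis.
    voxel_mm : isotropic voxel edge length in mm.
    """

    name: str
    enhanced_fraction: float
    effect_size: float = 3.0
    noise_sd: float = 1.0
    hippocampus_scale: float = 1.0
    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 0.140

    def __post_init__(self) -> None:
        for key in ("enhanced_fraction", "effect_size", "noise_sd",
                    "hippocampus_scale", "voxel_mm"):
            _check_finite(key, getattr(self, key))
        if not 0.0 <= self.enhanced_fraction <= 1.0:
            raise ValueError("enhanced_fraction must lie in [0, 1]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 < self.hippocampus_scale <= 1.0:
            raise ValueError("hippocampus_scale must lie in (0, 1]")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be > 0")
        if len(self.grid_shape) != 3 or any(int(n) < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be three axes of at least 16 voxels")


@dataclass(frozen=True)
class DendritePreset:
    """Ground-truth parameters for one synthetic EM dendrite phantom.

    ``class_geometry`` maps each spine class to ``(length_um, neck_diam_um,
    head_over_neck)`` sampling ranges; geometries are deliberately
    well-separated so the shape classes are robust to voxelization at the
    phantom resolution (20 nm in-plane, 75 nm sections).
    """

    name: str
    density_per_um: float
    class_mixture: Mapping[str, float]
    perforated_fraction: float
    astro_contact_fraction: float
    voxel_nm: Tuple[float, float, float] = (20.0, 20.0, 75.0)  # (x, y, z-section)
    shaft_radius_um: float = 0.35
    min_gap_um: float = 0.4
    # Per-class (low, high) sampling ranges, in um except for the unitless
    # head/neck ratio.  Total spine length = neck length + head diameter for
    # headed classes; stubby and filamentous are single cylinders.
    neck_len_um: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: {
        "thin": (0.95, 1.45),
        "mushroom": (0.55, 0.85),
        "stubby": (0.30, 0.50),        # total length for stubby
        "filamentous": (2.30, 3.00),   # total length for filamentous
    })
    neck_diam_um: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: {
        "thin": (0.13, 0.16),
        "mushroom": (0.18, 0.24),
        "stubby": (0.32, 0.46),
        "filamentous": (0.11, 0.14),
    })
    head_over_neck: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: {
        "thin": (1.25, 1.35),
        "mushroom": (2.60, 3.20),
        "stubby": (1.0, 1.0),
        "filamentous": (1.0, 1.0),
    })

    def __post_init__(self) -> None:
        if self.density_per_um < 0:
            raise ValueError("density_per_um must be >= 0")
        total = float(sum(self.class_mixture.get(c, 0.0) for c in SPINE_CLASSES))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture must sum to 1, got {total}")
        if set(self.class_mixture) - set(SPINE_CLASSES):
            raise ValueError("class_mixture has unknown spine classes")
        if not 0.0 <= self.perforated_fraction <= 1.0:
            raise ValueError("perforated_fraction must lie in [0, 1]")
        if not 0.0 <= self.astro_contact_fraction <= 1.0:
            raise ValueError("astro_contact_fraction must lie in [0, 1]")
        if len(self.voxel_nm) != 3 or any(v <= 0 for v in self.voxel_nm):
            raise ValueError("voxel_nm must be three positive dimensions")

    @property
    def mixture_tuple(self) -> Tuple[float, ...]:
        return tuple(float(self.class_mixture.get(c, 0.0)) for c in SPINE_CLASSES)


@dataclass(frozen=True)
class EphysPreset:
    """Ground-truth parameters for synthetic field-potential sweeps.

    Amplitudes are in mV; the EPSP is an alpha function with time constant
    ``epsp_tau_ms`` starting 5 ms after the stimulus, the afferent volley a
    biphasic (difference-of-Gaussians) deflection at 2 ms latency.
    """

    name: str
    av_amp_mV: float
    epsp_amp_mV_mean: float
    epsp_amp_mV_sd: float = 0.0
    epsp_tau_ms: float = 5.0
    ppf_ratio: Mapping[float, float] = field(default_factory=lambda: dict(
        zip(PPF_INTERVALS_MS, (1.30, 1.60, 1.45, 1.25, 1.10))))
    ltp_factor: float = 1.0
    noise_sd_mV: float = 0.05
    sample_rate_kHz: float = 10.0
    av_latency_ms: float = 2.0
    epsp_onset_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.av_amp_mV < 0 or self.epsp_amp_mV_mean < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.epsp_amp_mV_sd < 0 or self.noise_sd_mV < 0:
            raise ValueError("SDs must be >= 0")
        if self.epsp_tau_ms <= 0 or self.sample_rate_kHz <= 0:
            raise ValueError("epsp_tau_ms and sample_rate_kHz must be > 0")
        if set(self.ppf_ratio) != set(PPF_INTERVALS_MS):
            raise ValueError(f"ppf_ratio must be keyed by {PPF_INTERVALS_MS}")
        if any(r <= 0 for r in self.ppf_ratio.values()):
            raise ValueError("ppf_ratio entries must be > 0")
        if self.ltp_factor <= 0:
            raise ValueError("ltp_factor must be > 0")


MEMRI_PRESETS: Dict[str, MemriPreset] = {
    "control": MemriPreset("control", enhanced_fraction=0.60, hippocampus_scale=1.0),
    "demyelinated": MemriPreset("demyelinated", enhanced_fraction=0.276,
                                hippocampus_scale=0.889),
    "remyelinated": MemriPreset("remyelinated", enhanced_fraction=0.558,
                                hippocampus_scale=0.889),
}

DENDRITE_PRESETS: Dict[str, DendritePreset] = {
    "myelinated": DendritePreset(
        "myelinated", density_per_um=4.2,
        class_mixture={"thin": 0.45, "mushroom": 0.30, "stubby": 0.20,
                       "filamentous": 0.05},
        perforated_fraction=1.0 / 3.0, astro_contact_fraction=0.30),
    "demyelinated": DendritePreset(
        "demyelinated", density_per_um=4.2,
        class_mixture={"thin": 0.20, "mushroom": 0.42, "stubby": 0.33,
                       "filamentous": 0.05},
        perforated_fraction=2.0 / 3.0, astro_contact_fraction=0.60),
    "remyelinated": DendritePreset(
        "remyelinated", density_per_um=5.0,
        class_mixture={"thin": 0.28, "mushroom": 0.37, "stubby": 0.30,
                       "filamentous": 0.05},
        perforated_fraction=2.0 / 3.0, astro_contact_fraction=0.60),
}

EPHYS_PRESETS: Dict[str, EphysPreset] = {
    "control": EphysPreset("control", av_amp_mV=1.43, epsp_amp_mV_mean=1.96,
                           epsp_amp_mV_sd=0.96, ltp_factor=1.57),
    "demyelinated": EphysPreset("demyelinated", av_amp_mV=1.43,
                                epsp_amp_mV_mean=0.0, epsp_amp_mV_sd=0.0,
                                ltp_factor=1.0),
    "remyelinated": EphysPreset("remyelinated", av_amp_mV=1.42,
                                epsp_amp_mV_mean=1.5, epsp_amp_mV_sd=0.96,
                                ltp_factor=1.57),
}

_PRESET_TABLES = {"memri": MEMRI_PRESETS, "em": DENDRITE_PRESETS,
                  "ephys": EPHYS_PRESETS}


def get_preset(arm: str, name: str):
    """Look up a built-in preset by arm (``memri``/``em``/``ephys``) and name."""
    try:
        table = _PRESET_TABLES[arm]
    except KeyError:
        raise ValueError(f"unknown arm {arm!r}; expected one of {sorted(_PRESET_TABLES)}")
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown {arm} preset {name!r}; "
                         f"expected one of {sorted(table)}")


def scaled_preset(preset, **overrides):
    """Return a copy of ``preset`` with fields replaced (convenience for tests)."""
    return replace(preset, **overrides)
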