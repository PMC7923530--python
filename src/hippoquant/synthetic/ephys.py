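"""Synthetic field-potential sweeps.

Each sweep is a stimulus artifact (one-sample spike), a biphasic afferent
volley (difference of two offset Gaussians, fixed peak-to-peak amplitude,
2 ms latency), a negative-going alpha-function EPSP A*(t/tau)*exp(1-t/tau)
starting 5 ms post-stimulus, and additive Gaussian noise.

EPSP amplitudes are drawn from the preset's (mean, SD) normal distribution
by jittered stratified (quantile-balanced) sampling, truncated at zero:
small synthetic cohorts are meant to represent the condition's amplitude
distribution, so the strata pin the cohort mean at the preset mean while
preserving the preset spread across sweeps.  Protocols: ``single`` (one
stimulus), ``ppf`` (two stimuli at a chosen inter-stimulus interval, second
EPSP scaled by the preset's facilitation ratio), and ``ltp`` (a 30-s-interval
time course with three 100-Hz tetani 15 min apart, EPSPs scaling stepwise
to ``ltp_factor``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from hippoquant.ephys import Sweep
from hippoquant.presets import EphysPreset, PPF_INTERVALS_MS

__all__ = ["SweepTruth", "LTPProtocol", "gen_sweeps"]

_STIM_ARTIFACT_MV = 8.0
_AV_SIGMA_MS = 0.25
_AV_LOBE_OFFSET_MS = 0.3


@dataclass
class SweepTruth:
    """Ground truth per generated sweep (one row per stimulus)."""

    table: pd.DataFrame


@dataclass(frozen=True)
class LTPProtocol:
    """Timing of an LTP experiment: 30-s sweeps, three tetani 15 min apart."""

    n_baseline: int = 20
    n_post: int = 90
    sweep_interval_s: float = 30.0
    n_hfs: int = 3
    hfs_interval_min: float = 15.0

    def __post_init__(self) -> None:
        if self.n_baseline < 10:
            raise ValueError("need >= 10 baseline sweeps")
        if self.n_post < 1 or self.n_hfs < 1:
            raise ValueError("need >= 1 post sweep and >= 1 tetanus")


def _alpha(t_ms: np.ndarray, onset_ms: float, amp: float, tau: float) -> np.ndarray:
    x = (t_ms - onset_ms) / tau
    out = np.where(x > 0, amp * x * np.exp(1.0 - x), 0.0)
    return out


def _av_shape(t_ms: np.ndarray, latency_center: float) -> np.ndarray:
    g1 = np.exp(-0.5 * ((t_ms - (latency_center - _AV_LOBE_OFFSET_MS))
                        / _AV_SIGMA_MS) ** 2)
    g2 = np.exp(-0.5 * ((t_ms - (latency_center + _AV_LOBE_OFFSET_MS))
                        / _AV_SIGMA_MS) ** 2)
    return g1 - g2


def _stratified_amps(rng, mean: float, sd: float, n: int) -> np.ndarray:
    """Jittered stratified normal draws, truncated at zero."""
    if sd == 0:
        return np.full(n, max(mean, 0.0))
    from scipy.stats import norm as _norm
    u = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
    amps = mean + sd * _norm.ppf(u)
    rng.shuffle(amps)
    return np.maximum(amps, 0.0)


def _slice_amps(rng, preset: EphysPreset, n: int) -> np.ndarray:
    """Within-slice amplitude series for repeated-trial protocols (PPF/LTP).

    One slice-level amplitude (5% between-slice jitter around the preset
    mean) with 3% trial-to-trial jitter: successive sweeps from one slice
    are nearly constant, unlike the across-slice spread of ``single``
    cohorts.
    """
    base = max(preset.epsp_amp_mV_mean * (1.0 + 0.05 * rng.standard_normal()),
               0.0)
    return np.maximum(base * (1.0 + 0.03 * rng.standard_normal(n)), 0.0)


def _render(preset: EphysPreset, duration_ms: float, stim_times, amps,
            rng) -> Sweep:
    n = int(round(duration_ms * preset.sample_rate_kHz)) + 1
    t = np.arange(n) / preset.sample_rate_kHz
    v = np.zeros(n)
    av_shape_scale = None
    for stim, amp in zip(stim_times, amps):
        idx = int(round(stim * preset.sample_rate_kHz))
        v[idx] += _STIM_ARTIFACT_MV
        if preset.av_amp_mV > 0:
            shape = _av_shape(t, stim + preset.av_latency_ms)
            if av_shape_scale is None:
                av_shape_scale = shape.max() - shape.min()
            v += preset.av_amp_mV / av_shape_scale * shape
        if amp > 0:
            v -= _alpha(t, stim + preset.epsp_onset_ms, amp, preset.epsp_tau_ms)
    if preset.noise_sd_mV > 0:
        v = v + rng.normal(0.0, preset.noise_sd_mV, n)
    return Sweep(time_ms=t, voltage_mV=v, stim_times_ms=tuple(stim_times),
                 sample_rate_kHz=preset.sample_rate_kHz)


def gen_sweeps(preset: EphysPreset, n_sweeps: int, protocol: str, seed: int,
               interval_ms: Optional[float] = None,
               ltp_protocol: Optional[LTPProtocol] = None):
    """Generate ``(sweeps, SweepTruth)`` under ``single``/``ppf``/``ltp``.

    For ``ppf`` the inter-stimulus interval must be one of the probed set
    (10, 50, 100, 200, 400 ms).  For ``ltp`` the ``n_sweeps`` argument is
    ignored in favor of the protocol's sweep counts, and sweep times (min)
    plus tetanus markers are included in the ground truth.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    if protocol == "single":
        stim = 20.0
        amps = _stratified_amps(rng, preset.epsp_amp_mV_mean,
                                preset.epsp_amp_mV_sd, n_sweeps)
        sweeps = [_render(preset, 100.0, (stim,), (amps[i],), rng)
                  for i in range(n_sweeps)]
        table = pd.DataFrame({
            "sweep_id": np.arange(n_sweeps), "stim_time_ms": stim,
            "true_epsp_amp_mV": amps, "true_av_amp_mV": preset.av_amp_mV})
        return sweeps, SweepTruth(table=table)

    if protocol == "ppf":
        if interval_ms is None or float(interval_ms) not in PPF_INTERVALS_MS:
            raise ValueError(
                f"ppf interval must be one of {PPF_INTERVALS_MS} ms")
        interval = float(interval_ms)
        ratio = float(preset.ppf_ratio[interval])
        stim1 = 20.0
        stim2 = stim1 + interval
        amps = _slice_amps(rng, preset, n_sweeps)
        duration = stim2 + 70.0
        sweeps = [_render(preset, duration, (stim1, stim2),
                          (amps[i], amps[i] * ratio), rng)
                  for i in range(n_sweeps)]
        table = pd.DataFrame({
            "sweep_id": np.repeat(np.arange(n_sweeps), 2),
            "stim_time_ms": np.tile([stim1, stim2], n_sweeps),
            "true_epsp_amp_mV": np.column_stack([amps, amps * ratio]).ravel(),
            "true_av_amp_mV": preset.av_amp_mV,
            "interval_ms": interval, "true_ppf_ratio": ratio})
        return sweeps, SweepTruth(table=table)

    if protocol == "ltp":
        proto = ltp_protocol or LTPProtocol()
        dt_min = proto.sweep_interval_s / 60.0
        n_total = proto.n_baseline + proto.n_post
        times = np.arange(n_total) * dt_min
        first_hfs = proto.n_baseline * dt_min
        hfs_times = tuple(first_hfs + k * proto.hfs_interval_min
                          for k in range(proto.n_hfs))
        amps = _slice_amps(rng, preset, n_total)
        factors = np.ones(n_total)
        for k, h in enumerate(hfs_times):
            step = 1.0 + (preset.ltp_factor - 1.0) * (k + 1) / proto.n_hfs
            factors[times >= h] = step
        sweeps = [_render(preset, 100.0, (20.0,), (amps[i] * factors[i],), rng)
                  for i in range(n_total)]
        table = pd.DataFrame({
            "sweep_id": np.arange(n_total), "stim_time_ms": 20.0,
            "sweep_time_min": times,
            "true_epsp_amp_mV": amps * factors,
            "true_av_amp_mV": preset.av_amp_mV,
            "ltp_step_factor": factors})
        table.attrs["hfs_times_min"] = hfs_times
        return sweeps, SweepTruth(table=table)

    raise ValueError(f"unknown protocol {protocol!r}; "
                     "expected 'single', 'ppf' or 'ltp'")
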