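"""Field-potential feature extraction: afferent volley, EPSP, PPF, I/O, LTP.

Extracts the standard CA1 stratum-radiatum readouts from extracellular
sweeps: the afferent volley (AV, the fast biphasic presynaptic deflection),
the field EPSP (peak, 20-80% rising slope, area), paired-pulse facilitation
ratios, normalized input-output curve fits (Y = A + B*X), and the LTP
magnitude as the post-tetanus mean of baseline-normalized EPSP slopes.

Field EPSPs are negative-going; all features are computed on the magnitude
of the baseline-subtracted deflection, so polarity conventions do not
matter.  An EPSP smaller than ``threshold_mult`` times the robust pre-stimulus
noise floor is set to exactly zero - the detection rule that renders the
demyelinated condition's "0 +/- 0" EPSP while the afferent volley is
preserved.  Peaks are located on a lightly boxcar-smoothed trace (1 ms for
the slow EPSP, 0.2 ms for the fast AV) so that the extremum statistic does
not ride on single noise samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import linregress

__all__ = [
    "Sweep", "SweepFeatures", "FeatureConfig", "IOCurve", "LTPTimecourse",
    "extract_features", "ppf_ratio", "fit_io_curve", "ltp_magnitude",
    "UndefinedPPFError",
]


class UndefinedPPFError(ValueError):
    """PPF is not computable when the conditioning EPSP is absent."""


@dataclass
class Sweep:
    """One recorded sweep: time base, voltage trace, stimulus markers."""

    time_ms: np.ndarray
    voltage_mV: np.ndarray
    stim_times_ms: Tuple[float, ...]
    sample_rate_kHz: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.time_ms.shape != self.voltage_mV.shape:
            raise ValueError("time and voltage must have equal length")
        if self.time_ms.size < 2 or np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time must be strictly increasing")
        self.stim_times_ms = tuple(float(t) for t in self.stim_times_ms)
        if len(self.stim_times_ms) < 1:
            raise ValueError("at least one stimulus time is required")
        if self.sample_rate_kHz <= 0:
            raise ValueError("sample_rate_kHz must be > 0")


@dataclass
class SweepFeatures:
    """Extracted per-stimulus features."""

    av_amp_mV: float
    epsp_peak_mV: float
    epsp_slope_mV_per_ms: float
    epsp_area_mV_ms: float
    noise_floor_mV: float


@dataclass(frozen=True)
class FeatureConfig:
    """Windows (ms, relative to the stimulus) and detection settings."""

    av_window_ms: Tuple[float, float] = (1.0, 4.0)
    epsp_window_ms: Tuple[float, float] = (4.0, 50.0)
    baseline_ms: float = 10.0
    threshold_mult: float = 3.0
    epsp_smooth_ms: float = 1.0
    av_smooth_ms: float = 0.2

    def __post_init__(self) -> None:
        if not (self.av_window_ms[0] < self.av_window_ms[1]
                <= self.epsp_window_ms[0] < self.epsp_window_ms[1]):
            raise ValueError("windows must be ordered: AV before EPSP")
        if self.baseline_ms <= 0 or self.threshold_mult < 0:
            raise ValueError("invalid baseline or threshold settings")


@dataclass
class IOCurve:
    """Normalized input-output curve and its Y = A + B*X fit."""

    stim_intensity: np.ndarray
    response: np.ndarray
    fit_A: float
    fit_B: float
    se_A: float
    se_B: float
    normalized: bool = True


@dataclass
class LTPTimecourse:
    """Baseline-normalized EPSP-slope time course and the LTP magnitude."""

    sweep_times_min: np.ndarray
    norm_epsp_slope: np.ndarray
    hfs_times_min: Tuple[float, ...]
    baseline_window_min: Tuple[float, float]
    post_window_min: Tuple[float, float]
    ltp_magnitude: float
    undefined: bool = False


def _boxcar(x: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return x
    kernel = np.ones(width_samples) / width_samples
    pad = width_samples // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    return out[pad:pad + x.size] if pad else out


def extract_features(sweep: Sweep, config: FeatureConfig = FeatureConfig(),
                     stim_index: int = 0) -> SweepFeatures:
    """Extract AV and EPSP features for one stimulus of a sweep.

    Baseline is the mean of the ``baseline_ms`` pre-stimulus; the noise floor
    is 1.4826 x MAD of the raw pre-stimulus samples.  The AV amplitude is
    max - min in the AV window; the EPSP peak is the magnitude of the
    smoothed extremum relative to baseline, zeroed below the detection
    threshold; slope is the least-squares line through the 20-80% rising
    phase; area the trapezoidal integral of |deflection| over the window.
    """
    t = sweep.time_ms
    v = sweep.voltage_mV
    stim = sweep.stim_times_ms[stim_index]
    if not t[0] <= stim <= t[-1]:
        raise ValueError("stimulus lies outside the recorded span")
    for w in (config.av_window_ms, config.epsp_window_ms):
        if stim + w[1] > t[-1] + 1e-9:
            raise ValueError("analysis window extends past the sweep")

    # In multi-stimulus sweeps the analysis windows end before the next
    # stimulus so its artifact and response stay out of this one's features.
    later = [s for s in sweep.stim_times_ms if s > stim]
    cutoff = min(later) - 0.5 if later else float("inf")

    base_sel = (t >= stim - config.baseline_ms) & (t < stim)
    if not base_sel.any():
        raise ValueError("no pre-stimulus baseline samples")
    baseline = float(v[base_sel].mean())
    mad = float(np.median(np.abs(v[base_sel] - np.median(v[base_sel]))))
    noise_floor = 1.4826 * mad

    dt_samples = lambda ms: max(1, int(round(ms * sweep.sample_rate_kHz)))

    av_sel = (t >= stim + config.av_window_ms[0]) & \
             (t <= min(stim + config.av_window_ms[1], cutoff))
    av_smooth = _boxcar(v, dt_samples(config.av_smooth_ms))
    av_amp = float(av_smooth[av_sel].max() - av_smooth[av_sel].min()) \
        if av_sel.any() else 0.0

    ep_sel = (t >= stim + config.epsp_window_ms[0]) & \
             (t <= min(stim + config.epsp_window_ms[1], cutoff))
    smooth = _boxcar(v, dt_samples(config.epsp_smooth_ms))
    defl = np.abs(smooth - baseline)
    win_defl = defl[ep_sel]
    peak = float(win_defl.max()) if ep_sel.any() else 0.0

    if peak < config.threshold_mult * noise_floor:
        return SweepFeatures(av_amp_mV=av_amp, epsp_peak_mV=0.0,
                             epsp_slope_mV_per_ms=0.0, epsp_area_mV_ms=0.0,
                             noise_floor_mV=noise_floor)

    win_t = t[ep_sel]
    peak_idx = int(win_defl.argmax())
    rising = win_defl[:peak_idx + 1]
    lo, hi = 0.2 * peak, 0.8 * peak
    above_lo = np.nonzero(rising >= lo)[0]
    start = int(above_lo[0]) if above_lo.size else 0
    above_hi = np.nonzero(rising[start:] >= hi)[0]
    stop = start + (int(above_hi[0]) if above_hi.size else peak_idx - start)
    if stop - start >= 1:
        seg_t = win_t[start:stop + 1]
        seg_v = rising[start:stop + 1]
        slope = float(np.polyfit(seg_t, seg_v, 1)[0])
    else:
        slope = float(rising[stop] - rising[max(stop - 1, 0)]) * \
            sweep.sample_rate_kHz
    area = float(np.trapezoid(win_defl, win_t))
    return SweepFeatures(av_amp_mV=av_amp, epsp_peak_mV=peak,
                         epsp_slope_mV_per_ms=abs(slope),
                         epsp_area_mV_ms=area, noise_floor_mV=noise_floor)


def ppf_ratio(first: SweepFeatures, second: SweepFeatures,
              on: str = "slope") -> float:
    """Paired-pulse ratio, second over first (slope-based by default)."""
    if on not in ("slope", "peak"):
        raise ValueError("on must be 'slope' or 'peak'")
    a = first.epsp_slope_mV_per_ms if on == "slope" else first.epsp_peak_mV
    b = second.epsp_slope_mV_per_ms if on == "slope" else second.epsp_peak_mV
    if a <= 0:
        raise UndefinedPPFError("conditioning EPSP absent; PPF undefined")
    return b / a


def fit_io_curve(points: Sequence[Tuple[float, float]],
                 normalize: bool = True) -> IOCurve:
    """Fit Y = A + B*X to an input-output curve by least squares.

    With ``normalize`` (the default pooling convention for input-output
    plots) stimuli are divided by the maximal stimulus and responses by the
    response at that stimulus before fitting.  Comparing raw gains between
    two curves requires ``normalize=False`` (or a shared normalization
    reference), since per-curve normalization maps every proportional curve
    to unit slope.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or np.unique(pts[:, 0]).size < 3:
        raise ValueError("need >= 3 distinct stimulus intensities")
    stim, resp = pts[:, 0], pts[:, 1]
    if normalize:
        imax = int(stim.argmax())
        if resp[imax] == 0:
            raise ValueError("zero response at the maximal stimulus; "
                             "cannot normalize")
        x = stim / stim[imax]
        y = resp / resp[imax]
    else:
        x, y = stim, resp
    fit = linregress(x, y)
    return IOCurve(stim_intensity=x, response=y,
                   fit_A=float(fit.intercept), fit_B=float(fit.slope),
                   se_A=float(fit.intercept_stderr), se_B=float(fit.stderr),
                   normalized=normalize)


def ltp_magnitude(sweep_times_min: Sequence[float],
                  epsp_slopes: Sequence[float],
                  hfs_times_min: Sequence[float],
                  post_window_min: Optional[Tuple[float, float]] = None,
                  min_baseline_sweeps: int = 10) -> LTPTimecourse:
    """LTP magnitude: post-HFS mean of baseline-normalized EPSP slopes.

    The baseline is every sweep before the first tetanus; the default post
    window is the last 15 minutes of the recording.  1.0 means no
    potentiation.  A zero mean baseline slope (the demyelinated case) flags
    the time course undefined rather than raising.
    """
    times = np.asarray(sweep_times_min, dtype=float)
    slopes = np.asarray(epsp_slopes, dtype=float)
    if times.shape != slopes.shape:
        raise ValueError("times and slopes must have equal length")
    hfs = tuple(float(h) for h in hfs_times_min)
    if not hfs:
        raise ValueError("at least one HFS time is required")
    first_hfs = min(hfs)
    base_sel = times < first_hfs
    if int(base_sel.sum()) < min_baseline_sweeps:
        raise ValueError(f"need >= {min_baseline_sweeps} baseline sweeps "
                         f"before the first HFS")
    base_mean = float(slopes[base_sel].mean())
    baseline_window = (float(times[base_sel].min()), float(times[base_sel].max()))
    if post_window_min is None:
        post_window_min = (float(times.max()) - 15.0, float(times.max()))
    post_sel = (times >= post_window_min[0]) & (times <= post_window_min[1])
    if base_mean <= 0:
        return LTPTimecourse(
            sweep_times_min=times, norm_epsp_slope=np.full_like(slopes, np.nan),
            hfs_times_min=hfs, baseline_window_min=baseline_window,
            post_window_min=tuple(post_window_min), ltp_magnitude=math.nan,
            undefined=True)
    norm = slopes / base_mean
    magnitude = float(norm[post_sel].mean()) if post_sel.any() else math.nan
    return LTPTimecourse(
        sweep_times_min=times, norm_epsp_slope=norm, hfs_times_min=hfs,
        baseline_window_min=baseline_window,
        post_window_min=tuple(post_window_min), ltp_magnitude=magnitude)
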