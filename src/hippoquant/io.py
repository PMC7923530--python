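"""File formats: NIfTI volumes, multi-page TIFF label stacks, sweep CSVs.

Conventions: NIfTI affines are honored only for voxel size (orientation is a
documented non-goal); label stacks are written one 75-nm section per TIFF
page with a plain-text sidecar holding the voxel dimensions; sweeps are CSV
(time_ms, voltage_mV) with stimulus times and the sample rate in commented
header lines.  CSV decimals use '.', UTF-8, mandatory header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from hippoquant.ephys import Sweep
from hippoquant.spines import LabeledStack

__all__ = [
    "read_nifti", "write_nifti", "read_label_tiff", "write_label_tiff",
    "read_sweep_csv", "write_sweep_csv", "FormatError",
]


class FormatError(ValueError):
    """Malformed input file (message names the offending field)."""


def write_nifti(grid: np.ndarray, voxel_mm: float, path) -> None:
    """Write a 3-D grid as NIfTI with an isotropic voxel-size affine."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise FormatError(f"expected a 3-D grid, got {grid.ndim}-D")
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float64), affine),
             str(path))


def read_nifti(path) -> Tuple[np.ndarray, float]:
    """Read a 3-D NIfTI; returns (grid, voxel_mm). Round trips bit-exactly."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"dimension: expected 3-D volume, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-6:
        raise FormatError(f"voxel size: anisotropic zooms {zooms} unsupported")
    return np.asarray(data, dtype=np.float64), float(zooms[0])


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_label_tiff(stack: LabeledStack, path) -> None:
    """Write a label stack as multi-page TIFF (one page per section) plus a
    JSON sidecar with the voxel dimensions in nm."""
    tifffile.imwrite(str(path), stack.labels.astype(np.uint8))
    _sidecar_path(path).write_text(json.dumps(
        {"voxel_nm": list(stack.voxel_nm)}), encoding="utf-8")


def read_label_tiff(path, sidecar=None) -> LabeledStack:
    """Read a multi-page TIFF label stack and its voxel-size sidecar."""
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"sidecar: missing voxel-size metadata {sidecar}")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    if "voxel_nm" not in meta or len(meta["voxel_nm"]) != 3:
        raise FormatError("sidecar: field 'voxel_nm' missing or malformed")
    labels = tifffile.imread(str(path))
    if labels.ndim == 2:
        labels = labels[None]
    bad = sorted(set(np.unique(labels).tolist()) - set(range(6)))
    if bad:
        raise FormatError(f"labels: invalid codes present: {bad}")
    return LabeledStack(labels=labels, voxel_nm=tuple(meta["voxel_nm"]))


def write_sweep_csv(sweep: Sweep, path) -> None:
    """Write a sweep as CSV with stimulus/sample-rate header comments."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# stim_times_ms: "
                 + ",".join(f"{t:.9g}" for t in sweep.stim_times_ms) + "\n")
        fh.write(f"# sample_rate_kHz: {sweep.sample_rate_kHz:.9g}\n")
        pd.DataFrame({"time_ms": sweep.time_ms,
                      "voltage_mV": sweep.voltage_mV}).to_csv(
            fh, index=False, float_format="%.10g")


def read_sweep_csv(path) -> Sweep:
    """Read a sweep CSV written by :func:`write_sweep_csv`."""
    stim_times = None
    rate = None
    with open(path, "r", encoding="utf-8") as fh:
        while True:
            line = fh.readline()
            if not line or not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key == "stim_times_ms":
                stim_times = tuple(float(x) for x in value.split(","))
            elif key == "sample_rate_kHz":
                rate = float(value)
    if stim_times is None:
        raise FormatError("header: missing '# stim_times_ms:' line")
    if rate is None:
        raise FormatError("header: missing '# sample_rate_kHz:' line")
    df = pd.read_csv(path, comment="#")
    for col in ("time_ms", "voltage_mV"):
        if col not in df.columns:
            raise FormatError(f"columns: missing {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError("time_ms: column must be strictly increasing")
    return Sweep(time_ms=t, voltage_mV=df["voltage_mV"].to_numpy(dtype=float),
                 stim_times_ms=stim_times, sample_rate_kHz=rate)
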