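"""Tag-record I/O, acceleration decomposition, orientation, speed and dive phases.

Conventions used throughout the package:

* depth is in metres, positive downward;
* the body axes are surge (positive toward the head), sway (left-right) and
  heave (dorso-ventral);
* pitch is in degrees, negative = head-down, computed from the gravity
  (low-pass) component of acceleration as ``arcsin(-g_surge / |g|)``;
* roll is ``atan2(g_sway, -g_heave)`` in (-180, 180];
* along-path speed is the non-negative magnitude ``|d(depth)/dt / sin(pitch)|``,
  defined only where ``|pitch| > 30 deg``.

A dive is any maximal interval deeper than 5 m. Within a dive, the descent
runs until pitch first becomes positive, the ascent starts at the last sample
with negative pitch, and the bottom phase lies between.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import AnalysisError, DataError, FormatError

__all__ = [
    "TagRecord",
    "OrientationSeries",
    "read_tag_record",
    "downsample",
    "select_filter_cutoff",
    "separate_acceleration",
    "compute_orientation",
    "compute_speed",
    "segment_dives",
    "segment_phases",
    "segment_dives_and_phases",
    "DIVE_THRESHOLD_M",
]

#: Minimum depth (m) that defines a dive; shallower is surface phase.
DIVE_THRESHOLD_M = 5.0

#: Pitch magnitude (deg) below which depth-rate speed is undefined.
SPEED_PITCH_MIN_DEG = 30.0

CSV_COLUMNS = ["time_s", "depth_m", "ax", "ay", "az"]


@dataclass
class TagRecord:
    """A multirate tag record: depth plus triaxial acceleration.

    ``depth`` is sampled at ``depth_rate`` Hz; ``accel`` is an (n, 3) array of
    (surge, sway, heave) in m/s^2 at ``accel_rate`` Hz.
    """

    deployment_id: str
    depth: np.ndarray
    accel: np.ndarray
    depth_rate: float
    accel_rate: float
    start_time: str = "1970-01-01T00:00:00"

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.depth_rate <= 0 or self.accel_rate <= 0:
            raise DataError("sampling rates must be strictly positive")
        if self.accel_rate < self.depth_rate:
            raise DataError("accel_rate must be >= depth_rate")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise DataError("accel must be an (n, 3) array (surge, sway, heave)")
        if not np.all(np.isfinite(self.depth)):
            raise DataError("depth contains non-finite samples")
        if np.any(self.depth < -1.0):
            raise DataError("depth below -1 m: sensor or sign convention problem")

    @property
    def surge(self):
        return self.accel[:, 0]

    @property
    def sway(self):
        return self.accel[:, 1]

    @property
    def heave(self):
        return self.accel[:, 2]


@dataclass
class OrientationSeries:
    """Pitch and roll (degrees) on the time base of the source acceleration."""

    pitch: np.ndarray
    roll: np.ndarray

    def __post_init__(self):
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        ok = np.isfinite(self.pitch)
        if np.any(np.abs(self.pitch[ok]) > 90.0 + 1e-9):
            raise DataError("pitch outside [-90, 90] deg")


def _infer_rate(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise DataError("time column is not strictly increasing")
    return float(round(1.0 / np.median(dt), 6))


def read_tag_record(path, format: str | None = None) -> TagRecord:
    """Read a tag record from CSV or NetCDF.

    CSV dialect: columns ``time_s, depth_m, ax, ay, az`` sampled at a single
    rate (depth and acceleration share the time base; use :func:`downsample`
    afterwards). NetCDF dialect: variables ``depth`` (dim ``time_depth``) and
    ``ax/ay/az`` (dim ``time_accel``) with global attributes ``depth_rate``,
    ``accel_rate``, ``deployment_id`` and ``start_time``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "netcdf" if path.endswith((".nc", ".cdf", ".netcdf")) else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in CSV_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"tag CSV {path!r} is missing channel {col!r}")
        rate = _infer_rate(df["time_s"].to_numpy(dtype=float))
        return TagRecord(
            deployment_id=os.path.splitext(os.path.basename(path))[0],
            depth=df["depth_m"].to_numpy(dtype=float),
            accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
            depth_rate=rate,
            accel_rate=rate,
        )
    if format == "netcdf":
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        for name in ("depth", "ax", "ay", "az"):
            if name not in ds:
                raise FormatError(f"tag NetCDF {path!r} is missing channel {name!r}")
        return TagRecord(
            deployment_id=str(ds.attrs.get(
                "deployment_id", os.path.splitext(os.path.basename(path))[0]
            )),
            depth=ds["depth"].values,
            accel=np.column_stack([ds["ax"].values, ds["ay"].values, ds["az"].values]),
            depth_rate=float(ds.attrs["depth_rate"]),
            accel_rate=float(ds.attrs["accel_rate"]),
            start_time=str(ds.attrs.get("start_time", "1970-01-01T00:00:00")),
        )
    raise ValueError(f"unknown tag format {format!r}")


def _antialias_decimate(x: np.ndarray, source: float, target: float) -> np.ndarray:
    if target > source:
        raise ValueError(f"target rate {target} exceeds source rate {source}")
    q = source / target
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"target rate {target} does not divide source rate {source}")
    q = int(round(q))
    if q == 1:
        return x.copy()
    # zero-phase 4th-order Butterworth anti-alias filter, then decimate
    sos = signal.butter(4, 0.45 * target, btype="low", fs=source, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=0)
    return y[::q]


def downsample(record: TagRecord, depth_to: float = 1.0,
               accel_to: float = 25.0) -> TagRecord:
    """Anti-alias low-pass then decimate depth and acceleration to new rates."""
    return TagRecord(
        deployment_id=record.deployment_id,
        depth=_antialias_decimate(record.depth, record.depth_rate, depth_to),
        accel=_antialias_decimate(record.accel, record.accel_rate, accel_to),
        depth_rate=depth_to,
        accel_rate=accel_to,
        start_time=record.start_time,
    )


def select_filter_cutoff(sway: np.ndarray, rate: float,
                         min_peak_snr: float = 10.0,
                         min_valley_contrast: float = 4.0) -> float:
    """Choose the gravity/dynamic separation cutoff (Hz) from the sway PSD.

    The dominant stroking peak is the largest Welch-PSD peak above 0.5 Hz; the
    cutoff is the frequency of the PSD minimum between the low-frequency
    (postural) band and that peak. If no clear minimum exists (no postural
    band rising above the valley), falls back to half the stroking frequency.

    Raises :class:`AnalysisError` if the series is shorter than 60 s or shows
    no dominant stroking peak (peak < ``min_peak_snr`` times the median
    high-band PSD, e.g. white noise).
    """
    sway = np.asarray(sway, dtype=float)
    if sway.size < 60 * rate:
        raise AnalysisError("sway series shorter than 60 s; cannot choose cutoff")
    nperseg = min(sway.size, 1024)
    f, psd = signal.welch(sway, fs=rate, nperseg=nperseg)
    high = f > 0.5
    if not np.any(high):
        raise AnalysisError("sampling rate too low to resolve stroking band")
    ipk = np.nonzero(high)[0][np.argmax(psd[high])]
    f_peak = f[ipk]
    if psd[ipk] < min_peak_snr * np.median(psd[high]):
        raise AnalysisError("no dominant stroking peak in sway PSD")
    # postural band: largest PSD between 0.05 Hz and 0.5 Hz
    low = (f >= 0.05) & (f <= 0.5)
    if not np.any(low):
        return f_peak / 2.0
    ilow = np.nonzero(low)[0][np.argmax(psd[low])]
    mid = (f > f[ilow]) & (f < f_peak)
    if not np.any(mid):
        return f_peak / 2.0
    imin = np.nonzero(mid)[0][np.argmin(psd[mid])]
    # a clear valley must sit well below both shoulders
    if psd[imin] * min_valley_contrast >= min(psd[ilow], psd[ipk]):
        return f_peak / 2.0
    return float(f[imin])


def separate_acceleration(accel: np.ndarray, cutoff: float, rate: float):
    """Split measured acceleration into gravity (low-pass) and dynamic parts.

    Zero-phase 4th-order Butterworth low-pass per axis gives the gravity
    component; the dynamic component is the residual, so
    ``gravity + dynamic == accel`` exactly.
    """
    accel = np.asarray(accel, dtype=float)
    if not (0.0 < cutoff < rate / 2.0):
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist)")
    sos = signal.butter(4, cutoff, btype="low", fs=rate, output="sos")
    gravity = signal.sosfiltfilt(sos, accel, axis=0)
    return gravity, accel - gravity


def compute_orientation(gravity: np.ndarray) -> OrientationSeries:
    """Pitch and roll (deg) from the gravity acceleration components.

    pitch = arcsin(-g_surge / |g|), negative head-down; roll =
    atan2(g_sway, -g_heave). Samples with zero gravity norm get NaN.
    """
    g = np.asarray(gravity, dtype=float)
    norm = np.linalg.norm(g, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(norm > 0, -g[:, 0] / np.where(norm > 0, norm, 1.0), np.nan)
        pitch = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
        roll = np.degrees(np.arctan2(g[:, 1], -g[:, 2]))
    pitch[norm == 0] = np.nan
    roll[norm == 0] = np.nan
    return OrientationSeries(pitch=pitch, roll=roll)


def compute_speed(depth: np.ndarray, pitch: np.ndarray) -> np.ndarray:
    """Along-path speed (m/s) from 1 Hz depth rate and pitch.

    ``U_t = |(d_{t+1} - d_t) / sin(p_t)|`` where ``|p_t| > 30 deg``; elsewhere
    (and at the final sample, which has no forward difference) NaN.
    """
    depth = np.asarray(depth, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    if depth.shape != pitch.shape:
        raise ValueError("depth and pitch must be aligned")
    u = np.full(depth.shape, np.nan)
    dd = np.diff(depth)
    steep = np.abs(pitch[:-1]) > SPEED_PITCH_MIN_DEG
    sinp = np.sin(np.radians(pitch[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        u[:-1] = np.where(steep, np.abs(dd / sinp), np.nan)
    return u


def segment_dives(depth: np.ndarray, threshold: float = DIVE_THRESHOLD_M) -> pd.DataFrame:
    """Find dives: maximal 1 Hz intervals with depth > ``threshold``.

    Returns a DataFrame with ``dive_id, start, end, max_depth`` where
    ``start``/``end`` are sample indices (end exclusive).
    """
    depth = np.asarray(depth, dtype=float)
    deep = depth > threshold
    edges = np.diff(deep.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if deep.size and deep[0]:
        starts.insert(0, 0)
    if deep.size and deep[-1]:
        ends.append(deep.size)
    rows = [
        {"dive_id": i, "start": s, "end": e, "max_depth": float(depth[s:e].max())}
        for i, (s, e) in enumerate(zip(starts, ends))
    ]
    return pd.DataFrame(rows, columns=["dive_id", "start", "end", "max_depth"])


def segment_phases(depth: np.ndarray, pitch: np.ndarray, start: int, end: int) -> dict:
    """Phase boundaries within one dive (absolute sample indices).

    descent: [start, descent_end); bottom: [descent_end, ascent_start);
    ascent: [ascent_start, end). The bottom phase starts where pitch first
    exceeds 0 and the ascent starts at the last sample with negative pitch.
    If pitch never turns positive the dive is descent-only and flagged.
    """
    p = np.asarray(pitch, dtype=float)[start:end]
    pos = np.nonzero(p > 0)[0]
    if pos.size == 0:
        return {"descent_end": end, "ascent_start": end, "flag": "no_bottom"}
    descent_end = start + int(pos[0])
    neg = np.nonzero(p < 0)[0]
    ascent_start = start + int(neg[-1]) if neg.size else descent_end
    ascent_start = max(ascent_start, descent_end)
    return {"descent_end": descent_end, "ascent_start": ascent_start, "flag": ""}


def segment_dives_and_phases(depth: np.ndarray, pitch: np.ndarray,
                             threshold: float = DIVE_THRESHOLD_M) -> pd.DataFrame:
    """Dive table with phase boundaries: one row per dive."""
    dives = segment_dives(depth, threshold)
    extra = [segment_phases(depth, pitch, int(r.start), int(r.end))
             for r in dives.itertuples()]
    if len(dives):
        dives = dives.join(pd.DataFrame(extra, index=dives.index))
    else:
        dives = dives.reindex(
            columns=list(dives.columns) + ["descent_end", "ascent_start", "flag"]
        )
    return dives
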