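"""Stroke and glide detection from high-pass (dynamic) sway acceleration.

Phocid seals propel themselves with lateral body undulations, so active
stroking shows up as oscillations of the dynamic sway channel. A *half-stroke*
is the interval between two consecutive zero-crossings whose peak amplitude
reaches the detection threshold; per-stroke effort is summarised as the RMS of
dynamic sway over the half-stroke. A *glide* is a maximal interval containing
no detected half-stroke, with |dynamic sway| below the threshold throughout,
lasting at least a configurable minimum duration.

Zero-crossing tie-break: a sample that is exactly zero belongs to the
following half-stroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HalfStroke",
    "GlideSegment",
    "StrokeDetectionConfig",
    "detect_half_strokes",
    "half_stroke_rms",
    "mean_descent_rms",
    "detect_glides",
    "stroke_cessation_depth",
    "circular_variance",
    "build_glide_segment",
]


@dataclass
class HalfStroke:
    """One half-stroke: [start_s, end_s) between consecutive zero-crossings."""

    start_s: float
    end_s: float
    rms: float
    mean_depth: float | None = None

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("half-stroke must have end > start")
        if self.rms < 0:
            raise ValueError("rms must be non-negative")


@dataclass
class StrokeDetectionConfig:
    """Stroke/glide detection settings.

    threshold            peak |dynamic sway| (m/s^2) for a half-stroke;
                         individual-specific in practice
    min_glide_duration   shortest interval (s) reported as a glide
    rms_depth_window     depth band (m) for descent mean RMS
    min_half_strokes     half-strokes required for a defined descent mean RMS
    """

    threshold: float = 0.5
    min_glide_duration: float = 5.0
    rms_depth_window: tuple = (5.0, 30.0)
    min_half_strokes: int = 3

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_glide_duration <= 0:
            raise ValueError("min_glide_duration must be positive")


@dataclass
class GlideSegment:
    """A contiguous passive glide with aligned per-second arrays.

    ``speed`` may contain NaN where undefined (shallow pitch, final sample).
    """

    dive_id: int
    start_s: float
    end_s: float
    depth: np.ndarray
    pitch: np.ndarray
    speed: np.ndarray
    mean_pitch: float = float("nan")
    circ_var_pitch: float = float("nan")
    circ_var_roll: float = float("nan")

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if not (len(self.depth) == len(self.pitch) == len(self.speed)):
            raise ValueError("GlideSegment per-second arrays must be aligned")

    @property
    def start_depth(self) -> float:
        return float(self.depth[0])

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def _zero_crossing_boundaries(x: np.ndarray) -> np.ndarray:
    """Segment boundaries: series start, every zero-crossing, series end.

    A crossing sits at index i when the sign changes between i-1 and i; an
    exactly-zero sample is a boundary itself (it opens the next half-stroke).
    """
    n = x.size
    cross = np.nonzero(x[:-1] * x[1:] < 0)[0] + 1
    zeros = np.nonzero(x == 0)[0]
    b = np.unique(np.concatenate([[0], cross, zeros, [n]]))
    return b[(b >= 0) & (b <= n)]


def detect_half_strokes(dynamic_sway: np.ndarray, rate: float,
                        threshold: float) -> list[HalfStroke]:
    """Half-strokes: between-crossing segments whose peak |amplitude| >= threshold."""
    x = np.asarray(dynamic_sway, dtype=float)
    out = []
    b = _zero_crossing_boundaries(x)
    for s, e in zip(b[:-1], b[1:]):
        seg = x[s:e]
        if seg.size and np.max(np.abs(seg)) >= threshold:
            out.append(HalfStroke(start_s=s / rate, end_s=e / rate,
                                  rms=half_stroke_rms(seg)))
    return out


def half_stroke_rms(segment: np.ndarray) -> float:
    """Root mean square of dynamic sway over a half-stroke slice."""
    seg = np.asarray(segment, dtype=float)
    if seg.size == 0:
        raise ValueError("empty half-stroke slice")
    return float(np.sqrt(np.mean(seg**2)))


def _depth_at(time_s, depth_1hz):
    """Linear interpolation of the 1 Hz depth series at arbitrary seconds."""
    t = np.arange(len(depth_1hz), dtype=float)
    return np.interp(time_s, t, depth_1hz)


def mean_descent_rms(half_strokes: list[HalfStroke], depth_1hz: np.ndarray,
                     descent_start_s: float, descent_end_s: float,
                     depth_window: tuple = (5.0, 30.0),
                     min_half_strokes: int = 3) -> float:
    """Mean per-half-stroke RMS over the 5-30 m band of the descent.

    Only half-strokes lying wholly inside the descent interval *and* wholly
    inside the depth window count ("complete" half-strokes); returns NaN when
    fewer than ``min_half_strokes`` qualify.
    """
    lo, hi = depth_window
    vals = []
    for hs in half_strokes:
        if hs.start_s < descent_start_s or hs.end_s > descent_end_s:
            continue
        d0 = _depth_at(hs.start_s, depth_1hz)
        d1 = _depth_at(hs.end_s, depth_1hz)
        if min(d0, d1) >= lo and max(d0, d1) <= hi:
            vals.append(hs.rms)
    if len(vals) < min_half_strokes:
        return float("nan")
    return float(np.mean(vals))


def detect_glides(dynamic_sway: np.ndarray, rate: float,
                  config: StrokeDetectionConfig) -> list[tuple]:
    """Maximal stroke-free intervals, in seconds.

    A sample is glide-eligible when |dynamic sway| < threshold and it is not
    inside any detected half-stroke; runs of eligible samples lasting at least
    ``min_glide_duration`` are reported as (start_s, end_s) pairs.
    """
    x = np.asarray(dynamic_sway, dtype=float)
    quiet = np.abs(x) < config.threshold
    for hs in detect_half_strokes(x, rate, config.threshold):
        quiet[int(round(hs.start_s * rate)):int(round(hs.end_s * rate))] = False
    out = []
    n = x.size
    i = 0
    min_len = int(round(config.min_glide_duration * rate))
    while i < n:
        if quiet[i]:
            j = i
            while j < n and quiet[j]:
                j += 1
            if j - i >= min_len:
                out.append((i / rate, j / rate))
            i = j
        else:
            i += 1
    return out


def stroke_cessation_depth(half_strokes: list[HalfStroke], glides: list[tuple],
                           depth_1hz: np.ndarray, descent_start_s: float,
                           descent_end_s: float) -> float:
    """Depth (m) at which descent stroking gives way to gliding.

    The depth at the end of the last descent half-stroke preceding the first
    glide that starts within the descent. NaN when the descent has no
    half-strokes or no glide (stroking throughout).
    """
    descent_glides = [g for g in glides
                      if descent_start_s <= g[0] < descent_end_s]
    if not descent_glides:
        return float("nan")
    g0 = min(g[0] for g in descent_glides)
    prior = [hs for hs in half_strokes
             if hs.end_s <= g0 + 1e-9 and hs.start_s >= descent_start_s - 1e-9]
    if not prior:
        return float("nan")
    last = max(prior, key=lambda hs: hs.end_s)
    return float(_depth_at(last.end_s, depth_1hz))


def circular_variance(angles_deg) -> float:
    """Circular variance of angles in degrees: 1 - mean resultant length.

    0 for identical angles, 1 for angles spread uniformly around the circle.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise ValueError("circular variance requires at least 2 angles")
    return float(stats.circvar(np.radians(a)))


def build_glide_segment(dive_id: int, start_s: float, end_s: float,
                        depth_1hz: np.ndarray, pitch_1hz: np.ndarray,
                        roll_1hz: np.ndarray, speed_1hz: np.ndarray) -> GlideSegment:
    """Cut a per-second GlideSegment out of aligned 1 Hz series.

    ``start_s``/``end_s`` are seconds on the 1 Hz time base; stability metrics
    (mean pitch, circular variance of pitch and roll) are computed here.
    """
    s, e = int(np.ceil(start_s)), int(np.floor(end_s))
    e = min(e, len(depth_1hz))
    if e - s < 2:
        raise ValueError("glide too short to build a per-second segment")
    pitch = pitch_1hz[s:e]
    roll = roll_1hz[s:e]
    return GlideSegment(
        dive_id=dive_id,
        start_s=float(s),
        end_s=float(e),
        depth=depth_1hz[s:e],
        pitch=pitch,
        speed=speed_1hz[s:e],
        mean_pitch=float(np.nanmean(pitch)),
        circ_var_pitch=circular_variance(pitch),
        circ_var_roll=circular_variance(roll),
    )
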