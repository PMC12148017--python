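"""Synthetic dive generator with known ground truth.

Because no raw seal-tag data are distributed, every pipeline stage is
exercised against simulated dives whose physics, behavioural template and
noise are fully known:

* a steep stroking descent (default pitch -75 deg, speed 1.84 m/s, sinusoidal
  sway at 1.4 Hz) from the surface to the stroke-cessation depth;
* a passive glide governed by the hydrodynamic glide model, integrated
  *closed-loop* (speed and depth both propagated, dt = 0.04 s) from the
  cessation depth down to the maximum dive depth;
* a quiet bottom phase and a stroking ascent to close the dive.

The closed-loop generator is deliberately asymmetric to the estimator, which
simulates speed *open-loop* over the measured depth: the estimator never sees
the generator's internals. Default parameter values follow the deployment
summary the package is calibrated against (mass 313 kg, descent pitch
-74.9 deg, speed 1.84 m/s, cessation 18.8 m, DRAV 21.1 ml/kg).

All randomness derives from the ``seed`` field, so outputs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .glide_physics import (Environment, GRAVITY, ModelParams, Morphometry,
                            glide_acceleration)
from .stroke_glide import GlideSegment, circular_variance
from .tag_kinematics import TagRecord

__all__ = [
    "TruthParams",
    "SyntheticDive",
    "simulate_dive",
    "make_glide_segment",
    "sample_truths",
    "make_cohort",
    "write_fixture",
    "TAG_RATE_HZ",
]

#: Native sampling rate of the synthetic tag record (Hz).
TAG_RATE_HZ = 25.0


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of one synthetic dive."""

    mass: float = 313.0            # kg
    girth: float = 1.70            # m
    cd: float = 0.03
    rho_tissue: float = 1037.0     # kg/m^3
    drav: float = 21.1             # ml/kg
    descent_pitch: float = -75.0   # deg
    descent_speed: float = 1.84    # m/s during stroking
    stroke_freq: float = 1.4       # Hz
    stroke_amp: float = 2.0        # m/s^2 peak dynamic sway
    cessation_depth: float = 18.8  # m
    max_depth: float = 435.0       # m
    speed_noise_sd: float = 0.0    # m/s, on measured glide speed
    accel_noise_sd: float = 0.0    # m/s^2, on the 25 Hz channels
    depth_noise_sd: float = 0.0    # m, on the 25 Hz depth channel
    seed: int = 0

    def __post_init__(self):
        for name in ("mass", "girth", "cd", "rho_tissue", "descent_speed",
                     "stroke_freq", "stroke_amp", "cessation_depth", "max_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.drav < 0:
            raise ValueError("drav must be non-negative")

    @property
    def v_air0(self) -> float:
        """Surface air volume (m^3)."""
        return self.mass * self.drav * 1e-6

    def morphometry(self) -> Morphometry:
        return Morphometry(mass=self.mass, girth=self.girth)

    def model_params(self) -> ModelParams:
        return ModelParams(cd=self.cd, rho_tissue=self.rho_tissue)


@dataclass
class SyntheticDive:
    """A tag-format record plus its generating truth."""

    record: TagRecord
    truth: TruthParams
    glide_start_s: float
    glide_end_s: float
    cessation_depth_actual: float


def _integrate_glide(truth: TruthParams, env: Environment, start_depth: float,
                     u0: float, end_depth: float, dt: float):
    """Closed-loop glide integration: returns fine (t, depth, speed) arrays."""
    params = truth.model_params()
    morph = truth.morphometry()
    sinp = abs(np.sin(np.radians(truth.descent_pitch)))
    d, u, t = float(start_depth), float(u0), 0.0
    ts, ds, us = [t], [d], [u]
    while d < end_depth and t < 3600.0:
        a = glide_acceleration(u, d, truth.descent_pitch, truth.v_air0,
                               params, morph, env)
        u = max(u + a * dt, 0.0)
        d += u * sinp * dt
        t += dt
        ts.append(t)
        ds.append(d)
        us.append(u)
        if u == 0.0 and a <= 0.0:
            break  # stalled: buoyancy stopped the glide
    return np.array(ts), np.array(ds), np.array(us)


def make_glide_segment(truth: TruthParams, env: Environment,
                       start_depth: float | None = None,
                       u0: float | None = None,
                       end_depth: float = 50.0,
                       dive_id: int = 0, dt: float = 0.05,
                       rng: np.random.Generator | None = None) -> GlideSegment:
    """Generate one per-second glide segment as the tag pipeline would see it.

    Integrates the glide model closed-loop at fine resolution, samples depth
    at whole seconds, and derives the measured speed as the forward difference
    of the 1 Hz depth divided by |sin(pitch)| — exactly what the kinematics
    stage computes from a real record — plus Gaussian noise of s.d.
    ``truth.speed_noise_sd``. The final speed sample is NaN (no forward
    difference).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    start = truth.cessation_depth if start_depth is None else start_depth
    u_start = truth.descent_speed if u0 is None else u0
    ts, ds, _ = _integrate_glide(truth, env, start, u_start, end_depth, dt)
    n_sec = int(ts[-1])
    if n_sec < 2:
        raise ValueError("glide too short; lower start_depth or raise end_depth")
    sec = np.arange(n_sec + 1, dtype=float)
    depth = np.interp(sec, ts, ds)
    sinp = abs(np.sin(np.radians(truth.descent_pitch)))
    speed = np.empty(n_sec + 1)
    speed[:-1] = np.diff(depth) / sinp
    if truth.speed_noise_sd > 0:
        speed[:-1] += rng.normal(0.0, truth.speed_noise_sd, n_sec)
    speed[-1] = np.nan
    pitch = np.full(n_sec + 1, truth.descent_pitch)
    return GlideSegment(
        dive_id=dive_id, start_s=0.0, end_s=float(n_sec + 1),
        depth=depth, pitch=pitch, speed=speed,
        mean_pitch=truth.descent_pitch,
        circ_var_pitch=0.0, circ_var_roll=0.0,
    )


def simulate_dive(truth: TruthParams, env: Environment,
                  dive_index: int = 0) -> SyntheticDive:
    """Build a full tag-format synthetic dive.

    Phases: 8 s surface, stroking descent to the cessation depth (duration
    quantised to whole half-stroke cycles so stroking ends on a sway
    zero-crossing), closed-loop glide to the maximum depth, 40 s quiet bottom,
    stroking ascent, 8 s surface. Acceleration channels carry gravity
    components consistent with the programmed pitch, the sway stroking
    oscillation, and optional Gaussian noise.
    """
    if truth.cessation_depth >= truth.max_depth:
        raise ValueError("cessation_depth must be shallower than max_depth")
    rng = np.random.default_rng(truth.seed)
    dt = 1.0 / TAG_RATE_HZ
    sinp = abs(np.sin(np.radians(truth.descent_pitch)))

    segs = []  # (depth array, pitch value, stroking flag)

    def block(n, depth, pitch, stroking):
        segs.append((np.asarray(depth, dtype=float) * np.ones(n),
                     float(pitch), bool(stroking)))

    # surface
    block(int(8 * TAG_RATE_HZ), 0.0, 0.0, False)

    # stroking descent: constant vertical rate, whole half-stroke cycles
    v_rate = truth.descent_speed * sinp
    half_period = 1.0 / (2.0 * truth.stroke_freq)
    t_strk = max(half_period,
                 round((truth.cessation_depth / v_rate) / half_period) * half_period)
    n_strk = int(round(t_strk * TAG_RATE_HZ))
    cess_actual = v_rate * n_strk * dt
    segs.append((v_rate * dt * np.arange(1, n_strk + 1),
                 truth.descent_pitch, True))
    glide_start_s = 8.0 + n_strk * dt

    # passive glide (closed loop), sampled on the tag clock
    ts, ds, _ = _integrate_glide(truth, env, cess_actual, truth.descent_speed,
                                 truth.max_depth, dt=0.04)
    tg = np.arange(dt, ts[-1], dt)
    segs.append((np.interp(tg, ts, ds), truth.descent_pitch, False))
    glide_end_s = glide_start_s + (tg.size) * dt
    bottom_depth = float(np.interp(tg[-1], ts, ds)) if tg.size else cess_actual

    # quiet bottom, then stroking ascent
    block(int(40 * TAG_RATE_HZ), bottom_depth, 5.0, False)
    ascent_rate = 1.5
    n_asc = int(round(bottom_depth / ascent_rate * TAG_RATE_HZ))
    segs.append((bottom_depth - ascent_rate * dt * np.arange(1, n_asc + 1),
                 70.0, True))
    block(int(8 * TAG_RATE_HZ), 0.0, 0.0, False)

    depth = np.concatenate([s[0] for s in segs])
    depth = np.maximum(depth, 0.0)
    pitch = np.concatenate([np.full(s[0].size, s[1]) for s in segs])
    sway_dyn = np.zeros(depth.size)
    pos = 0
    for d_arr, _, stroking in segs:
        n = d_arr.size
        if stroking:
            t_loc = dt * np.arange(n)
            sway_dyn[pos:pos + n] = truth.stroke_amp * np.sin(
                2.0 * np.pi * truth.stroke_freq * t_loc)
        pos += n

    pr = np.radians(pitch)
    gravity = np.column_stack([
        -GRAVITY * np.sin(pr),
        np.zeros(depth.size),
        -GRAVITY * np.cos(pr),
    ])
    accel = gravity + np.column_stack(
        [np.zeros(depth.size), sway_dyn, np.zeros(depth.size)])
    if truth.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, truth.accel_noise_sd, accel.shape)
    if truth.depth_noise_sd > 0:
        depth = np.maximum(depth + rng.normal(0.0, truth.depth_noise_sd,
                                              depth.size), 0.0)

    record = TagRecord(
        deployment_id=f"sim_{dive_index:03d}",
        depth=depth, accel=accel,
        depth_rate=TAG_RATE_HZ, accel_rate=TAG_RATE_HZ,
    )
    return SyntheticDive(record=record, truth=truth,
                         glide_start_s=glide_start_s, glide_end_s=glide_end_s,
                         cessation_depth_actual=cess_actual)


def sample_truths(n_dives: int, seed: int = 0,
                  drav_depth_slope: float | None = None,
                  drav_tissue_slope: float | None = None,
                  drav_scatter_sd: float = 3.0,
                  **overrides) -> list[TruthParams]:
    """Draw per-dive ground-truth parameters for a cohort.

    Defaults mirror the calibration deployment summary: maximum depth uniform
    over 100-700 m, tissue density normal (1037.0, 1.7) kg/m^3, cessation
    depth normal (18.8, 5.0) m, DRAV normal (21.1, 8.1) ml/kg clipped to the
    observed 1.3-53.7 ml/kg range. Passing ``drav_depth_slope`` (ml/kg per m)
    and/or ``drav_tissue_slope`` (ml/kg per kg/m^3) instead imposes a known
    linear dependence of DRAV on depth and tissue density, with Gaussian
    scatter, so pipeline-level trend checks have a programmed sign.
    Any :class:`TruthParams` field can be fixed via keyword overrides.
    """
    if n_dives < 1:
        raise ValueError("n_dives must be >= 1")
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_dives):
        max_depth = rng.uniform(100.0, 700.0)
        rho_tissue = float(np.clip(rng.normal(1037.0, 1.7), 1028.0, 1046.0))
        cessation = float(np.clip(rng.normal(18.8, 5.0), 8.0, 28.0))
        if drav_depth_slope is None and drav_tissue_slope is None:
            drav = float(np.clip(rng.normal(21.1, 8.1), 1.3, 53.7))
        else:
            drav = 21.1
            drav += (drav_depth_slope or 0.0) * (max_depth - 400.0)
            drav += (drav_tissue_slope or 0.0) * (rho_tissue - 1037.0)
            drav += rng.normal(0.0, drav_scatter_sd)
            drav = float(np.clip(drav, 1.3, 53.7))
        fields = dict(
            max_depth=float(max_depth), rho_tissue=rho_tissue,
            cessation_depth=cessation, drav=drav,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fields.update(overrides)
        truths.append(TruthParams(**fields))
    return truths


def make_cohort(n_dives: int, env: Environment, seed: int = 0,
                **kwargs) -> list[SyntheticDive]:
    """Simulate a reproducible cohort of full synthetic dives."""
    truths = sample_truths(n_dives, seed=seed, **kwargs)
    return [simulate_dive(t, env, dive_index=i) for i, t in enumerate(truths)]


def write_fixture(dives, path, format: str = "csv") -> list[str]:
    """Write dives in the tag dialect plus a ``truth.csv`` sidecar.

    Returns the list of files written. The sidecar carries every
    :class:`TruthParams` field, the realised cessation depth, and the
    programmed glide interval per dive.
    """
    if isinstance(dives, SyntheticDive):
        dives = [dives]
    path = os.fspath(path)
    if not os.path.isdir(path):
        raise FileNotFoundError(f"output directory does not exist: {path!r}")
    written = []
    truth_rows = []
    for dive in dives:
        rec = dive.record
        stem = os.path.join(path, rec.deployment_id)
        if format == "csv":
            fn = stem + ".csv"
            t = np.arange(rec.depth.size) / rec.depth_rate
            pd.DataFrame({
                "time_s": t, "depth_m": rec.depth,
                "ax": rec.accel[:, 0], "ay": rec.accel[:, 1],
                "az": rec.accel[:, 2],
            }).to_csv(fn, index=False, float_format="%.17g")
        elif format == "netcdf":
            import xarray as xr

            fn = stem + ".nc"
            ds = xr.Dataset(
                {
                    "depth": ("time_depth", rec.depth),
                    "ax": ("time_accel", rec.accel[:, 0]),
                    "ay": ("time_accel", rec.accel[:, 1]),
                    "az": ("time_accel", rec.accel[:, 2]),
                },
                attrs={
                    "deployment_id": rec.deployment_id,
                    "depth_rate": rec.depth_rate,
                    "accel_rate": rec.accel_rate,
                    "start_time": rec.start_time,
                },
            )
            ds.to_netcdf(fn, engine="scipy")
        else:
            raise ValueError(f"unknown fixture format {format!r}")
        written.append(fn)
        row = {"deployment_id": rec.deployment_id}
        row.update(asdict(dive.truth))
        row["cessation_depth_actual"] = dive.cessation_depth_actual
        row["glide_start_s"] = dive.glide_start_s
        row["glide_end_s"] = dive.glide_end_s
        truth_rows.append(row)
    sidecar = os.path.join(path, "truth.csv")
    pd.DataFrame(truth_rows).to_csv(sidecar, index=False)
    written.append(sidecar)
    return written
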