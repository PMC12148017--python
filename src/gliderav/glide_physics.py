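"""Hydrodynamic glide model for a passively gliding, negatively buoyant diver.

The model balances three along-path forces on a gliding animal at pitch ``p``
(degrees, negative = head-down), depth ``d`` (m, positive down) and speed ``U``
(m/s, non-negative along-path magnitude):

* quadratic drag, opposing motion:            -(rho_sw * A_f * C_d / 2m) * U^2
* tissue (non-air) net buoyancy along path:    g sin(p) * (rho_sw/rho_tissue - 1)
* respiratory-air buoyancy along path:         g sin(p)/m * V_air(0) *
                                               (rho_sw/(1 + 0.1 d) - rho_air)

The air space carried from the surface, ``V_air(0)`` (m^3), compresses with
depth following Boyle's law, ``V(d) = V(0) / (1 + 0.1 d)``, while the tissue is
treated as incompressible over the shallow depths analysed. Acceleration is
positive when the animal speeds up along its movement direction, so for a
negatively buoyant animal descending steeply the tissue term is propulsive and
the air term resists descent near the surface.

Speed during a glide is propagated with an explicit 1-s update
``U_{t+1} = U_t + a(U_t, d_t, p_t)`` using the *measured* depth and pitch at
each step (open loop in depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Morphometry",
    "Environment",
    "ModelParams",
    "GlideState",
    "frontal_area",
    "air_compression_fraction",
    "seawater_density",
    "glide_acceleration",
    "simulate_glide_speed",
    "terminal_speed",
    "eos80_density",
]

#: Air density at the surface (kg/m^3) at 101,325 Pa and 15 degC.
RHO_AIR = 1.225
#: Gravitational acceleration (m/s^2).
GRAVITY = 9.81


def frontal_area(girth: float) -> float:
    """Frontal surface area (m^2) of a circular cross-section of girth ``G`` (m).

    A_f = pi * (G / 2 pi)^2 = G^2 / (4 pi).
    """
    if girth <= 0:
        raise ValueError(f"girth must be positive, got {girth}")
    return girth**2 / (4.0 * np.pi)


def air_compression_fraction(d):
    """Boyle's-law fraction of surface air volume remaining at depth ``d`` (m).

    Returns 1/(1 + 0.1 d): 1 at the surface, 0.5 at 10 m (one extra
    atmosphere), 1/6 at 50 m. Strictly decreasing in depth.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    out = 1.0 / (1.0 + 0.1 * d)
    return float(out) if out.ndim == 0 else out


def eos80_density(temp_c, salinity_psu):
    """Seawater density (kg/m^3) at atmospheric pressure.

    One-atmosphere international equation of state of seawater (EOS-80
    polynomial in temperature, degC, and practical salinity).
    """
    t = np.asarray(temp_c, dtype=float)
    s = np.asarray(salinity_psu, dtype=float)
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    rho = rho_w + a * s + b * s**1.5 + c * s**2
    return float(rho) if rho.ndim == 0 else rho


@dataclass(frozen=True)
class Morphometry:
    """Animal morphometrics: mass (kg), girth (m), frontal area (m^2).

    If ``frontal_area_m2`` is omitted it is derived from girth.
    """

    mass: float
    girth: float | None = None
    frontal_area_m2: float | None = None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.frontal_area_m2 is None:
            if self.girth is None:
                raise ValueError("either girth or frontal_area_m2 is required")
            object.__setattr__(self, "frontal_area_m2", frontal_area(self.girth))
        elif self.frontal_area_m2 <= 0:
            raise ValueError("frontal_area_m2 must be positive")

    @property
    def frontal_area(self) -> float:
        return self.frontal_area_m2


class Environment:
    """Seawater density as a function of depth.

    Holds either a constant density or a (depth, density) table that is
    interpolated piecewise-linearly, with constant extrapolation beyond the
    table ends. A (depth, temperature, salinity) profile is converted with the
    EOS-80 one-atmosphere equation of state.
    """

    def __init__(self, depths=None, densities=None, constant: float | None = None):
        if constant is not None:
            self._validate_density(np.array([constant]))
            self._constant = float(constant)
            self._depths = None
            self._densities = None
            return
        if depths is None or densities is None or len(np.atleast_1d(depths)) == 0:
            raise ConfigurationError("empty seawater density profile")
        depths = np.asarray(depths, dtype=float)
        densities = np.asarray(densities, dtype=float)
        if depths.shape != densities.shape:
            raise ConfigurationError("profile depth/density lengths differ")
        if np.any(depths < 0) or np.any(np.diff(depths) <= 0):
            raise ConfigurationError(
                "profile depths must be non-negative and strictly increasing"
            )
        self._validate_density(densities)
        self._constant = None
        self._depths = depths
        self._densities = densities

    @staticmethod
    def _validate_density(rho):
        if np.any((rho < 1000.0) | (rho > 1050.0)):
            raise ConfigurationError(
                "seawater densities must lie in [1000, 1050] kg m-3"
            )

    @classmethod
    def constant(cls, rho_sw: float) -> "Environment":
        return cls(constant=rho_sw)

    @classmethod
    def from_profile(cls, depths, densities) -> "Environment":
        return cls(depths=depths, densities=densities)

    @classmethod
    def from_ts_profile(cls, depths, temp_c, salinity_psu) -> "Environment":
        return cls(depths=depths, densities=eos80_density(temp_c, salinity_psu))

    @classmethod
    def from_csv(cls, path) -> "Environment":
        """Read a density profile CSV.

        Two columns (depth_m, rho_sw) or three (depth_m, temp_C,
        salinity_PSU); header optional, judged from the first row.
        """
        import pandas as pd

        df = pd.read_csv(path)
        # headerless files parse the first data row as column names
        try:
            [float(c) for c in df.columns]
        except ValueError:
            pass
        else:
            df = pd.read_csv(path, header=None)
        if df.shape[1] == 2:
            return cls.from_profile(df.iloc[:, 0].values, df.iloc[:, 1].values)
        if df.shape[1] == 3:
            return cls.from_ts_profile(
                df.iloc[:, 0].values, df.iloc[:, 1].values, df.iloc[:, 2].values
            )
        raise ConfigurationError(
            f"profile CSV must have 2 or 3 columns, found {df.shape[1]}"
        )

    def density(self, d):
        """Seawater density (kg/m^3) at depth(s) ``d`` (m)."""
        d = np.asarray(d, dtype=float)
        if self._constant is not None:
            out = np.full(d.shape, self._constant)
        else:
            out = np.interp(d, self._depths, self._densities)
        return float(out) if out.ndim == 0 else out


def seawater_density(d, env: Environment):
    """Seawater density (kg/m^3) at depth ``d`` under ``env`` (module-level alias)."""
    return env.density(d)


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the glide model.

    cd          drag coefficient (dimensionless, referenced to frontal area)
    rho_tissue  density of the non-air body (kg/m^3)
    rho_air     air density at the surface (kg/m^3)
    g           gravitational acceleration (m/s^2)
    """

    cd: float = 0.03
    rho_tissue: float = 1037.0
    rho_air: float = RHO_AIR
    g: float = GRAVITY

    def __post_init__(self):
        if not (0.0 < self.cd <= 1.0):
            raise ValueError(f"cd must be in (0, 1], got {self.cd}")
        if not (1000.0 <= self.rho_tissue <= 1100.0):
            raise ValueError(
                f"rho_tissue must be in [1000, 1100] kg m-3, got {self.rho_tissue}"
            )

    def with_cd(self, cd: float) -> "ModelParams":
        return ModelParams(cd=cd, rho_tissue=self.rho_tissue, rho_air=self.rho_air, g=self.g)

    def with_rho_tissue(self, rho_tissue: float) -> "ModelParams":
        return ModelParams(cd=self.cd, rho_tissue=rho_tissue, rho_air=self.rho_air, g=self.g)


@dataclass
class GlideState:
    """Per-second glide arrays: depth (m), pitch (deg), speed (m/s)."""

    depth: np.ndarray
    pitch: np.ndarray
    speed: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if not (len(self.depth) == len(self.pitch) == len(self.speed)):
            raise ValueError("GlideState arrays must have equal length")


def glide_acceleration(u, d, p, v_air0, params: ModelParams, morph: Morphometry,
                       env: Environment):
    """Along-path acceleration (m/s^2) of a passive glide at one state.

    ``u`` speed (m/s, >= 0), ``d`` depth (m), ``p`` pitch (deg), ``v_air0``
    surface air volume (m^3, scalar or array of candidates). Broadcasts over
    numpy inputs.
    """
    u = np.asarray(u, dtype=float)
    rho = env.density(d)
    sinp = np.sin(np.radians(p))
    drag = -(rho * morph.frontal_area * params.cd / (2.0 * morph.mass)) * u**2
    tissue = params.g * sinp * (rho / params.rho_tissue - 1.0)
    air = (
        (params.g * sinp / morph.mass)
        * np.asarray(v_air0, dtype=float)
        * (rho * air_compression_fraction(d) - params.rho_air)
    )
    out = drag + tissue + air
    return float(out) if np.ndim(out) == 0 else out


def simulate_glide_speed(u0, depth, pitch, v_air0, params: ModelParams,
                         morph: Morphometry, env: Environment,
                         dt: float = 1.0, stop_depth: float | None = None,
                         method: str = "heun"):
    """Propagate glide speed over a measured depth/pitch series.

    Explicit per-second update, open-loop in the measured depth and pitch,
    seeded with the measured speed at the glide start. Two schemes:

    * ``"heun"`` (default): explicit trapezoidal step averaging the
      acceleration at (U_t, d_t, p_t) and at the Euler-predicted state at
      (d_{t+1}, p_{t+1}). Consistent with speeds measured as first differences
      of 1 Hz depth, which represent interval averages rather than samples.
    * ``"euler"``: plain forward step ``U_{t+1} = U_t + dt * a(U_t, d_t, p_t)``.

    Speeds are floored at zero. If ``stop_depth`` is given the simulation
    stops at the first sample whose depth exceeds it (that sample is the last
    one returned). ``v_air0`` may be a scalar (returns shape ``(n,)``) or an
    array of k candidate volumes (returns shape ``(n, k)``).
    """
    depth = np.asarray(depth, dtype=float)
    pitch = np.asarray(pitch, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth/pitch series")
    if depth.shape != pitch.shape:
        raise ValueError("depth and pitch must have equal length")
    if method not in ("heun", "euler"):
        raise ValueError(f"unknown integration method {method!r}")
    n = depth.size
    if stop_depth is not None:
        over = np.nonzero(depth > stop_depth)[0]
        if over.size:
            n = min(n, over[0] + 1)
    v = np.asarray(v_air0, dtype=float)
    u = np.broadcast_to(np.asarray(u0, dtype=float), v.shape).copy()
    out = np.empty((n,) + v.shape)
    out[0] = u
    for t in range(n - 1):
        a1 = glide_acceleration(u, depth[t], pitch[t], v, params, morph, env)
        if method == "euler":
            u = np.maximum(u + dt * a1, 0.0)
        else:
            u_pred = np.maximum(u + dt * a1, 0.0)
            a2 = glide_acceleration(
                u_pred, depth[t + 1], pitch[t + 1], v, params, morph, env
            )
            u = np.maximum(u + dt * 0.5 * (a1 + a2), 0.0)
        out[t + 1] = u
    return out


def terminal_speed(p, d, v_air0, params: ModelParams, morph: Morphometry,
                   env: Environment):
    """Closed-form terminal glide speed (m/s) at fixed depth and pitch.

    The root of ``a(U) = 0``: drag balances the along-path component of net
    buoyancy. Returns 0 when net buoyancy does not propel motion at (d, p).
    """
    if params.cd <= 0:
        raise ValueError("cd must be positive")
    rho = env.density(d)
    sinp = np.sin(np.radians(p))
    b = params.g * sinp * (
        (rho / params.rho_tissue - 1.0)
        + (np.asarray(v_air0, dtype=float) / morph.mass)
        * (rho * air_compression_fraction(d) - params.rho_air)
    )
    b = np.maximum(b, 0.0)  # non-propulsive => terminal speed 0
    out = np.sqrt(b * 2.0 * morph.mass / (rho * morph.frontal_area * params.cd))
    return float(out) if np.ndim(out) == 0 else out
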