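"""Parameter estimation: DRAV grid search, tissue density, drag coefficient.

The diving respiratory air volume (DRAV) of a dive is estimated from a shallow
descent glide by simulating glide speed for 301 candidate surface air volumes
(0 to 0.03 m^3 in 0.0001 m^3 steps) and picking the candidate whose simulated
speed profile minimises a compression-weighted mean squared error against the
measured speed. The Boyle compression factor c = 1/(1 + 0.1 d) gives more
weight to near-surface samples, where the air volume affects net buoyancy most.

Glide selection applies four criteria to descent glides clipped to the 5-50 m
analysis window: gliding must start shallower than 30 m, last longer than
10 s, have mean pitch steeper than -60 deg, and circular variance of both
pitch and roll below 0.1.

Tissue density is estimated from glides entirely deeper than 100 m, where the
air space is so compressed that its buoyancy contribution is negligible; the
drag coefficient from the observed terminal speeds of deep glides across a
candidate range of 0.01-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError
from .glide_physics import (Environment, ModelParams, Morphometry,
                            air_compression_fraction, simulate_glide_speed,
                            terminal_speed)
from .stroke_glide import GlideSegment

__all__ = [
    "SelectionCriteria",
    "DravEstimate",
    "TissueDensityEstimate",
    "CdEstimate",
    "select_descent_glides",
    "weighted_mse",
    "estimate_drav",
    "estimate_tissue_density",
    "estimate_cd",
    "sensitivity_over_cd",
    "DEFAULT_GRID",
]

#: Candidate air-volume grid (m^3): lo, hi, step.
DEFAULT_GRID = (0.0, 0.03, 0.0001)


@dataclass(frozen=True)
class SelectionCriteria:
    """The four descent-glide selection criteria plus the analysis window."""

    max_start_depth: float = 30.0     # (1) gliding starts shallower than this (m)
    min_duration: float = 10.0        # (2) glide longer than this (s)
    max_mean_pitch: float = -60.0     # (3) mean pitch steeper (more negative)
    max_circ_var: float = 0.1         # (4) circular variance of pitch and roll
    depth_window: tuple = (5.0, 50.0)  # analysis window (m)


@dataclass
class DravEstimate:
    """Per-dive DRAV estimate.

    ``v_air0`` is the best-fit surface air volume (m^3, a grid point);
    ``drav_ml_kg`` the mass-specific volume; ``mse_curve`` the full candidate
    -> weighted MSE table; ``qc_flags`` e.g. {"zero_estimate", "grid_boundary"}.
    """

    dive_id: int
    v_air0: float
    drav_ml_kg: float
    mse_curve: pd.DataFrame
    glide: GlideSegment | None = None
    qc_flags: tuple = ()


@dataclass
class TissueDensityEstimate:
    block_id: str
    rho_tissue: float
    fit_mse: float
    n_glides_used: int
    qc_flags: tuple = ()


@dataclass
class CdEstimate:
    per_individual: dict
    pooled_median: float
    rho_tissue_per_individual: dict = field(default_factory=dict)


def select_descent_glides(phases: pd.DataFrame, glide_intervals: list,
                          depth_1hz: np.ndarray, pitch_1hz: np.ndarray,
                          roll_1hz: np.ndarray, speed_1hz: np.ndarray,
                          criteria: SelectionCriteria = SelectionCriteria()):
    """Apply the four selection criteria; at most one glide per dive.

    ``glide_intervals`` are (start_s, end_s) pairs on the 1 Hz time base
    (whole record). Returns ``(selected, rejections)`` where ``rejections``
    is a DataFrame of (dive_id, reason) with reasons ``criterion_1`` ..
    ``criterion_4`` (first criterion failed by the dive's first descent
    glide), ``no_glide``, or ``too_short``.
    """
    from .stroke_glide import build_glide_segment

    selected = []
    rejects = []
    for row in phases.itertuples():
        descent = (float(row.start), float(row.descent_end))
        cands = sorted(g for g in glide_intervals
                       if descent[0] <= g[0] < descent[1])
        if not cands:
            rejects.append({"dive_id": row.dive_id, "reason": "no_glide"})
            continue
        reason = None
        hit = None
        for g0, g1 in cands:
            g1 = min(g1, descent[1])
            res = _evaluate_glide(row.dive_id, g0, g1, depth_1hz, pitch_1hz,
                                  roll_1hz, speed_1hz, criteria)
            if isinstance(res, GlideSegment):
                hit = res
                break
            if reason is None:
                reason = res  # record the first candidate's failure
        if hit is not None:
            selected.append(hit)
        else:
            rejects.append({"dive_id": row.dive_id, "reason": reason})
    return selected, pd.DataFrame(rejects, columns=["dive_id", "reason"])


def _evaluate_glide(dive_id, g0, g1, depth, pitch, roll, speed, criteria):
    """One glide against the four criteria; a GlideSegment or a reason string."""
    s, e = int(np.ceil(g0)), int(np.floor(g1))
    e = min(e, len(depth))
    if e - s < 2:
        return "too_short"
    lo, hi = criteria.depth_window
    d = depth[s:e]
    # clip to the analysis window: drop leading samples above the shallow
    # bound, truncate at the first sample below the deep bound
    first = np.argmax(d >= lo) if np.any(d >= lo) else d.size
    over = np.nonzero(d > hi)[0]
    last = int(over[0]) if over.size else d.size
    s2, e2 = s + int(first), s + last
    if e2 - s2 < 2:
        return "too_short"
    if depth[s2] >= criteria.max_start_depth:
        return "criterion_1"
    if (e2 - s2) <= criteria.min_duration:
        return "criterion_2"
    seg = None
    try:
        seg = _build(dive_id, s2, e2, depth, pitch, roll, speed)
    except ValueError:
        return "too_short"
    if not (seg.mean_pitch < criteria.max_mean_pitch):
        return "criterion_3"
    if not (seg.circ_var_pitch < criteria.max_circ_var
            and seg.circ_var_roll < criteria.max_circ_var):
        return "criterion_4"
    return seg


def _build(dive_id, s, e, depth, pitch, roll, speed):
    from .stroke_glide import build_glide_segment

    return build_glide_segment(dive_id, float(s), float(e), depth, pitch,
                               roll, speed)


def weighted_mse(u_meas, u_sim, depths):
    """Compression-weighted mean squared speed error.

    ``(1/n) * sum_i c_i (U_meas,i - U_sim,i)^2`` with ``c_i = 1/(1+0.1 d_i)``.
    ``u_sim`` may be 1-D (one series) or 2-D ``(n, k)`` for k candidates;
    samples where the measured speed is not finite are dropped.
    """
    u_meas = np.asarray(u_meas, dtype=float)
    u_sim = np.asarray(u_sim, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if u_sim.shape[0] != u_meas.shape[0] or depths.shape[0] != u_meas.shape[0]:
        raise ValueError("u_meas, u_sim and depths must be aligned")
    ok = np.isfinite(u_meas)
    if not np.any(ok):
        raise ValueError("no finite measured speed samples")
    c = air_compression_fraction(np.maximum(depths[ok], 0.0))
    err = (u_meas[ok, None] if u_sim.ndim == 2 else u_meas[ok]) - u_sim[ok]
    w = c[:, None] if u_sim.ndim == 2 else c
    out = np.mean(w * err**2, axis=0)
    return float(out) if np.ndim(out) == 0 else out


def _candidate_grid(grid):
    lo, hi, step = grid
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _staggered(glide: GlideSegment):
    """Midpoint depth/pitch grid matching forward-difference speed samples.

    Speed sample t is the mean speed over [t, t+1], so it is compared at the
    mid-interval depth and pitch.
    """
    d = 0.5 * (glide.depth[:-1] + glide.depth[1:])
    p = 0.5 * (glide.pitch[:-1] + glide.pitch[1:])
    u = glide.speed[:-1]
    return d, p, u


def estimate_drav(glide: GlideSegment, params: ModelParams, morph: Morphometry,
                  env: Environment, grid: tuple = DEFAULT_GRID) -> DravEstimate:
    """Grid-search the surface air volume that best explains a glide's speeds.

    For each candidate volume the glide speed is simulated from the measured
    speed at the glide start over the measured depth/pitch series, and scored
    with :func:`weighted_mse`; the argmin (ties: smallest volume) is the
    estimate. Estimates of exactly zero and estimates at the grid's upper
    boundary are flagged.
    """
    if len(glide.depth) < 2:
        raise ValueError("glide must contain at least 2 samples")
    d, p, u_meas = _staggered(glide)
    finite = np.nonzero(np.isfinite(u_meas))[0]
    if finite.size < 2:
        raise ValueError("glide has fewer than 2 finite speed samples")
    i0 = finite[0]
    d, p, u_meas = d[i0:], p[i0:], u_meas[i0:]
    cands = _candidate_grid(grid)
    sims = simulate_glide_speed(u_meas[0], d, p, cands, params, morph, env)
    mse = weighted_mse(u_meas, sims, d)
    best = int(np.argmin(mse))  # first minimum = smallest volume on ties
    v = float(cands[best])
    flags = []
    if best == 0:
        flags.append("zero_estimate")
    if best == cands.size - 1:
        flags.append("grid_boundary")
    return DravEstimate(
        dive_id=glide.dive_id,
        v_air0=v,
        drav_ml_kg=v / morph.mass * 1e6,
        mse_curve=pd.DataFrame({"v_air0_m3": cands, "weighted_mse": mse}),
        glide=glide,
        qc_flags=tuple(flags),
    )


def estimate_tissue_density(deep_glides: list, params: ModelParams,
                            morph: Morphometry, env: Environment,
                            bounds: tuple = (1015.0, 1060.0),
                            min_depth: float = 100.0,
                            block_id: str = "") -> TissueDensityEstimate:
    """Fit tissue density on glides entirely deeper than ``min_depth``.

    At these depths the respiratory air is compressed to a few percent of its
    surface volume, so its buoyancy is negligible and the speed profile
    constrains tissue density alone (the simulation runs with V_air(0) = 0).
    Minimises the unweighted mean squared speed error over the stated bounds.
    """
    usable = [g for g in deep_glides if np.min(g.depth) > min_depth]
    if not usable:
        raise EstimationError(
            f"no glides entirely deeper than {min_depth} m for tissue density"
        )
    staggered = [_staggered(g) for g in usable]

    def objective(rho):
        pr = params.with_rho_tissue(rho)
        tot, n = 0.0, 0
        for d, p, u in staggered:
            ok = np.isfinite(u)
            if ok.sum() < 2:
                continue
            i0 = np.nonzero(ok)[0][0]
            sim = simulate_glide_speed(u[i0], d[i0:], p[i0:], 0.0, pr, morph, env)
            resid = u[i0:][ok[i0:]] - sim[ok[i0:]]
            tot += float(np.sum(resid**2))
            n += int(ok[i0:].sum())
        if n == 0:
            raise EstimationError("no finite speed samples in deep glides")
        return tot / n

    res = optimize.minimize_scalar(objective, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-3})
    flags = []
    probe = [objective(r) for r in np.linspace(bounds[0], bounds[1], 5)]
    if max(probe) - min(probe) < 1e-12:
        flags.append("flat_objective")
    return TissueDensityEstimate(
        block_id=block_id,
        rho_tissue=float(res.x),
        fit_mse=float(res.fun),
        n_glides_used=len(usable),
        qc_flags=tuple(flags),
    )


def _terminal_observations(glides: list, plateau_window: float = 5.0,
                           max_rel_slope: float = 0.01):
    """Extract (speed, depth, pitch) plateau observations from deep glides.

    A glide qualifies when the relative speed slope over its last
    ``plateau_window`` seconds is below ``max_rel_slope`` (1 %/s): the glide
    has reached terminal speed. The observation is the mean speed, depth and
    pitch over that window.
    """
    obs = []
    w = int(round(plateau_window))
    for g in glides:
        d, p, u = _staggered(g)
        ok = np.isfinite(u)
        d, p, u = d[ok], p[ok], u[ok]
        if u.size < w + 1:
            continue
        tail = u[-w:]
        slope = np.polyfit(np.arange(w), tail, 1)[0]
        mean_u = float(np.mean(tail))
        if mean_u <= 0 or abs(slope) / mean_u > max_rel_slope:
            continue
        obs.append((mean_u, float(np.mean(d[-w:])), float(np.mean(p[-w:]))))
    return obs


def _simulate_cd_rho_grid(u0, d, p, cds, rhos, morph, env, g):
    """Open-loop glide speeds (V_air = 0) on a (C_d, rho_tissue) grid.

    Trapezoidal per-second update vectorised over both grids; returns an
    array of shape (n_samples, n_cd, n_rho).
    """
    rho_sw = env.density(d)
    sinp = np.sin(np.radians(p))
    kdrag = rho_sw * morph.frontal_area / (2.0 * morph.mass)
    buoy = g * sinp[:, None] * (rho_sw[:, None] / rhos[None, :] - 1.0)
    c = cds[:, None]
    u = np.full((cds.size, rhos.size), float(u0))
    out = np.empty((d.size, cds.size, rhos.size))
    out[0] = u
    for t in range(d.size - 1):
        a1 = -kdrag[t] * c * u**2 + buoy[t]
        up = np.maximum(u + a1, 0.0)
        a2 = -kdrag[t + 1] * c * up**2 + buoy[t + 1]
        u = np.maximum(u + 0.5 * (a1 + a2), 0.0)
        out[t + 1] = u
    return out


def _refine_cd_rho(cd0, rho0, obs_cache, cd_range, rho_bounds, morph, env, g):
    """Polish the coarse-grid (C_d, rho_tissue) minimum.

    A joint Nelder-Mead search in (log10 C_d, rho_tissue) removes the
    aliasing a discrete grid suffers along the narrow C_d/density trade-off
    ridge (where coordinate-wise refinement stalls).
    """

    def objective(x):
        cd = float(np.clip(10.0 ** x[0], cd_range[0], cd_range[1]))
        rho = float(np.clip(x[1], rho_bounds[0], rho_bounds[1]))
        tot = 0.0
        for d, p, u, tail in obs_cache:
            sim = _simulate_cd_rho_grid(u[0], d, p, np.array([cd]),
                                        np.array([rho]), morph, env, g)
            tot += float(np.sum((tail - sim[-tail.size:, 0, 0]) ** 2))
        return tot

    res = optimize.minimize(
        objective, x0=[np.log10(cd0), rho0], method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 400,
                 "initial_simplex": [
                     [np.log10(cd0), rho0],
                     [np.log10(cd0) + 0.05, rho0],
                     [np.log10(cd0), rho0 + 1.0],
                 ]})
    cd = float(np.clip(10.0 ** res.x[0], cd_range[0], cd_range[1]))
    rho = float(np.clip(res.x[1], rho_bounds[0], rho_bounds[1]))
    return cd, rho


def estimate_cd(deep_glides, morph: Morphometry, env: Environment,
                cd_range: tuple = (0.01, 1.0), n_cd: int = 100,
                rho_bounds: tuple = (1015.0, 1060.0), rho_step: float = 0.5,
                plateau_window: int = 5, g: float = 9.81) -> CdEstimate:
    """Drag coefficient from the terminal-speed plateaus of deep glides.

    ``deep_glides`` is either a list of glides (one individual) or a mapping
    individual -> list of glides. Terminal speed confounds C_d and tissue
    density, so a joint 2-D grid search (C_d log-spaced over ``cd_range``,
    tissue density over ``rho_bounds``) minimises the MSE between the
    measured speeds over the plateau window of each qualifying glide and the
    open-loop simulated speeds (air volume zero) at those samples; the depth
    variation of seawater density disentangles the two parameters. Only
    glides whose relative speed slope over the final ``plateau_window``
    seconds is below 1 %/s qualify (they have reached terminal speed).
    Returns per-individual best fits and the pooled median C_d.
    """
    if not isinstance(deep_glides, dict):
        deep_glides = {"individual": deep_glides}
    cds = np.geomspace(cd_range[0], cd_range[1], n_cd)
    rhos = np.arange(rho_bounds[0], rho_bounds[1] + rho_step / 2, rho_step)
    per_cd, per_rho = {}, {}
    for ind, glides in deep_glides.items():
        mse = np.zeros((cds.size, rhos.size))
        n_obs = 0
        obs_cache = []
        for glide in glides:
            d, p, u = _staggered(glide)
            ok = np.isfinite(u)
            d, p, u = d[ok], p[ok], u[ok]
            if u.size < plateau_window + 2:
                continue
            tail = u[-plateau_window:]
            mean_u = float(np.mean(tail))
            slope = np.polyfit(np.arange(plateau_window), tail, 1)[0]
            if mean_u <= 0 or abs(slope) / mean_u > 0.01:
                continue
            sims = _simulate_cd_rho_grid(u[0], d, p, cds, rhos, morph, env, g)
            resid = tail[:, None, None] - sims[-plateau_window:]
            mse += np.sum(resid**2, axis=0)
            obs_cache.append((d, p, u, tail))
            n_obs += 1
        if n_obs == 0:
            continue
        i, j = np.unravel_index(np.argmin(mse), mse.shape)
        cd_best, rho_best = _refine_cd_rho(
            float(cds[i]), float(rhos[j]), obs_cache, cd_range, rho_bounds,
            morph, env, g)
        per_cd[ind] = cd_best
        per_rho[ind] = rho_best
    if not per_cd:
        raise EstimationError("no deep glide reached a stable terminal speed")
    return CdEstimate(
        per_individual=per_cd,
        pooled_median=float(np.median(list(per_cd.values()))),
        rho_tissue_per_individual=per_rho,
    )


def sensitivity_over_cd(selected_glides: list, params: ModelParams,
                        morph: Morphometry, env: Environment,
                        cd_values=(0.02, 0.03, 0.04, 0.05),
                        grid: tuple = DEFAULT_GRID) -> pd.DataFrame:
    """Re-estimate DRAV for every glide under each assumed drag coefficient.

    Returns a table with one row per C_d: mean and s.d. of the mass-specific
    DRAV across dives. A larger C_d attributes more of the observed
    deceleration to drag, so estimated DRAV decreases as C_d grows.
    """
    rows = []
    for cd in cd_values:
        dravs = [estimate_drav(g, params.with_cd(cd), morph, env, grid).drav_ml_kg
                 for g in selected_glides]
        rows.append({
            "cd": cd,
            "mean_drav_ml_kg": float(np.mean(dravs)) if dravs else np.nan,
            "sd_drav_ml_kg": float(np.std(dravs, ddof=1)) if len(dravs) > 1 else np.nan,
            "n_dives": len(dravs),
        })
    return pd.DataFrame(rows)
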