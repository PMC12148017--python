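"""Net buoyancy force profiles and the depth of neutral buoyancy.

For a diver of mass ``m`` with tissue density ``rho_tissue`` carrying surface
air volume ``V_air(0)``, the net (upward-positive) buoyancy force at depth
``d`` is

    F_B(d) = g * [ rho_sw(d) * ( m / rho_tissue + V_air(0)/(1 + 0.1 d) )
                   - m - rho_air * V_air(0) ]

i.e. the weight of displaced seawater (tissue volume plus the Boyle-compressed
air space) minus the weight of the body and of the carried air. For a
negatively buoyant animal descending, F_B > 0 hinders the descent; the *depth
of neutral buoyancy* is where F_B first changes sign, after which buoyancy
aids the descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glide_physics import Environment, ModelParams, Morphometry, air_compression_fraction

__all__ = [
    "NeutralBuoyancyResult",
    "SUB_1M",
    "NEVER",
    "net_buoyancy_force",
    "neutral_buoyancy_depth",
    "neutral_depth_isolines",
    "required_drav_for_neutral_depth",
]

#: Sentinel: buoyancy aids the descent from the onset (neutral depth < 1 m).
SUB_1M = "<1m"
#: Sentinel: buoyancy hinders the descent over the whole scanned range.
NEVER = "never"


@dataclass
class NeutralBuoyancyResult:
    """Neutral-buoyancy depth for one dive.

    ``neutral_depth`` is a depth in metres, or one of the sentinels
    :data:`SUB_1M` / :data:`NEVER`. ``force_profile`` maps scanned depth to
    net buoyancy force (N, positive upward).
    """

    dive_id: int
    neutral_depth: float | str
    force_profile: pd.DataFrame


def net_buoyancy_force(d, v_air0: float, morph: Morphometry,
                       params: ModelParams, env: Environment):
    """Net buoyancy force (N, positive = upward) at depth(s) ``d``."""
    d = np.asarray(d, dtype=float)
    rho = env.density(d)
    displaced = rho * (morph.mass / params.rho_tissue
                       + v_air0 * air_compression_fraction(d))
    out = params.g * (displaced - morph.mass - params.rho_air * v_air0)
    return float(out) if np.ndim(out) == 0 else out


def neutral_buoyancy_depth(max_depth: float, v_air0: float, morph: Morphometry,
                           params: ModelParams, env: Environment,
                           dive_id: int = 0, step: float = 1.0) -> NeutralBuoyancyResult:
    """Scan the descent for the depth where net buoyancy changes sign.

    Evaluates F_B on a grid from 1 m to ``max_depth`` (1 m steps) and returns
    the first depth at which F_B <= 0 (descent-aiding). :data:`SUB_1M` when
    buoyancy aids from the onset, :data:`NEVER` when it hinders throughout.
    """
    if max_depth < 1.0:
        raise ValueError("max_depth must be at least 1 m")
    depths = np.arange(1.0, max_depth + step / 2, step)
    forces = net_buoyancy_force(depths, v_air0, morph, params, env)
    profile = pd.DataFrame({"depth_m": depths, "net_buoyancy_N": forces})
    aiding = np.nonzero(forces <= 1e-6)[0]  # small tolerance: exact zeros count
    if aiding.size == 0:
        nd = NEVER
    elif aiding[0] == 0:
        nd = SUB_1M
    else:
        nd = float(depths[aiding[0]])
    return NeutralBuoyancyResult(dive_id=dive_id, neutral_depth=nd,
                                 force_profile=profile)


def required_drav_for_neutral_depth(target_depth: float, rho_tissue: float,
                                    rho_sw: float, params: ModelParams = ModelParams()):
    """Mass-specific DRAV (ml/kg) achieving neutral buoyancy at ``target_depth``.

    Closed-form inversion of F_B(D) = 0 for the surface air volume per unit
    mass; independent of total mass. Negative for positively buoyant tissue.
    """
    denom = rho_sw * air_compression_fraction(target_depth) - params.rho_air
    return (1.0 - rho_sw / rho_tissue) / denom * 1e6


def neutral_depth_isolines(mass: float, rho_sw: float,
                           target_depths=(10.0, 20.0, 30.0),
                           tissue_range=(1026.0, 1046.0),
                           tissue_step: float = 0.5,
                           params: ModelParams = ModelParams()) -> pd.DataFrame:
    """DRAV-vs-tissue-density curves of constant neutral-buoyancy depth.

    For a vertically swimming individual in seawater of constant density
    ``rho_sw``, each curve gives the mass-specific DRAV for which net buoyancy
    crosses zero exactly at the target depth. DRAV rises with tissue density
    along every isoline and deeper targets need larger DRAV.
    Returns a tidy table (rho_tissue, drav_ml_kg, target_depth_m).
    """
    rhos = np.arange(tissue_range[0], tissue_range[1] + tissue_step / 2, tissue_step)
    frames = []
    for target in target_depths:
        drav = np.array([
            required_drav_for_neutral_depth(target, rt, rho_sw, params)
            for rt in rhos
        ])
        frames.append(pd.DataFrame({
            "rho_tissue": rhos,
            "drav_ml_kg": drav,
            "target_depth_m": target,
        }))
    out = pd.concat(frames, ignore_index=True)
    # mass enters only through the absolute volume; keep it for traceability
    out["v_air0_m3"] = out["drav_ml_kg"] * mass * 1e-6
    return out
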