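"""End-to-end orchestration: tag records -> per-dive DRAV results table.

The pipeline chains the kinematics, stroke/glide, estimation and buoyancy
stages and exports a tidy per-dive table (plus per-block tissue densities and
a per-dive accept/reject log, since selection attrition is itself a result).
Analysis constants default to the standard configuration: 5 m dive threshold,
5-50 m DRAV analysis window, >100 m tissue-density window, -60 deg pitch
criterion, 0.1 circular variance, 10 s minimum glide, candidate grid
0-0.03 m^3 at 0.0001 m^3, drag coefficient 0.03.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .buoyancy_analysis import neutral_buoyancy_depth
from .errors import AnalysisError, ConfigurationError, EstimationError
from .estimators import (DEFAULT_GRID, SelectionCriteria, estimate_cd,
                         estimate_drav, estimate_tissue_density,
                         select_descent_glides)
from .glide_physics import Environment, ModelParams, Morphometry
from .stroke_glide import (StrokeDetectionConfig, build_glide_segment,
                           detect_glides, detect_half_strokes,
                           mean_descent_rms, stroke_cessation_depth)
from .tag_kinematics import (TagRecord, compute_orientation, compute_speed,
                             downsample, read_tag_record,
                             segment_dives_and_phases, select_filter_cutoff,
                             separate_acceleration)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "quicklook_association"]

#: Glides must lie entirely deeper than this (m) to constrain tissue density.
TISSUE_MIN_DEPTH_M = 100.0


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration; defaults are the standard constants."""

    inputs: list = field(default_factory=list)
    morphometrics: dict = field(default_factory=lambda: {
        "default": {"mass": 313.0, "girth": 1.70}})
    env_constant: float | None = None
    env_profile: str | None = None
    cd: float | str = 0.03              # numeric, or "estimate"
    rho_tissue: float | None = None     # None -> estimate from deep glides
    tissue_scope: str = "block"         # "block" or "dive"
    grid: tuple = DEFAULT_GRID
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    stroke_threshold: float | None = None   # None -> 3*MAD rule per individual
    min_glide_duration: float = 5.0
    default_cutoff_hz: float = 0.7
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        env = raw.pop("environment", {})
        sel = raw.pop("selection", {})
        stroke = raw.pop("stroke", {})
        cfg = cls(
            inputs=raw.pop("inputs", []),
            morphometrics=raw.pop("morphometrics",
                                  {"default": {"mass": 313.0, "girth": 1.70}}),
            env_constant=env.get("constant"),
            env_profile=env.get("profile"),
            criteria=SelectionCriteria(**sel),
            stroke_threshold=stroke.get("threshold"),
            min_glide_duration=stroke.get("min_glide_duration", 5.0),
            **raw,
        )
        return cfg

    def environment(self) -> Environment:
        if self.env_profile is not None:
            return Environment.from_csv(self.env_profile)
        if self.env_constant is not None:
            return Environment.constant(self.env_constant)
        raise ConfigurationError("no seawater density environment configured")

    def morph_for(self, deployment_id: str) -> Morphometry:
        entry = self.morphometrics.get(deployment_id,
                                       self.morphometrics.get("default"))
        if entry is None:
            raise ConfigurationError(
                f"no morphometrics for deployment {deployment_id!r}")
        return Morphometry(mass=entry["mass"], girth=entry.get("girth"),
                           frontal_area_m2=entry.get("frontal_area_m2"))


@dataclass
class PipelineResult:
    results: pd.DataFrame
    tissue: pd.DataFrame
    rejections: pd.DataFrame
    report: dict

    def write(self, outdir):
        os.makedirs(outdir, exist_ok=True)
        self.results.to_csv(os.path.join(outdir, "results.csv"), index=False)
        self.tissue.to_csv(os.path.join(outdir, "tissue_density.csv"), index=False)
        self.rejections.to_csv(os.path.join(outdir, "rejections.csv"), index=False)
        with open(os.path.join(outdir, "report.yaml"), "w") as fh:
            yaml.safe_dump(self.report, fh, sort_keys=False)


def _process_record(record: TagRecord, config: PipelineConfig):
    """One deployment record -> 1 Hz channels, dives, strokes, glides."""
    if record.depth_rate != 1.0 or record.accel_rate != 25.0:
        record = downsample(record, depth_to=1.0, accel_to=25.0)
    try:
        cutoff = select_filter_cutoff(record.sway, record.accel_rate)
        cutoff_flag = ""
    except AnalysisError:
        cutoff = config.default_cutoff_hz
        cutoff_flag = "default_cutoff"
    gravity, dynamic = separate_acceleration(record.accel, cutoff,
                                             record.accel_rate)
    step = int(round(record.accel_rate))
    ori = compute_orientation(gravity[::step])
    n = min(record.depth.size, ori.pitch.size)
    depth1 = record.depth[:n]
    pitch1, roll1 = ori.pitch[:n], ori.roll[:n]
    speed1 = compute_speed(depth1, pitch1)
    phases = segment_dives_and_phases(depth1, pitch1)

    if config.stroke_threshold is not None:
        threshold = config.stroke_threshold
    else:
        # per-individual threshold: 3 * MAD of bottom-phase dynamic sway,
        # floored so a noise-free record cannot degenerate to zero
        bottom = []
        for r in phases.itertuples():
            b0, b1 = int(r.descent_end) * step, int(r.ascent_start) * step
            if b1 > b0:
                bottom.append(dynamic[b0:b1, 1])
        mad = (np.median(np.abs(np.concatenate(bottom)
                                - np.median(np.concatenate(bottom))))
               if bottom else 0.0)
        # floor ~ a quarter of a typical stroking amplitude: keeps filter-edge
        # transients sub-threshold on low-noise records
        threshold = max(3.0 * float(mad), 0.5)

    sconf = StrokeDetectionConfig(threshold=threshold,
                                  min_glide_duration=config.min_glide_duration)
    half_strokes = detect_half_strokes(dynamic[:, 1], record.accel_rate, threshold)
    glides = detect_glides(dynamic[:, 1], record.accel_rate, sconf)
    return {
        "record": record, "cutoff": cutoff, "cutoff_flag": cutoff_flag,
        "depth1": depth1, "pitch1": pitch1, "roll1": roll1, "speed1": speed1,
        "phases": phases, "threshold": threshold,
        "half_strokes": half_strokes, "glides": glides,
    }


def _deep_glide_segments(proc, min_depth: float = TISSUE_MIN_DEPTH_M,
                         tail_trim_s: int = 4):
    """Descent-glide portions lying entirely deeper than ``min_depth``.

    The last ``tail_trim_s`` seconds before the bottom phase are dropped: the
    pitch-over and the anti-alias filtering of the depth corner distort the
    measured speed there.
    """
    out = []
    depth1 = proc["depth1"]
    for row in proc["phases"].itertuples():
        for g0, g1 in proc["glides"]:
            s = max(int(np.ceil(g0)), int(row.start))
            e = min(int(np.floor(g1)), int(row.descent_end) - tail_trim_s)
            if e - s < 2:
                continue
            idx = np.nonzero(depth1[s:e] > min_depth)[0]
            if idx.size < 12:
                continue
            s2, e2 = s + int(idx[0]), s + int(idx[-1]) + 1
            try:
                seg = build_glide_segment(row.dive_id, float(s2), float(e2),
                                          depth1, proc["pitch1"], proc["roll1"],
                                          proc["speed1"])
            except ValueError:
                continue
            out.append(seg)
    return out


def run_pipeline(config: PipelineConfig, records=None) -> PipelineResult:
    """Run the full chain and return the per-dive results table.

    ``records`` may be given directly (a list of :class:`TagRecord`) to skip
    file input; otherwise ``config.inputs`` is read. If ``config.output_dir``
    is set, the tables are also written there as CSV.
    """
    env = config.environment()
    if records is None:
        records = [read_tag_record(p) for p in config.inputs]
    if not records:
        raise ConfigurationError("no input records")

    processed, rejections = [], []
    for rec in records:
        try:
            processed.append(_process_record(rec, config))
        except Exception as exc:  # surface stage context per record
            raise type(exc)(
                f"[stage=kinematics deployment={rec.deployment_id}] {exc}"
            ) from exc

    # deep glides, grouped per deployment and per day-block
    deep_by_dep = {p["record"].deployment_id: _deep_glide_segments(p)
                   for p in processed}

    # drag coefficient
    if config.cd == "estimate":
        usable = {k: v for k, v in deep_by_dep.items() if v}
        cd_est = estimate_cd(
            usable, config.morph_for(next(iter(usable))), env)
        cd = cd_est.pooled_median
    else:
        cd_est = None
        cd = float(config.cd)
    base_params = ModelParams(cd=cd)

    # tissue density
    tissue_rows = []
    pooled_tissue = None
    if config.rho_tissue is None:
        all_deep = [g for v in deep_by_dep.values() for g in v]
        if not all_deep:
            raise EstimationError("no deep (>100 m) glides to fit tissue density")
        pooled = estimate_tissue_density(all_deep, base_params,
                                         _pooled_morph(config, processed), env,
                                         block_id="pooled")
        pooled_tissue = pooled.rho_tissue
        tissue_rows.append(pooled)

    results = []
    for proc in processed:
        rec = proc["record"]
        morph = config.morph_for(rec.deployment_id)
        block = _block_id(rec)
        selected, rej = select_descent_glides(
            proc["phases"], proc["glides"], proc["depth1"], proc["pitch1"],
            proc["roll1"], proc["speed1"], config.criteria)
        for r in rej.itertuples():
            rejections.append({"deployment_id": rec.deployment_id,
                               "dive_id": r.dive_id, "reason": r.reason})
        if config.rho_tissue is not None:
            rho_t, rho_src = float(config.rho_tissue), "configured"
        elif config.tissue_scope == "dive" and deep_by_dep[rec.deployment_id]:
            est = estimate_tissue_density(deep_by_dep[rec.deployment_id],
                                          base_params, morph, env, block_id=block)
            tissue_rows.append(est)
            rho_t, rho_src = est.rho_tissue, "dive"
        else:
            rho_t, rho_src = pooled_tissue, "pooled"
        params = base_params.with_rho_tissue(rho_t)

        by_dive = {g.dive_id: g for g in selected}
        for row in proc["phases"].itertuples():
            glide = by_dive.get(row.dive_id)
            if glide is None:
                continue
            est = estimate_drav(glide, params, morph, env, config.grid)
            mean_rms = mean_descent_rms(proc["half_strokes"], proc["depth1"],
                                        float(row.start), float(row.descent_end))
            cess = stroke_cessation_depth(proc["half_strokes"], proc["glides"],
                                          proc["depth1"], float(row.start),
                                          float(row.descent_end))
            nb = neutral_buoyancy_depth(row.max_depth, est.v_air0, morph,
                                        params, env, dive_id=row.dive_id)
            results.append({
                "deployment_id": rec.deployment_id,
                "dive_id": row.dive_id,
                "day_block": block,
                "max_depth_m": row.max_depth,
                "glide_start_depth_m": glide.start_depth,
                "glide_duration_s": glide.duration,
                "mean_pitch_deg": glide.mean_pitch,
                "v_air0_m3": est.v_air0,
                "drav_ml_kg": est.drav_ml_kg,
                "rho_tissue": rho_t,
                "rho_tissue_source": rho_src,
                "cd": cd,
                "cessation_depth_m": cess,
                "mean_rms": mean_rms,
                "neutral_depth_m": nb.neutral_depth,
                "qc_flags": ";".join(est.qc_flags),
            })

    results_df = pd.DataFrame(results)
    rej_df = pd.DataFrame(rejections, columns=["deployment_id", "dive_id", "reason"])
    tissue_df = pd.DataFrame([{
        "block_id": t.block_id, "rho_tissue": t.rho_tissue,
        "fit_mse": t.fit_mse, "n_glides_used": t.n_glides_used,
    } for t in tissue_rows])
    n_dives = int(sum(len(p["phases"]) for p in processed))
    report = {
        "n_records": len(processed),
        "n_dives": n_dives,
        "n_accepted": int(len(results_df)),
        "n_rejected": int(len(rej_df)),
        "rejections_by_reason": {} if rej_df.empty else
            rej_df["reason"].value_counts().to_dict(),
        "cd": cd,
        "cd_source": "estimated" if cd_est is not None else "configured",
    }
    out = PipelineResult(results=results_df, tissue=tissue_df,
                         rejections=rej_df, report=report)
    if config.output_dir:
        out.write(config.output_dir)
    return out


def _block_id(record: TagRecord) -> str:
    return f"{record.deployment_id.rsplit('_', 1)[0]}:{record.start_time[:10]}"


def _pooled_morph(config, processed) -> Morphometry:
    return config.morph_for(processed[0]["record"].deployment_id)


def quicklook_association(results: pd.DataFrame, x: str, y: str):
    """OLS slope/intercept and Pearson correlation between two result columns.

    A quick sanity check of trend direction; inferential modelling (mixed
    models, bootstrap) is left to external statistics tooling on the exported
    table. Missing rows are dropped; needs >= 3 complete rows and a
    non-constant x.
    """
    from scipy import stats

    df = results[[x, y]].apply(pd.to_numeric, errors="coerce").dropna()
    if len(df) < 3:
        raise AnalysisError("need at least 3 complete rows")
    if np.ptp(df[x].values) == 0:
        raise AnalysisError(f"column {x!r} is constant; slope undefined")
    fit = stats.linregress(df[x].values, df[y].values)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
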