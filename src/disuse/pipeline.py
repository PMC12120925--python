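"""End-to-end orchestration of the analysis stages on synthetic or loaded
data, with JSON summaries and map outputs on disk.

Stage order: generate/load -> preprocess -> fc-change -> pulses ->
pulse-model -> task-glm -> spatial-test -> dynamics. Each stage derives
its own RNG seed from the global seed and the stage name, so the output
bundle is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import dynamics as dyn
from . import fc_change, preprocess, pulse_detect, pulse_model, spatial_stats, task_glm
from ._utils import child_seed
from .datamodel import BoldRun, StudyConfig
from .io import write_json, write_map
from .simulate import GroundTruth, SimParams, make_space, make_truth, simulate_run, simulate_task_run
from .space import GrayordinateSpace

log = logging.getLogger("disuse")

ALL_STAGES = (
    "generate", "preprocess", "fc-change", "pulses", "pulse-model",
    "task-glm", "spatial-test", "dynamics",
)


@dataclass
class PipelineState:
    config: StudyConfig
    seed: int
    space: GrayordinateSpace | None = None
    truth: GroundTruth | None = None
    runs: list = field(default_factory=list)
    task_runs: list = field(default_factory=list)
    clean_runs: list = field(default_factory=list)
    pulse_runs: list = field(default_factory=list)
    fc_maps: list = field(default_factory=list)
    clusters: fc_change.ClusterResult | None = None
    detection: pulse_detect.PulseDetectionResult | None = None
    task_map: task_glm.TStatMap | None = None
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: StudyConfig | None = None,
    mode: str = "synthetic",
    sim_params: SimParams | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    stages: tuple = ALL_STAGES,
    runs: list[BoldRun] | None = None,
    space: GrayordinateSpace | None = None,
) -> PipelineState:
    """Execute the requested stages in order; any stage failure aborts
    with the stage name in the message. Returns the in-memory state; if
    ``out_dir`` is given, writes the JSON summary and the key maps."""
    config = config or StudyConfig()
    config.validate()
    seed = config.rng_seed if seed is None else int(seed)
    st = PipelineState(config=config, seed=seed)
    st.summary["config"] = config.to_dict()
    st.summary["seed"] = seed
    if mode == "real":
        if runs is None or space is None:
            raise ValueError("real mode requires runs and space")
        st.runs, st.space = list(runs), space
    params = sim_params or SimParams()
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        log.info("stage %s (seed %d)", stage, child_seed(seed, stage))
        try:
            _STAGES[stage](st, params, mode)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    if out_dir is not None:
        _write_outputs(st, Path(out_dir))
    return st


def _default_schedule(params: SimParams) -> list[tuple[str, float, float]]:
    """Right-hand movement blocks of 15 s spaced every 60 s within the
    run length."""
    run_len = params.T * params.tr_seconds
    onsets = np.arange(20.0, run_len - 35.0, 60.0)
    if onsets.size == 0:
        onsets = np.array([run_len * 0.2])
    return [("right-hand", float(o), 15.0) for o in onsets]


def _stage_generate(st: PipelineState, params: SimParams, mode: str):
    if mode == "real":
        st.summary["generate"] = {"mode": "real", "n_runs": len(st.runs)}
        return
    seed = child_seed(st.seed, "generate")
    st.space = make_space(params, seed)
    st.truth = make_truth(st.space, params, seed)
    S = params.sessions_per_phase
    day0 = {"pre": -S, "cast": 0, "post": S}
    for phase in ("pre", "cast", "post"):
        for i in range(S):
            sid = f"{phase}-{i + 1:02d}"
            st.runs.append(simulate_run(
                st.space, sid, phase, day0[phase] + i + 1, params, st.truth,
                seed=child_seed(seed, sid),
            ))
    schedule = _default_schedule(params)
    for k in range(2):
        st.task_runs.append(simulate_task_run(
            st.space, schedule, params, st.truth,
            seed=child_seed(seed, f"task-{k}"), session_id=f"task-{k}",
        ))
    st.summary["generate"] = {
        "mode": "synthetic", "n_runs": len(st.runs),
        "n_grayordinates": st.space.n,
        "n_injected_pulses": len(st.truth.injected_pulses),
    }


def _stage_preprocess(st: PipelineState, params: SimParams, mode: str):
    snr = preprocess.compute_snr_map(st.runs, denominator=st.config.snr_denominator)
    st.summary["preprocess"] = {"snr_max": float(np.nanmax(snr.value))}
    kept = []
    for run in st.runs:
        clean, mask = preprocess.preprocess_run(run, st.space, st.config)
        st.clean_runs.append(clean)
        kept.append(mask.n_kept)
        # high-pass-only variant preserved for pulse-shape modeling
        hp_cfg = StudyConfig(**{**st.config.to_dict(),
                                "filter_mode": "highpass_only",
                                "band": tuple(st.config.band)})
        hp, _ = preprocess.preprocess_run(run, st.space, hp_cfg, do_smooth=False)
        st.pulse_runs.append(hp)
    st.summary["preprocess"]["frames_kept"] = kept
    st.summary["preprocess"]["snr_value_mean"] = float(np.nanmean(snr.value))


def _stage_fc(st: PipelineState, params: SimParams, mode: str):
    seed_roi = st.truth.rois["sm1ue-left"] if st.truth else np.array([0])
    st.fc_maps = [fc_change.seed_fc_map(r, seed_roi) for r in st.clean_runs]
    effect = fc_change.phase_effect_size(st.fc_maps, "cast", "pre")
    st.clusters = fc_change.permutation_cluster_correct(
        st.fc_maps, st.space, "cast", "pre",
        n_perm=st.config.n_perm,
        n_thresholds=st.config.n_cluster_thresholds,
        min_pass=st.config.min_thresholds_passed,
        alpha=st.config.alpha,
        seed=child_seed(st.seed, "fc-change"),
        two_sided=st.config.two_sided,
    )
    st.summary["fc_change"] = {
        "d_max": float(np.nanmax(effect.d)),
        "n_significant_clusters": len(st.clusters.clusters),
        "clusters": [c.to_dict() for c in st.clusters.clusters],
    }
    st.effect = effect


def _stage_pulses(st: PipelineState, params: SimParams, mode: str):
    left = st.truth.rois["sm1ue-left"]
    right = st.truth.rois["sm1ue-right"]
    st.detection = pulse_detect.detect_study(
        st.pulse_runs, left, right,
        z=st.config.z_pulse, r_max=st.config.motion_r_max,
        window_s=st.config.motion_window_s,
    )
    st.summary["pulses"] = {
        "n_detected": len(st.detection.events),
        "n_retained": len(st.detection.retained),
        "events": [e.to_dict() for e in st.detection.events],
    }


def _stage_pulse_model(st: PipelineState, params: SimParams, mode: str):
    events = st.detection.retained if st.detection else []
    if not events:
        st.summary["pulse_model"] = {"n_events": 0}
        return
    runs = {r.session_id: r for r in st.pulse_runs}
    # reference: fitted left-SM1 peak per event; per-voxel maps are fitted
    # on the latency structures (the subcortical question), capped at 12
    # events to bound runtime
    events = events[:12]
    refs, fits_by_event = [], []
    left = st.truth.rois["sm1ue-left"]
    fit_structs = sorted(params.latency_offsets)
    fit_idx = np.concatenate([st.space.indices(s) for s in fit_structs])
    for ev in events:
        run = runs[ev.run_id]
        times = run.times()
        ref_series = run.data[left].mean(axis=0)
        ref_fit = pulse_model.fit_hrf_at_pulse(ref_series, times, ev)
        refs.append(ref_fit.peak_time_s if ref_fit.converged else np.nan)
        fits_by_event.append({
            i: pulse_model.fit_hrf_at_pulse(run.data[i], times, ev)
            for i in fit_idx
        })
    fits = [[fits_by_event[e][i] for e in range(len(events))] for i in fit_idx]
    maps = pulse_model.pulse_maps(fits, np.array(refs))
    det_full = np.zeros(st.space.n)
    lat_full = np.full(st.space.n, np.nan)
    det_full[fit_idx] = maps.detectability
    lat_full[fit_idx] = maps.latency_s
    st.pulse_maps_full = pulse_model.PulseMaps(det_full, lat_full,
                                               np.full(st.space.n, np.nan))
    lat_by_struct = {}
    for s in fit_structs:
        sel = np.isin(fit_idx, st.space.indices(s))
        vals = maps.latency_s[sel]
        lat_by_struct[s] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else None
    st.summary["pulse_model"] = {
        "n_events": len(events),
        "mean_latency_by_structure_s": lat_by_struct,
        "detectability_mean": float(maps.detectability.mean()),
    }


def _stage_task(st: PipelineState, params: SimParams, mode: str):
    if not st.task_runs:
        st.summary["task_glm"] = {"n_runs": 0}
        return
    tr = st.task_runs[0].tr_seconds
    schedule = _default_schedule(params)
    run_maps = []
    for run in st.task_runs:
        design = task_glm.build_design(schedule, tr, run.T)
        run_maps.append(task_glm.fit_glm(
            run, design, {"right-hand:block": 1.0},
            contrast_name="right-hand vs baseline",
        ))
    st.task_map = task_glm.second_level(run_maps)
    st.summary["task_glm"] = {
        "n_runs": len(run_maps),
        "t_max": float(np.nanmax(st.task_map.t)),
    }


def _stage_spatial(st: PipelineState, params: SimParams, mode: str):
    if st.task_map is None or st.clusters is None:
        st.summary["spatial_stats"] = {}
        return
    structure = params.fc_target_structure
    ens = spatial_stats.moran_surrogates(
        st.clusters.d_map, st.space, structure,
        n=st.config.n_surrogates, seed=child_seed(st.seed, "spatial-test"),
    )
    r, p = spatial_stats.map_similarity_test(
        st.clusters.d_map, st.task_map.t, ens, tail="upper"
    )
    idx = st.space.indices(structure)
    thirds = np.array_split(np.arange(idx.size), 4)
    labels = np.zeros(st.space.n, dtype=int)
    for k, block in enumerate(thirds):
        labels[idx[block]] = k + 1
    nuclei = spatial_stats.nucleus_means(st.task_map.t, labels, ensemble=None)
    box = spatial_stats.vim_box((0.0, -24.0, 0.0), 24.0, 0.0, 2.0)
    st.summary["spatial_stats"] = {
        "structure": structure,
        "fc_task_similarity_r": r,
        "fc_task_similarity_p": p,
        "moran_i_original": ens.i_original,
        "moran_i_surrogate_mean": float(ens.i_surrogates.mean()),
        "nucleus_means": nuclei.table.to_dict(orient="records"),
        "vim_box_n_voxels": int(len(box.voxels_mm)),
    }


def _stage_dynamics(st: PipelineState, params: SimParams, mode: str):
    if st.clusters is None or st.task_map is None:
        st.summary["dynamics"] = {}
        return
    try:
        roi = dyn.select_roi(
            st.clusters, st.task_map, st.space, params.fc_target_structure,
            task_top=st.config.task_top_fraction,
        )
    except ValueError as e:
        log.info("dynamics stage skipped: %s", e)
        st.summary["dynamics"] = {"skipped": str(e)}
        return
    days = np.array([m.day_index for m in st.fc_maps])
    vals = np.array([m.r[roi.indices].mean() for m in st.fc_maps])
    phases = np.array([m.phase for m in st.fc_maps])
    try:
        fit = dyn.fit_decay(days, vals, phases,
                            seed=child_seed(st.seed, "dynamics"))
    except (ValueError, RuntimeError) as e:
        st.summary["dynamics"] = {"skipped": str(e), "roi_size": len(roi)}
        return
    st.summary["dynamics"] = {"roi_size": len(roi), **fit.summary()}


_STAGES = {
    "generate": _stage_generate,
    "preprocess": _stage_preprocess,
    "fc-change": _stage_fc,
    "pulses": _stage_pulses,
    "pulse-model": _stage_pulse_model,
    "task-glm": _stage_task,
    "spatial-test": _stage_spatial,
    "dynamics": _stage_dynamics,
}


def _write_outputs(st: PipelineState, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    write_json(st.summary, out_dir / "summary.json")
    if st.space is not None and st.clusters is not None:
        write_map(np.nan_to_num(st.clusters.d_map), st.space,
                  out_dir / "effect_d")
    if st.space is not None and st.task_map is not None:
        write_map(np.nan_to_num(st.task_map.t), st.space, out_dir / "task_t")
    if st.space is not None and getattr(st, "pulse_maps_full", None) is not None:
        write_map(st.pulse_maps_full.detectability, st.space,
                  out_dir / "pulse_detectability")
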