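"""End-to-end evaluation protocols on synthetic studies.

Each function generates studies with the synthetic-data module, runs the
relevant analysis stage(s), and measures a calibration or recovery
quantity against the generator's ground truth: family-wise error of the
cluster test under a pure FC null, recovery of an injected effect-size
blob, pulse detection sensitivity/specificity, thalamic latency recovery,
agreement between the parametric-HRF and FIR pulse pipelines, calibration
of the spatially constrained similarity nulls, and decay-model parameter
recovery. Problem sizes are scaled-down versions of the study design (see
the methods note) so every protocol runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from ._utils import child_seed
from .datamodel import StudyConfig
from .dynamics import fit_decay
from .fc_change import permutation_cluster_correct, seed_fc_map
from .preprocess import preprocess_run, smooth
from .pulse_detect import PulseEvent, detect_study
from .pulse_model import disp_to_fwhm, fir_estimate, fir_features, fit_hrf_at_pulse
from .simulate import SimParams, decay_curve, make_space, make_truth, simulate_run, simulate_study
from .spatial_stats import map_similarity_test, moran_surrogates

#: ~300-grayordinate space for null calibration runs
NULL_PARAMS = dict(
    cortex_shape=(8, 8), thalamus_shape=(3, 3, 3), putamen_shape=(2, 2, 2),
    pallidum_shape=(2, 2, 3), caudate_shape=(2, 3, 3),
    cerebellum_shape=(3, 3, 3), T=150,
)


def gaussian_fwhm_by_root_finding(sd: float = 1.0) -> float:
    """FWHM of a Gaussian of the given SD located numerically: the
    distance between the two points where the density crosses half its
    maximum (independent check of the 2*sqrt(2*ln 2) factor)."""
    pdf = lambda x: np.exp(-0.5 * (x / sd) ** 2)
    half = lambda x: pdf(x) - 0.5
    right = optimize.brentq(half, 0.0, 10.0 * sd, xtol=1e-12)
    left = optimize.brentq(half, -10.0 * sd, 0.0, xtol=1e-12)
    return right - left


def _study_fc_maps(space, truth, params, seed, phases=("pre", "cast")):
    maps = []
    S = params.sessions_per_phase
    for phase in phases:
        for i in range(S):
            sid = f"{phase}-{i + 1:02d}"
            run = simulate_run(space, sid, phase, 0.0, params, truth,
                               seed=child_seed(seed, sid))
            maps.append(seed_fc_map(run, truth.rois["sm1ue-left"]))
    return maps


def cluster_null_fwer(n_replicates: int = 200, n_perm: int = 200,
                      seed: int = 0) -> float:
    """Family-wise positive rate of the permutation cluster test on pure
    FC-null studies (no coupling change, no pulses), 6 sessions/phase,
    ~300 grayordinates."""
    params = SimParams(effect_d=0.0, pulse_rate_per_run=0.0, **NULL_PARAMS)
    space = make_space(params, seed)
    fp = 0
    for rep in range(n_replicates):
        truth = make_truth(space, params, seed)
        maps = _study_fc_maps(space, truth, params,
                              child_seed(seed, f"null-{rep}"))
        res = permutation_cluster_correct(
            maps, space, n_perm=n_perm, seed=child_seed(seed, f"perm-{rep}")
        )
        fp += res.significant
    return fp / n_replicates


def blob_recovery_rate(n_replicates: int = 50, n_perm: int = 200,
                       seed: int = 0, min_overlap: float = 0.25) -> float:
    """Fraction of studies in which the injected d=2.5, 40-voxel thalamic
    blob is detected: a significant cluster in the target structure
    covering at least ``min_overlap`` of the blob's voxels."""
    params = SimParams()
    space = make_space(params, seed)
    hits = 0
    for rep in range(n_replicates):
        truth = make_truth(space, params, seed)
        maps = _study_fc_maps(space, truth, params,
                              child_seed(seed, f"blob-{rep}"))
        res = permutation_cluster_correct(
            maps, space, n_perm=n_perm, seed=child_seed(seed, f"bperm-{rep}")
        )
        blob = set(truth.rois["fc-blob"].tolist())
        hits += any(
            c.structure == params.fc_target_structure
            and len(blob & set(c.members.tolist())) >= min_overlap * len(blob)
            for c in res.clusters
        )
    return hits / n_replicates


# ---------------------------------------------------------------------------
# pulse detection

def _pulse_study(seed: int, params: SimParams | None = None,
                 phases=("pre", "cast")):
    params = params or SimParams()
    space, truth, runs = simulate_study(params, seed=seed, phases=phases)
    cfg = StudyConfig(filter_mode="highpass_only")
    clean = [preprocess_run(r, space, cfg, do_smooth=False)[0] for r in runs]
    det = detect_study(clean, truth.rois["sm1ue-left"],
                       truth.rois["sm1ue-right"])
    return space, truth, runs, clean, det


def _match_events(det, truth, runs, fd_threshold=0.1, tol_frames=8):
    """Match retained detections to injected pulses; returns
    (n_injected, n_hits, false_alarms_per_cast_run)."""
    inj: dict[str, list] = {}
    for pl in truth.injected_pulses:
        if not pl["motion_locked"]:
            inj.setdefault(pl["session_id"], []).append(pl["onset_frame"])
    hits = tot = fa = nruns = 0
    for run in runs:
        evs = [e for e in det.retained if e.run_id == run.session_id]
        keep = np.flatnonzero(run.motion.fd_mm <= fd_threshold)
        peaks = [keep[e.peak_frame] for e in evs]
        matched: set[int] = set()
        for onset in inj.get(run.session_id, []):
            tot += 1
            target = onset + 5.0 / run.tr_seconds
            cand = [i for i, pk in enumerate(peaks)
                    if abs(pk - target) <= tol_frames and i not in matched]
            if cand:
                hits += 1
                matched.add(cand[0])
        if run.phase == "cast":
            fa += len(evs) - len(matched)
            nruns += 1
    return tot, hits, fa / max(nruns, 1)


def pulse_detection_rates(n_studies: int = 12, seed: int = 0) -> dict:
    """Hit rate and false alarms per cast run for injected 4-SD pulses at
    default thresholds (2.3 SD, 0.8 motion-r, 18 s window)."""
    hits = tot = 0
    fa = []
    for rep in range(n_studies):
        space, truth, runs, clean, det = _pulse_study(child_seed(seed, f"pd-{rep}"))
        t, h, f = _match_events(det, truth, runs)
        tot += t
        hits += h
        fa.append(f)
    return {"hit_rate": hits / max(tot, 1),
            "false_alarms_per_run": float(np.mean(fa)),
            "n_pulses": tot}


def motion_screen_rates(n_studies: int = 10, seed: int = 0,
                        fraction: float = 0.2) -> dict:
    """Screening selectivity on a cohort with motion-locked artifact
    events: fraction of motion-locked detections screened and fraction of
    genuine detections screened."""
    params = SimParams(motion_locked_fraction=fraction)
    scr_ml = tot_ml = scr_gen = tot_gen = 0
    for rep in range(n_studies):
        space, truth, runs, clean, det = _pulse_study(
            child_seed(seed, f"ms-{rep}"), params, phases=("cast",))
        for pl in truth.injected_pulses:
            run = next(r for r in runs if r.session_id == pl["session_id"])
            keep = np.flatnonzero(run.motion.fd_mm <= 0.1)
            target = pl["onset_frame"] + (
                0.0 if pl["motion_locked"] else 5.0 / run.tr_seconds)
            evs = [e for e in det.events
                   if e.run_id == pl["session_id"]
                   and abs(keep[e.peak_frame] - target) <= 8]
            if not evs:
                continue
            e = max(evs, key=lambda ev: ev.z_diff)
            if pl["motion_locked"]:
                tot_ml += 1
                scr_ml += e.screened
            else:
                tot_gen += 1
                scr_gen += e.screened
    return {
        "motion_locked_screened": scr_ml / max(tot_ml, 1),
        "genuine_screened": scr_gen / max(tot_gen, 1),
        "n_motion_locked": tot_ml,
    }


# ---------------------------------------------------------------------------
# pulse modeling

def _true_aligned_events(truth, runs, fd_threshold=0.1):
    events = []
    for pl in truth.injected_pulses:
        if pl["motion_locked"]:
            continue
        run = next(r for r in runs if r.session_id == pl["session_id"])
        keep = np.flatnonzero(run.motion.fd_mm <= fd_threshold)
        tpk = pl["onset_frame"] + 5.0 / run.tr_seconds
        oc = int(np.searchsorted(keep, round(tpk)))
        oc = min(oc, len(keep) - 1)
        events.append(PulseEvent(
            run_id=pl["session_id"], peak_frame=oc,
            peak_time_s=oc * run.tr_seconds, z_diff=np.inf, z_left=np.inf,
        ))
    return events


def latency_recovery(n_studies: int = 12, seed: int = 0) -> dict:
    """Recovery of the injected +0.95 s thalamic latency from per-event
    HRF fits on detected pulses; per-study cortex<thalamus ordering."""
    lats: list[float] = []
    order_ok = []
    for rep in range(n_studies):
        space, truth, runs, clean, det = _pulse_study(
            child_seed(seed, f"lat-{rep}"), phases=("cast",))
        cruns = {r.session_id: r for r in clean}
        sm1 = truth.rois["sm1ue-left"]
        half_a, half_b = sm1[: len(sm1) // 2], sm1[len(sm1) // 2:]
        thal = truth.rois["pulse-thalamus-left"]
        study_th, study_cx = [], []
        for e in det.retained:
            run = cruns[e.run_id]
            t = run.times()
            ref = fit_hrf_at_pulse(run.data[sm1].mean(axis=0), t, e)
            if not ref.success:
                continue
            ft = fit_hrf_at_pulse(run.data[thal].mean(axis=0), t, e)
            fc = fit_hrf_at_pulse(run.data[half_b].mean(axis=0), t, e)
            if ft.success:
                study_th.append(ft.peak_time_s - ref.peak_time_s)
            if fc.success:
                study_cx.append(fc.peak_time_s - ref.peak_time_s)
        lats.extend(study_th)
        if study_th and study_cx:
            order_ok.append(np.mean(study_th) > np.mean(study_cx))
    return {
        "latency_mean_s": float(np.mean(lats)) if lats else np.nan,
        "n_events": len(lats),
        "ordering_rate": float(np.mean(order_ok)) if order_ok else np.nan,
    }


def hrf_fir_agreement(n_studies: int = 16, seed: int = 0) -> dict:
    """Cross-method consistency of the parametric-HRF and FIR pipelines on
    ground-truth-aligned events: difference of thalamic peak delays and
    ratio of FWHM estimates."""
    h_dl, h_fw, f_dl, f_fw = [], [], [], []
    n_events = 0
    for rep in range(n_studies):
        params = SimParams()
        space, truth, runs = simulate_study(
            params, seed=child_seed(seed, f"hf-{rep}"), phases=("cast",))
        cfg = StudyConfig(filter_mode="highpass_only")
        clean = [preprocess_run(r, space, cfg, do_smooth=False)[0] for r in runs]
        events = _true_aligned_events(truth, runs)
        if len(events) < 5:       # FIR needs a minimum event count
            continue
        n_events += len(events)
        sm1 = truth.rois["sm1ue-left"]
        thal = truth.rois["pulse-thalamus-left"]
        cruns = {r.session_id: r for r in clean}
        for e in events:
            run = cruns[e.run_id]
            t = run.times()
            fr = fit_hrf_at_pulse(run.data[sm1].mean(axis=0), t, e)
            ft = fit_hrf_at_pulse(run.data[thal].mean(axis=0), t, e)
            # waveform features at known-pulse loci use all successful
            # fits: the bound-interior convergence rule is the *presence*
            # criterion and selectively truncates wide fits
            if ft.success:
                h_fw.append(disp_to_fwhm(ft.peak_disp_s))
                if fr.success:
                    h_dl.append(ft.peak_time_s - fr.peak_time_s)
        roi_runs = [
            r.with_data(np.vstack([r.data[sm1].mean(axis=0),
                                   r.data[thal].mean(axis=0)]))
            for r in clean
        ]
        curves = fir_estimate(roi_runs, events)
        _, _, dl0 = fir_features(curves[0])
        _, fw1, dl1 = fir_features(curves[1], reference_peak_lag_s=dl0)
        if np.isfinite(fw1):
            f_fw.append(fw1)
        if np.isfinite(dl1):
            f_dl.append(dl1)
    return {
        "n_events": n_events,
        "hrf_peak_delay_s": float(np.mean(h_dl)),
        "fir_peak_delay_s": float(np.mean(f_dl)),
        "peak_delay_diff_s": abs(float(np.mean(f_dl)) - float(np.mean(h_dl))),
        "hrf_fwhm_s": float(np.mean(h_fw)),
        "fir_fwhm_s": float(np.mean(f_fw)),
        "fwhm_ratio": float(np.mean(f_fw)) / float(np.mean(h_fw)),
    }


# ---------------------------------------------------------------------------
# spatial nulls

def surrogate_calibration(n_replicates: int = 200, n_surrogates: int = 200,
                          seed: int = 0) -> dict:
    """Moran-surrogate similarity-test p-values under independent
    white-noise maps (KS distance to uniform) and preservation of Moran's
    I on smooth maps (surrogate/original ratio)."""
    params = SimParams()
    space = make_space(params, seed)
    structure = "thalamus-left"
    rng = np.random.default_rng(child_seed(seed, "surr-cal"))
    ps = []
    for rep in range(n_replicates):
        a = rng.standard_normal(space.n)
        b = rng.standard_normal(space.n)
        ens = moran_surrogates(a, space, structure, n=n_surrogates,
                               seed=child_seed(seed, f"sur-{rep}"))
        _, p = map_similarity_test(a, b, ens)
        ps.append(p)
    ks = float(stats.kstest(ps, "uniform").statistic)
    ratios = []
    for rep in range(20):
        x = smooth(rng.standard_normal(space.n), space, 6.0, 6.0)
        ens = moran_surrogates(x, space, structure, n=n_surrogates,
                               seed=child_seed(seed, f"smooth-{rep}"))
        if ens.i_original != 0:
            ratios.append(float(ens.i_surrogates.mean()) / ens.i_original)
    return {"p_ks_distance": ks, "moran_i_ratio": float(np.mean(ratios))}


# ---------------------------------------------------------------------------
# dynamics

def decay_recovery(n_replicates: int = 100, noise_sd: float = 0.05,
                   sessions_per_phase: int = 14, seed: int = 0) -> dict:
    """Two-rate decay-model parameter recovery: exact on a noise-free
    curve; median relative rate error under session noise."""
    a1, a2, amp, base = 0.5, 0.8, 0.4, 0.1
    S = sessions_per_phase
    days = np.concatenate([np.arange(-S, 0), np.arange(1, S + 1),
                           np.arange(S + 1, 2 * S + 1)]).astype(float)
    phases = np.array(["pre"] * S + ["cast"] * S + ["post"] * S)
    t_cast, t_off = 0.0, float(S)
    clean = decay_curve(days, a1, a2, amp, base, t_cast=t_cast, t_off=t_off)
    f0 = fit_decay(days, clean, phases, t_cast=t_cast, t_off=t_off, seed=seed)
    exact_err = max(abs(f0.a1_rate - a1), abs(f0.a2_rate - a2),
                    abs(f0.amplitude - amp), abs(f0.baseline - base))
    rng = np.random.default_rng(child_seed(seed, "decay"))
    rel1, rel2 = [], []
    for rep in range(n_replicates):
        y = clean + rng.normal(0.0, noise_sd, size=days.size)
        f = fit_decay(days, y, phases, t_cast=t_cast, t_off=t_off, seed=rep)
        rel1.append(abs(f.a1_rate - a1) / a1)
        rel2.append(abs(f.a2_rate - a2) / a2)
    return {
        "noise_free_max_abs_error": float(exact_err),
        "median_rel_error_a1": float(np.median(rel1)),
        "median_rel_error_a2": float(np.median(rel2)),
    }


# ---------------------------------------------------------------------------
# generator effect-size calibration

def effect_size_calibration(n_replicates: int = 100, seed: int = 0) -> dict:
    """Empirical cast-vs-pre Cohen's d at the injected blob (target 2.5)
    and under a d=0 null, measured on raw generated sessions."""
    from .fc_change import phase_effect_size

    params = SimParams()
    space = make_space(params, seed)
    truth = make_truth(space, params, seed)
    ds = []
    for rep in range(n_replicates):
        maps = _study_fc_maps(space, truth, params,
                              child_seed(seed, f"cal-{rep}"))
        eff = phase_effect_size(maps, "cast", "pre")
        ds.append(float(np.nanmean(eff.d[truth.rois["fc-blob"]])))
    params0 = SimParams(effect_d=0.0, pulse_rate_per_run=0.0)
    truth0 = make_truth(space, params0, seed)
    ds0 = []
    for rep in range(max(n_replicates // 2, 20)):
        maps = _study_fc_maps(space, truth0, params0,
                              child_seed(seed, f"cal0-{rep}"))
        eff = phase_effect_size(maps, "cast", "pre")
        ds0.append(float(np.nanmean(eff.d[truth0.rois["fc-blob"]])))
    return {"mean_d": float(np.mean(ds)), "null_mean_d": float(np.mean(ds0))}
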