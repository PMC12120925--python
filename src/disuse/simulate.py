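"""Synthetic multi-session BOLD generator with full ground truth.

Emulates the statistical structure the downstream analyses assume: AR(1)
temporal noise, spatially smoothed within structures; a signal-amplitude
profile that drops toward the brain center (coil-distance signal loss);
shared network latents (a global component and a homotopic sensorimotor
component); a seed-coupled latent whose loading differs by experimental
phase so that the cast-vs-pre Cohen's d of seed FC hits a configurable
target; spontaneous lateralized pulse events with double-gamma shape and
region-specific latency offsets; and head-motion traces with censorable
spikes and optional motion-locked artifact events.

Nothing here simulates MR physics — data are generated directly in
registered grayordinate space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from ._utils import child_seed
from .datamodel import BoldRun, MotionTrace
from .hrf import double_gamma
from .preprocess import smooth
from .space import SURFACE, VOLUME, GrayordinateSpace, block_diag_spaces, lattice_adjacency

# 3-D structures and rough MNI-like centers (mm); cortex sheets are placed
# laterally as 2-D lattices.
_VOLUME_CENTERS = {
    "thalamus-left": (-12.0, -18.0, 8.0),
    "thalamus-right": (12.0, -18.0, 8.0),
    "putamen-left": (-26.0, 0.0, 0.0),
    "putamen-right": (26.0, 0.0, 0.0),
    "pallidum-left": (-19.0, -4.0, 0.0),
    "pallidum-right": (19.0, -4.0, 0.0),
    "caudate-left": (-13.0, 12.0, 9.0),
    "caudate-right": (13.0, 12.0, 9.0),
    "cerebellum-left": (-22.0, -60.0, -30.0),
    "cerebellum-right": (22.0, -60.0, -30.0),
}


@dataclass
class SimParams:
    """Generator configuration.

    Sizes are scaled down from the study (30-minute daily runs, 14 sessions
    per phase) to desk scale while keeping the same statistical structure.
    """

    cortex_shape: tuple = (12, 12)       # per-hemisphere surface lattice
    thalamus_shape: tuple = (4, 4, 4)
    putamen_shape: tuple = (3, 3, 3)
    pallidum_shape: tuple = (2, 2, 3)
    caudate_shape: tuple = (2, 3, 3)
    cerebellum_shape: tuple = (4, 4, 4)
    sessions_per_phase: int = 6
    T: int = 240                         # frames per run
    tr_seconds: float = 1.1
    ar1_coefficient: float = 0.5
    noise_smooth_fwhm_mm: float = 4.7    # spatial smoothness of the noise
    noise_sd: float = 1.0
    baseline_level: float = 1000.0       # raw-signal mean, scaled by SNR profile
    snr_center_drop: float = 0.6         # fractional amplitude loss at brain center
    snr_length_scale_mm: float = 40.0
    global_loading: float = 0.3
    homotopic_loading: float = 1.0       # SM1 left/right shared signal
    fc_base_coupling: float = 0.3        # pre-cast seed coupling of targets
    effect_d: float = 2.5                # target cast-vs-pre Cohen's d
    fc_target_structure: str = "thalamus-left"
    fc_blob_size: int = 40
    fc_dynamics: bool = False            # modulate coupling by the decay curve
    pulse_rate_per_run: float = 2.0      # cast-phase runs only
    pulse_amplitude_sd: float = 4.0      # kernel peak in ROI-difference-SD units
    latency_offsets: dict = field(
        default_factory=lambda: {"thalamus-left": 0.95, "thalamus-right": 0.95}
    )
    pulse_relative_amplitude: dict = field(
        default_factory=lambda: {"thalamus-left": 1.0, "thalamus-right": 0.6}
    )
    motion_spike_rate: float = 0.01      # per frame, censorable FD spikes
    motion_locked_fraction: float = 0.0  # spurious motion-locked events
    decay_a1: float = 0.5                # 1/day, FC rise during cast
    decay_a2: float = 0.8                # 1/day, recovery post-cast
    decay_amplitude: float = 0.4         # peak FC deviation (r units)
    decay_baseline: float = 0.1
    task_beta: float = 1.0               # % signal change of task activation

    def __post_init__(self):
        if self.sessions_per_phase < 2:
            raise ValueError("sessions_per_phase must be >= 2")
        for name in ("pulse_rate_per_run", "motion_spike_rate",
                     "motion_locked_fraction", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.effect_d):
            raise ValueError("effect_d must be finite")


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery testing."""

    rois: dict                 # name -> grayordinate index array
    fc_effect: np.ndarray      # true cast-vs-pre Cohen's d per grayordinate
    task_betas: dict           # condition -> per-grayordinate amplitude
    decay_params: dict         # a1_rate, a2_rate, amplitude, baseline
    injected_pulses: list = field(default_factory=list)
    coupling: dict = field(default_factory=dict)   # phase -> effective loading
    sigma_roi_diff: float = 1.0
    sigma_roi_left: float = 1.0


# ---------------------------------------------------------------------------
# space construction

def make_space(params: SimParams, seed: int = 0) -> GrayordinateSpace:
    """Build the grayordinate substrate: two cortical sheets (4-neighbor
    lattices) plus bilateral subcortical/cerebellar boxes (6-neighbor
    lattices) at plausible anatomical offsets, with a signal-amplitude
    profile decaying toward the brain center."""
    h = 3.0
    blocks, coords, labels, kinds = [], [], [], []

    def add_structure(name, shape, center, kind):
        if int(np.prod(shape)) < 1:
            raise ValueError(f"zero-size structure {name}")
        grid = np.indices(shape).reshape(len(shape), -1).T.astype(float)
        if kind == SURFACE:
            grid -= grid.mean(axis=0)
            # a sheet in the sagittal plane at fixed |x|
            xyz = np.column_stack([
                np.full(len(grid), center[0]),
                center[1] + grid[:, 0] * h,
                center[2] + grid[:, 1] * h,
            ])
        else:
            # volume voxels live on the global h-mm lattice so distinct
            # structures never collide in a shared voxel grid
            grid -= np.floor(grid.mean(axis=0))
            snapped = np.round(np.asarray(center) / h) * h
            xyz = snapped + grid * h
        blocks.append(lattice_adjacency(shape))
        coords.append(xyz)
        labels.extend([name] * len(grid))
        kinds.extend([kind] * len(grid))

    # canonical order: sorted by structure label, so add in sorted order
    specs = {
        "cortex-left": (params.cortex_shape, (-50.0, -20.0, 40.0), SURFACE),
        "cortex-right": (params.cortex_shape, (50.0, -20.0, 40.0), SURFACE),
    }
    for name, center in _VOLUME_CENTERS.items():
        base = name.split("-")[0]
        shape = getattr(params, f"{base}_shape")
        specs[name] = (shape, center, VOLUME)
    for name in sorted(specs):
        shape, center, kind = specs[name]
        add_structure(name, shape, center, kind)

    coords = np.vstack(coords)
    r = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    snr = 1.0 - params.snr_center_drop * np.exp(
        -((r / params.snr_length_scale_mm) ** 2)
    )
    return GrayordinateSpace(
        coords=coords,
        structure_label=np.array(labels),
        adjacency=block_diag_spaces(blocks),
        kind=np.array(kinds),
        snr=snr,
        voxel_size_mm=h,
    )


def _block_roi(space: GrayordinateSpace, structure: str, size: int) -> np.ndarray:
    """A compact connected ROI: the `size` grayordinates of a structure
    closest to its centroid (ties by index)."""
    idx = space.indices(structure)
    c = space.coords[idx].mean(axis=0)
    d = np.linalg.norm(space.coords[idx] - c, axis=1)
    order = np.lexsort((idx, d))
    return np.sort(idx[order[:size]])


def make_truth(space: GrayordinateSpace, params: SimParams, seed: int = 0) -> GroundTruth:
    """ROIs, true effect maps, task betas and decay parameters."""
    rois = {
        "sm1ue-left": _block_roi(space, "cortex-left", 16),
        "sm1ue-right": _block_roi(space, "cortex-right", 16),
        "fc-blob": _block_roi(space, params.fc_target_structure, params.fc_blob_size),
    }
    for struct in params.latency_offsets:
        rois[f"pulse-{struct}"] = _block_roi(space, struct, 20)
    fc_effect = np.zeros(space.n)
    fc_effect[rois["fc-blob"]] = params.effect_d
    betas = np.zeros(space.n)
    betas[rois["sm1ue-left"]] = params.task_beta
    betas[rois["fc-blob"]] = params.task_beta
    task_betas = {"right-hand": betas}
    decay = {
        "a1_rate": params.decay_a1,
        "a2_rate": params.decay_a2,
        "amplitude": params.decay_amplitude,
        "baseline": params.decay_baseline,
    }
    return GroundTruth(
        rois=rois, fc_effect=fc_effect, task_betas=task_betas, decay_params=decay
    )


# ---------------------------------------------------------------------------
# temporal building blocks

def ar1_series(rng: np.random.Generator, shape: tuple, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis."""
    burn = 50
    e = rng.standard_normal(shape[:-1] + (shape[-1] + burn,))
    x = signal.lfilter([np.sqrt(1.0 - phi**2)], [1.0, -phi], e, axis=-1)
    return x[..., burn:]


def _population_r(a: float, b: float, g: float) -> float:
    """Population correlation of target (loading a) with a seed voxel
    (loading b), both carrying the global latent (loading g) over unit
    noise."""
    num = a * b + g * g
    den = np.sqrt((a * a + g * g + 1.0) * (b * b + g * g + 1.0))
    return num / den


def _coupling_for_r(r_target: float, b: float, g: float) -> float:
    f = lambda a: _population_r(a, b, g) - r_target
    return float(optimize.brentq(f, 0.0, 50.0))


_CALIB_CACHE: dict = {}


def _params_calib_key(params: SimParams) -> tuple:
    return (
        params.cortex_shape, params.thalamus_shape, params.T,
        params.tr_seconds, params.ar1_coefficient,
        params.noise_smooth_fwhm_mm, params.noise_sd,
        params.snr_center_drop, params.global_loading,
        params.homotopic_loading, params.fc_base_coupling,
        params.effect_d, params.fc_target_structure, params.fc_blob_size,
    )


def calibrate_coupling(
    params: SimParams,
    seed: int = 0,
    space: GrayordinateSpace | None = None,
    truth: GroundTruth | None = None,
    n_pre: int = 150,
    n_cast: int = 100,
) -> dict:
    """Solve the cast-phase seed coupling so the empirical cast-vs-pre
    Cohen's d of per-session seed FC (measured on raw generated series)
    hits ``params.effect_d``.

    The between-session SD of a target voxel's seed FC depends on the
    run's effective temporal degrees of freedom and on the noise
    correlation across seed voxels induced by spatial smoothing, so it is
    measured by Monte Carlo with the actual measurement protocol: simulate
    pulse-free sessions, compute seed FC maps, and read off the mean and
    between-session SD at the target blob. The requested d then converts
    into a population-correlation shift, inverted analytically for the
    loading. Results are cached per parameter set; the internal seed is
    fixed so calibration is a pure function of the parameters.
    """
    key = _params_calib_key(params)
    if key in _CALIB_CACHE:
        return _CALIB_CACHE[key]
    b, g = params.homotopic_loading, params.global_loading
    a_pre = params.fc_base_coupling
    if params.effect_d == 0 or params.noise_sd == 0:
        out = {"a_pre": a_pre, "a_cast": a_pre,
               "r_pre": _population_r(a_pre, b, g),
               "r_cast": _population_r(a_pre, b, g), "sd_r": np.nan}
        _CALIB_CACHE[key] = out
        return out
    if space is None:
        space = make_space(params, 0)
    if truth is None:
        truth = make_truth(space, params, 0)
    # placeholder so recursive simulate_run calls skip calibration
    _CALIB_CACHE[key] = {"a_pre": a_pre, "a_cast": a_pre,
                         "r_pre": np.nan, "r_cast": np.nan, "sd_r": np.nan}
    from .fc_change import seed_fc_map  # local import: avoid module cycle

    cal_truth = GroundTruth(
        rois=truth.rois, fc_effect=truth.fc_effect,
        task_betas=truth.task_betas, decay_params=truth.decay_params,
    )
    blob = truth.rois["fc-blob"]
    seed_roi = truth.rois["sm1ue-left"]
    base_seed = child_seed(0, "fc-calibration")

    def session_r(a: float, k: int, tag: str) -> np.ndarray:
        rows = []
        for i in range(k):
            run = simulate_run(
                space, f"calib-{tag}-{i}", "pre", 0.0, params, cal_truth,
                seed=child_seed(base_seed, f"{tag}-{i}"),
                _coupling_override=a,
            )
            rows.append(seed_fc_map(run, seed_roi).r[blob])
        return np.stack(rows)

    # the contract is on the *empirical* Cohen's d at the configured
    # session count, which overestimates the population d by the Hedges
    # small-sample factor 1/J; target the population d that makes the
    # estimator's expectation hit effect_d
    nu = 2 * params.sessions_per_phase - 2
    d_eff = params.effect_d * (1.0 - 3.0 / (4.0 * nu - 1.0))

    R_pre = session_r(a_pre, n_pre, "pre")
    r_pre = float(R_pre.mean())
    sd_pre = float(np.mean(R_pre.std(axis=0, ddof=1)))
    a_cast = _coupling_for_r(
        min(r_pre + d_eff * sd_pre, 0.99), b, g
    )
    # one refinement: correct for the cast-phase SD and for the small
    # finite-T bias between measured and population correlation
    R_cast = session_r(a_cast, n_cast, "cast")
    sd_cast = float(np.mean(R_cast.std(axis=0, ddof=1)))
    sd_pool = float(np.sqrt(0.5 * (sd_pre**2 + sd_cast**2)))
    bias = float(R_cast.mean()) - _population_r(a_cast, b, g)
    target_pop = r_pre + d_eff * sd_pool - bias
    a_cast = _coupling_for_r(min(max(target_pop, 0.0), 0.99), b, g)
    out = {
        "a_pre": a_pre,
        "a_cast": a_cast,
        "r_pre": r_pre,
        "r_cast": _population_r(a_cast, b, g) + bias,
        "sd_r": sd_pool,
    }
    _CALIB_CACHE[key] = out
    return out


def decay_curve(days: np.ndarray, a1: float, a2: float, amplitude: float,
                baseline: float, t_cast: float = 0.0,
                t_off: float | None = None) -> np.ndarray:
    """Two-rate FC time course: saturating rise during cast, exponential
    recovery after cast removal, continuous at the boundary."""
    days = np.asarray(days, dtype=float)
    if t_off is None:
        t_off = float(days[days >= t_cast].max(initial=t_cast))
    out = np.full(days.shape, baseline, dtype=float)
    cast = (days >= t_cast) & (days <= t_off)
    post = days > t_off
    out[cast] = baseline + amplitude * (1.0 - np.exp(-a1 * (days[cast] - t_cast)))
    a_end = amplitude * (1.0 - np.exp(-a1 * (t_off - t_cast)))
    out[post] = baseline + a_end * np.exp(-a2 * (days[post] - t_off))
    return out


# ---------------------------------------------------------------------------
# run simulation

def _pulse_kernel(tr: float, amplitude: float, extra_delay_s: float = 0.0,
                  length_s: float = 30.0) -> np.ndarray:
    """Double-gamma kernel sampled at TR; scaled so the *sampled* peak
    equals ``amplitude`` (a "4-SD pulse" is one whose peak sample is 4 SD,
    independent of where the continuous peak falls between samples)."""
    t = np.arange(0.0, length_s, tr)
    k = double_gamma(t - extra_delay_s)
    peak = k.max()
    return amplitude * k / peak if peak > 0 else k


def _draw_onsets(rng, n_events: int, T: int, tr: float,
                 min_sep_s: float = 33.0) -> list[int]:
    lo = int(round(5.0 / tr))
    hi = T - int(round(30.0 / tr))
    if hi <= lo:
        raise ValueError("run too short for pulse injection")
    onsets: list[int] = []
    for _ in range(200):
        if len(onsets) == n_events:
            break
        cand = int(rng.integers(lo, hi))
        if all(abs(cand - o) * tr >= min_sep_s for o in onsets):
            onsets.append(cand)
    return sorted(onsets)


def _motion_trace(rng, T: int, spike_rate: float) -> tuple[MotionTrace, np.ndarray]:
    """Rigid-body parameters = slow random-walk drift + frame-to-frame
    measurement jitter, with Poisson censorable FD spikes; baseline FD is
    ~0.02 mm. Returns the trace and the spike frames."""
    diffs = rng.normal(0.0, 0.0015, size=(T, 6))
    spikes = np.flatnonzero(rng.random(T - 1) < spike_rate) + 1
    for s in spikes:
        j = int(rng.integers(6))
        diffs[s, j] += 0.15 + rng.exponential(0.1)
    diffs[0] = 0.0
    params6 = np.cumsum(diffs, axis=0)
    jitter_sd = np.array([0.01, 0.0005, 0.0005, 0.0005, 0.0005, 0.0005])
    params6 = params6 + rng.normal(0.0, 1.0, size=(T, 6)) * jitter_sd
    return MotionTrace.from_params(params6), spikes


def simulate_run(
    space: GrayordinateSpace,
    session_id: str,
    phase: str,
    day_index: float,
    params: SimParams,
    truth: GroundTruth,
    seed: int,
    pulse_onsets: list[int] | None = None,
    _coupling_override: float | None = None,
) -> BoldRun:
    """Generate one resting-state run; injected pulses are appended to
    ``truth.injected_pulses``.

    The raw-data model per grayordinate i is

        y_i(t) = snr_i * baseline + snr_i * 1%-scale * s_i(t)

    with s_i = global + homotopic/seed latents + coupled latent + pulses +
    unit-SD AR(1) noise (spatially smoothed within structure). The SNR
    profile scales each voxel's whole series, so correlations (and the
    calibrated FC ground truth) are unaffected by it; pulse kernels are
    additionally scaled by local SNR inside the fluctuation term, so pulse
    amplitude relative to noise is lower in low-SNR (deep) regions, as in
    real data.
    """
    rng = np.random.default_rng(child_seed(seed, f"run:{session_id}"))
    n, T, tr = space.n, params.T, params.tr_seconds
    phi = params.ar1_coefficient
    snr = space.snr if space.snr is not None else np.ones(n)

    if params.noise_sd > 0:
        noise = ar1_series(rng, (n, T), phi)
        noise = smooth(noise, space,
                       fwhm_surface_mm=params.noise_smooth_fwhm_mm,
                       fwhm_volume_mm=params.noise_smooth_fwhm_mm)
        sd = noise.std(axis=1, ddof=0, keepdims=True)
        noise = params.noise_sd * noise / np.maximum(sd, 1e-12)
    else:
        noise = np.zeros((n, T))

    sig = noise.copy()

    # network latents
    q = ar1_series(rng, (T,), phi)       # seed / homotopic latent
    G = ar1_series(rng, (T,), phi)       # global latent
    if params.noise_sd > 0:
        sig += params.global_loading * G[None, :]
        lefts = truth.rois["sm1ue-left"]
        rights = truth.rois["sm1ue-right"]
        sig[lefts] += params.homotopic_loading * q[None, :]
        sig[rights] += params.homotopic_loading * q[None, :]
        # phase-dependent seed coupling of the target blob
        if _coupling_override is not None:
            a = _coupling_override
        else:
            calib = calibrate_coupling(params, seed, space=space, truth=truth)
            truth.coupling = {
                "pre": calib["a_pre"], "cast": calib["a_cast"],
                "post": calib["a_pre"],
                "r_pre": calib["r_pre"], "r_cast": calib["r_cast"],
            }
            a = _phase_coupling(phase, day_index, params, calib)
        blob = truth.rois["fc-blob"]
        sig[blob] += a * q[None, :]

    # pulse injection (cast phase); amplitude is expressed in SD units of
    # the left ROI detection series (noise + network latents), the scale
    # against which the detection thresholds are defined
    sigma_diff = _roi_diff_sd(noise, truth)
    truth.sigma_roi_diff = sigma_diff
    left_series = (noise[truth.rois["sm1ue-left"]].mean(axis=0)
                   + params.homotopic_loading * q
                   + params.global_loading * G) if params.noise_sd > 0 else None
    sigma_left = float(np.std(left_series, ddof=0)) if left_series is not None else 0.0
    truth.sigma_roi_left = sigma_left
    if phase == "cast":
        if pulse_onsets is None:
            n_ev = rng.poisson(params.pulse_rate_per_run)
            pulse_onsets = _draw_onsets(rng, n_ev, T, tr)
        else:
            if any(o < 0 or o >= T for o in pulse_onsets):
                raise ValueError("pulse onset beyond run length")
            pulse_onsets = sorted(pulse_onsets)
        amp = (params.pulse_amplitude_sd * sigma_left if sigma_left > 0
               else 1.0)  # noise-free limit: unit kernel
        for onset in pulse_onsets:
            _add_pulse(sig, space, truth, params, onset, amp, tr, snr)
            truth.injected_pulses.append({
                "session_id": session_id,
                "onset_frame": int(onset),
                "amplitude": float(amp),
                "regions": ["sm1ue-left"] + [f"pulse-{s}" for s in params.latency_offsets],
                "latency_offsets_s": dict(params.latency_offsets),
                "motion_locked": False,
            })

    motion, fd_spikes = _motion_trace(rng, T, params.motion_spike_rate)

    # spurious motion-locked events (kept clear of censorable FD spikes,
    # whose censoring residue would dominate the screening window)
    f = params.motion_locked_fraction
    if f > 0 and phase == "cast":
        rate = params.pulse_rate_per_run * f / max(1e-9, 1.0 - f)
        n_sp = rng.poisson(rate)
        taken = [p["onset_frame"] for p in truth.injected_pulses
                 if p["session_id"] == session_id]
        half_w = int(round(12.0 / tr))
        for _ in range(n_sp):
            onset = None
            for _try in range(30):
                cands = _draw_onsets(rng, 1, T, tr)
                if (cands
                        and all(abs(cands[0] - o) * tr >= 33.0 for o in taken)
                        and all(abs(cands[0] - s) > half_w for s in fd_spikes)):
                    onset = cands[0]
                    break
            if onset is None:
                continue
            taken.append(onset)
            _add_motion_locked_event(sig, motion, truth, params, onset,
                                     12.0 * (sigma_left or 1.0), tr, rng)
            truth.injected_pulses.append({
                "session_id": session_id,
                "onset_frame": int(onset),
                "amplitude": float(12.0 * (sigma_left or 1.0)),
                "regions": ["sm1ue-left"],
                "latency_offsets_s": {},
                "motion_locked": True,
            })

    # raw-signal scale: baseline plus fluctuations in ~percent units
    scale = 0.01 * params.baseline_level
    data = snr[:, None] * (params.baseline_level + scale * sig)
    return BoldRun(
        data=data, tr_seconds=tr, session_id=session_id, phase=phase,
        motion=motion, day_index=day_index,
    )


def _phase_coupling(phase: str, day: float, params: SimParams, calib: dict) -> float:
    if not params.fc_dynamics:
        return {"pre": calib["a_pre"], "cast": calib["a_cast"],
                "post": calib["a_pre"]}[phase]
    dr = calib["r_cast"] - calib["r_pre"]
    t_off = float(params.sessions_per_phase)
    r = decay_curve(
        np.array([day]), params.decay_a1, params.decay_a2, dr,
        calib["r_pre"], t_cast=0.0, t_off=t_off,
    )[0]
    return _coupling_for_r(min(max(r, 0.0), 0.99),
                           params.homotopic_loading, params.global_loading)


def _roi_diff_sd(noise: np.ndarray, truth: GroundTruth) -> float:
    l = noise[truth.rois["sm1ue-left"]].mean(axis=0)
    r = noise[truth.rois["sm1ue-right"]].mean(axis=0)
    return float(np.std(l - r, ddof=0))


def _add_pulse(sig, space, truth, params, onset, amp, tr, snr):
    k0 = _pulse_kernel(tr, amp)
    for name, rel, delay in _pulse_targets(params):
        roi = truth.rois[name]
        k = k0 if delay == 0.0 else _pulse_kernel(tr, amp, extra_delay_s=delay)
        seg = min(len(k), sig.shape[1] - onset)
        sig[roi, onset:onset + seg] += rel * snr[roi][:, None] * k[None, :seg]


def _pulse_targets(params: SimParams):
    yield "sm1ue-left", 1.0, 0.0
    for struct, delay in params.latency_offsets.items():
        rel = params.pulse_relative_amplitude.get(struct, 1.0)
        yield f"pulse-{struct}", rel, float(delay)


def _add_motion_locked_event(sig, motion: MotionTrace, truth, params, onset,
                             amp, tr, rng):
    """A left-lateralized artifact sharing its waveform with one motion
    parameter: a sub-censoring-threshold head movement (per-frame
    displacement < 0.1 mm) that nevertheless imprints a large transient on
    the ROI series, so it correlates highly with head motion over the
    screening window while surviving frame censoring."""
    width = max(3, int(round(5.5 / tr)))
    w = np.exp(-np.arange(width) / (width / 2.5))
    seg = min(width, sig.shape[1] - onset)
    p = motion.params6.copy()
    p[onset:onset + seg, 0] += 0.08 * w[:seg]
    motion.params6[:] = p
    motion.fd_mm[:] = MotionTrace.from_params(p).fd_mm
    # the BOLD artifact tracks the motion parameter itself over the full
    # screening window (motion-locked by construction: same waveform, so
    # nuisance regression can shrink but not reshape it)
    half = int(round(9.0 / tr))
    lo = max(0, onset - half)
    hi = min(sig.shape[1], onset + int(round(16.0 / tr)))
    shape = p[lo:hi, 0] - p[lo:hi, 0].mean()
    m = np.abs(shape).max()
    if m > 0:
        roi = truth.rois["sm1ue-left"]
        sig[roi, lo:hi] += amp * shape[None, :] / m


def simulate_task_run(
    space: GrayordinateSpace,
    schedule: list[tuple[str, float, float]],
    params: SimParams,
    truth: GroundTruth,
    seed: int,
    session_id: str = "task",
    phase: str = "pre",
    day_index: float = 0.0,
) -> BoldRun:
    """A task run: the resting-run noise model plus condition boxcars
    convolved with the double-gamma HRF, scaled by the true betas.

    ``schedule`` rows are (condition, onset_s, duration_s).
    """
    by_cond: dict[str, list] = {}
    for cond, onset, dur in schedule:
        by_cond.setdefault(cond, []).append((float(onset), float(dur)))
    T, tr = params.T, params.tr_seconds
    for cond, blocks in by_cond.items():
        blocks.sort()
        for (o1, d1), (o2, _) in zip(blocks, blocks[1:]):
            if o1 + d1 > o2:
                raise ValueError(f"overlapping blocks of condition {cond!r}")
        for o, d in blocks:
            if o + d > T * tr:
                raise ValueError("block beyond run duration")

    run = simulate_run(space, session_id, phase, day_index, params, truth, seed)
    scale = 0.01 * params.baseline_level
    snr = space.snr if space.snr is not None else np.ones(space.n)
    t = np.arange(T) * tr
    hrf = double_gamma(np.arange(0.0, 30.0, tr))
    for cond, blocks in by_cond.items():
        if cond not in truth.task_betas:
            continue
        box = np.zeros(T)
        for o, d in blocks:
            box[(t >= o) & (t < o + d)] = 1.0
        reg = np.convolve(box, hrf)[:T]
        betas = truth.task_betas[cond]
        run.data += scale * (snr * betas)[:, None] * reg[None, :]
    return run


# ---------------------------------------------------------------------------
# study-level convenience

def simulate_study(
    params: SimParams, seed: int = 0, phases: tuple = ("pre", "cast"),
) -> tuple[GrayordinateSpace, GroundTruth, list[BoldRun]]:
    """Space, ground truth and one run per session for the given phases.

    Day indices: pre-cast days are negative, cast days 1..S, post-cast days
    S+1..2S (sessions are daily, as in the study design).
    """
    space = make_space(params, seed)
    truth = make_truth(space, params, seed)
    runs = []
    S = params.sessions_per_phase
    day0 = {"pre": -S, "cast": 0, "post": S}
    for phase in phases:
        for i in range(S):
            day = day0[phase] + i + 1
            sid = f"{phase}-{i + 1:02d}"
            runs.append(
                simulate_run(space, sid, phase, day, params, truth,
                             seed=child_seed(seed, sid))
            )
    return space, truth, runs
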