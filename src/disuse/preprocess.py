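"""Denoising chain: SNR mapping, frame censoring, temporal filtering,
nuisance regression, and graph-based spatial smoothing.

The implemented order for filtering censored data is: censor mask computed
first, censored frames linearly interpolated, zero-phase filter applied on
the full grid, then the censored frames dropped (censor -> interpolate ->
filter -> re-censor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import signal
from scipy.linalg import qr as scipy_qr

from .datamodel import BoldRun, StudyConfig
from .hrf import FWHM_PER_SD
from .space import SURFACE, GrayordinateSpace


@dataclass
class SNRMap:
    """Per-grayordinate signal-to-noise: temporal mean divided by temporal
    variability (variance by default; SD selectable). ``percent_drop`` is
    100*value minus the map maximum, so its own maximum is exactly 0."""

    value: np.ndarray
    denominator: str = "variance"

    @property
    def percent_drop(self) -> np.ndarray:
        v = 100.0 * self.value
        return v - np.nanmax(v)


@dataclass
class CensorMask:
    """Frame-retention flags from framewise-displacement screening."""

    keep: np.ndarray
    threshold_mm: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def __len__(self) -> int:
        return len(self.keep)


def compute_snr_map(
    runs: BoldRun | list[BoldRun], denominator: str = "variance"
) -> SNRMap:
    """Temporal mean over temporal variability, averaged across runs.

    Computed on data *before* nuisance regression. Zero-variability
    grayordinates are flagged undefined (NaN), never +inf.
    """
    if isinstance(runs, BoldRun):
        runs = [runs]
    if denominator not in ("variance", "sd"):
        raise ValueError("denominator must be 'variance' or 'sd'")
    maps = []
    for run in runs:
        mean = run.data.mean(axis=1)
        var = run.data.var(axis=1, ddof=1)
        denom = var if denominator == "variance" else np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(denom > 0, mean / denom, np.nan)
        maps.append(val)
    return SNRMap(value=np.nanmean(maps, axis=0), denominator=denominator)


def censor_frames(
    run: BoldRun, fd_threshold: float = 0.1, min_frames: int = 10
) -> tuple[BoldRun, CensorMask]:
    """Remove frames whose framewise displacement exceeds the threshold."""
    if not fd_threshold > 0:
        raise ValueError("fd_threshold must be positive")
    keep = run.motion.fd_mm <= fd_threshold
    mask = CensorMask(keep=keep, threshold_mm=float(fd_threshold))
    if mask.n_kept < min_frames:
        raise ValueError(
            f"run unusable: only {mask.n_kept} frames retained at "
            f"FD <= {fd_threshold} mm"
        )
    censored = BoldRun(
        data=run.data[:, keep],
        tr_seconds=run.tr_seconds,
        session_id=run.session_id,
        phase=run.phase,
        motion=run.motion.subset(keep),
        day_index=run.day_index,
    )
    return censored, mask


def _interpolate_censored(data: np.ndarray, keep: np.ndarray) -> np.ndarray:
    if keep.all():
        return data
    T = data.shape[1]
    t = np.arange(T)
    good = np.flatnonzero(keep)
    out = data.copy()
    bad = np.flatnonzero(~keep)
    for i in range(data.shape[0]):
        out[i, bad] = np.interp(t[bad], good, data[i, good])
    return out


def temporal_filter(
    run: BoldRun,
    mode: str = "bandpass",
    band: tuple[float, float] = (0.005, 0.1),
    censor_mask: CensorMask | None = None,
    order: int = 2,
) -> BoldRun:
    """Zero-phase Butterworth filtering of every grayordinate series.

    Modes
    -----
    ``bandpass``
        Band-pass between ``band[0]`` and ``band[1]`` Hz.
    ``highpass_only``
        High-pass at ``band[0]`` (drop the low-pass stage; preserves fast
        transients such as pulses for shape fitting).
    ``highpass_literal``
        High-pass at ``band[1]`` — the literal reading of a "high-pass at
        0.1 Hz" denoising variant; exposed for completeness, not default.

    If ``censor_mask`` is given, censored frames are linearly interpolated
    before filtering; the returned run keeps the full frame grid (drop the
    censored frames afterwards with :func:`censor_frames`).
    """
    nyq = 0.5 / run.tr_seconds
    lo, hi = band
    if mode == "bandpass":
        if not 0 < lo < hi < nyq:
            raise ValueError(f"band {band} outside (0, Nyquist={nyq:.3g})")
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=1.0 / run.tr_seconds, output="sos")
    elif mode == "highpass_only":
        if not 0 < lo < nyq:
            raise ValueError("high-pass edge outside (0, Nyquist)")
        sos = signal.butter(order, lo, btype="highpass", fs=1.0 / run.tr_seconds, output="sos")
    elif mode == "highpass_literal":
        if not 0 < hi < nyq:
            raise ValueError("high-pass edge outside (0, Nyquist)")
        sos = signal.butter(order, hi, btype="highpass", fs=1.0 / run.tr_seconds, output="sos")
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    data = run.data
    if censor_mask is not None:
        data = _interpolate_censored(data, censor_mask.keep)
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    # DC lies in the stopband of every mode; remove the residual mean the
    # zero-phase edge handling leaves behind
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return run.with_data(filtered)


def nuisance_regress(
    run: BoldRun,
    motion_params: np.ndarray | None = None,
    global_signal: np.ndarray | None = None,
    tissue_waveforms: np.ndarray | None = None,
    include_global: bool = True,
) -> BoldRun:
    """Residualize every grayordinate series against nuisance regressors.

    The design is [intercept, motion parameters, global gray-matter mean,
    tissue waveforms]; tissue waveforms are sequentially Gram-Schmidt
    orthogonalized against the preceding columns before inclusion.
    Rank-deficient designs drop collinear columns with a warning.
    """
    T = run.T
    cols = [np.ones((T, 1))]
    if motion_params is None:
        motion_params = run.motion.params6
    motion_params = np.asarray(motion_params, dtype=float)
    if motion_params.shape[0] != T:
        raise ValueError("regressor length must equal retained T")
    cols.append(motion_params)
    if include_global:
        if global_signal is None:
            global_signal = run.data.mean(axis=0)
        cols.append(np.asarray(global_signal, dtype=float).reshape(T, 1))
    X = np.column_stack(cols)
    if tissue_waveforms is not None:
        W = np.atleast_2d(np.asarray(tissue_waveforms, dtype=float))
        if W.shape[0] != T:
            W = W.T
        for j in range(W.shape[1]):
            w = W[:, j]
            beta, *_ = np.linalg.lstsq(X, w, rcond=None)
            w_orth = w - X @ beta
            if np.linalg.norm(w_orth) > 1e-10 * max(1.0, np.linalg.norm(w)):
                X = np.column_stack([X, w_orth])
            else:
                warnings.warn(f"tissue waveform {j} collinear; dropped")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; dropping collinear columns")
        _, _, piv = scipy_qr(X, mode="economic", pivoting=True)
        X = X[:, np.sort(piv[:rank])]
    beta, *_ = np.linalg.lstsq(X, run.data.T, rcond=None)
    resid = run.data - (X @ beta).T
    return run.with_data(resid)


# ---------------------------------------------------------------------------
# graph smoothing

_SMOOTH_CACHE: dict = {}


def _structure_operator(
    space: GrayordinateSpace, structure: str, fwhm_mm: float
) -> tuple[np.ndarray, sp.csr_matrix, int]:
    """Diffusion operator approximating a Gaussian kernel of the requested
    FWHM on one structure's lattice; returns (indices, operator, n_steps).

    One step of S = I - (w/k) L (L the graph Laplacian, k the full lattice
    degree) adds per-axis displacement variance (2w/k) h^2; m steps reach
    sigma^2 = m (2w/k) h^2.  S is symmetric and doubly stochastic, so mass
    and constants are preserved exactly.
    """
    key = (id(space), structure, round(fwhm_mm, 6))
    if key in _SMOOTH_CACHE:
        return _SMOOTH_CACHE[key]
    idx, A = space.sub_adjacency(structure)
    kinds = space.kind[idx]
    k_full = 4 if kinds[0] == SURFACE else 6
    h = space.voxel_size_mm
    sigma = fwhm_mm / FWHM_PER_SD
    w_max = 0.45
    var_per_step = 2.0 * w_max / k_full * h * h
    m = max(1, int(np.ceil(sigma**2 / var_per_step)))
    w = sigma**2 * k_full / (2.0 * m * h * h)
    deg = np.asarray(A.sum(axis=1)).ravel().astype(float)
    L = sp.diags(deg) - A.astype(float)
    S = (sp.identity(len(idx), format="csr") - (w / k_full) * L).tocsr()
    out = (idx, S, m)
    _SMOOTH_CACHE[key] = out
    return out


def smooth(
    values: np.ndarray,
    space: GrayordinateSpace,
    fwhm_surface_mm: float = 6.0,
    fwhm_volume_mm: float = 4.7,
) -> np.ndarray:
    """Gaussian graph smoothing of a map (n,) or run data (n, T).

    Surface-like structures use the 2-D kernel width, volume-like the 3-D
    width; smoothing never mixes structures.
    """
    if not (fwhm_surface_mm > 0 and fwhm_volume_mm > 0):
        raise ValueError("fwhm must be positive")
    x = np.asarray(values, dtype=float)
    out = x.copy()
    for structure in space.structures:
        idx = space.indices(structure)
        fwhm = fwhm_surface_mm if space.kind[idx[0]] == SURFACE else fwhm_volume_mm
        _, S, m = _structure_operator(space, structure, fwhm)
        block = out[idx]
        for _ in range(m):
            block = S @ block
        out[idx] = block
    return out


def smooth_run(run: BoldRun, space: GrayordinateSpace, **kw) -> BoldRun:
    return run.with_data(smooth(run.data, space, **kw))


def preprocess_run(
    run: BoldRun,
    space: GrayordinateSpace | None = None,
    config: StudyConfig | None = None,
    do_smooth: bool = True,
) -> tuple[BoldRun, CensorMask]:
    """Full denoising chain on one run: censor-aware zero-phase filtering,
    frame censoring, nuisance regression, and spatial smoothing."""
    config = config or StudyConfig()
    _, mask = censor_frames(run, config.fd_threshold)
    filtered = temporal_filter(
        run, mode=config.filter_mode, band=config.band, censor_mask=mask
    )
    censored, _ = censor_frames(filtered, config.fd_threshold)
    clean = nuisance_regress(censored)
    if do_smooth and space is not None:
        clean = smooth_run(
            clean,
            space,
            fwhm_surface_mm=config.smooth_fwhm_surface,
            fwhm_volume_mm=config.smooth_fwhm_volume,
        )
    return clean, mask
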