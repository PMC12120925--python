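"""Core run-level data types and study configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

PHASES = ("pre", "cast", "post")


@dataclass
class MotionTrace:
    """Per-frame head motion: framewise displacement plus the six rigid-body
    parameter series (3 translations mm, 3 rotations deg)."""

    fd_mm: np.ndarray
    params6: np.ndarray  # (T, 6)

    def __post_init__(self):
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        self.params6 = np.asarray(self.params6, dtype=float)
        if self.fd_mm.ndim != 1:
            raise ValueError("fd_mm must be 1-D")
        T = len(self.fd_mm)
        if self.params6.shape != (T, 6):
            raise ValueError("params6 must be (T, 6)")
        if np.any(self.fd_mm < 0):
            raise ValueError("fd_mm must be nonnegative")
        # first frame has no predecessor: FD defined as 0
        if T and self.fd_mm[0] != 0:
            raise ValueError("first-frame FD must be 0")

    def __len__(self) -> int:
        return len(self.fd_mm)

    @classmethod
    def from_params(cls, params6: np.ndarray) -> "MotionTrace":
        """FD as the sum of absolute backward differences of the six
        parameters (rotations already expressed in mm-equivalent units)."""
        p = np.asarray(params6, dtype=float)
        fd = np.zeros(len(p))
        if len(p) > 1:
            fd[1:] = np.abs(np.diff(p, axis=0)).sum(axis=1)
        return cls(fd_mm=fd, params6=p)

    def subset(self, keep: np.ndarray) -> "MotionTrace":
        fd = self.fd_mm[keep].copy()
        if fd.size:
            fd[0] = 0.0
        return MotionTrace(fd_mm=fd, params6=self.params6[keep])


@dataclass
class BoldRun:
    """One fMRI run: grayordinate-by-time data with session metadata.

    ``data`` is (n grayordinates, T frames) in arbitrary signal units.
    ``phase`` is one of pre / cast / post; ``day_index`` counts days from
    cast onset (negative during the pre-cast baseline).
    """

    data: np.ndarray
    tr_seconds: float
    session_id: str
    phase: str
    motion: MotionTrace
    day_index: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n, T)")
        if self.data.shape[1] < 2:
            raise ValueError("run must have T >= 2 frames")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if len(self.motion) != self.T:
            raise ValueError(
                f"motion trace length {len(self.motion)} != T {self.T}"
            )

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def T(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.T) * self.tr_seconds

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class StudyConfig:
    """All stage parameters, defaulting to the study's printed constants."""

    fd_threshold: float = 0.1            # mm, frame censoring
    band: tuple = (0.005, 0.1)           # Hz, resting-state band-pass
    filter_mode: str = "bandpass"        # or "highpass_only"
    z_pulse: float = 2.3                 # SD threshold for pulse detection
    motion_r_max: float = 0.8            # motion-correlation screen
    motion_window_s: float = 18.0        # screening window, s
    n_perm: int = 1000                   # session-label permutations
    n_cluster_thresholds: int = 10       # decile threshold grid
    min_thresholds_passed: int = 2
    alpha: float = 0.05
    detectability_top_fraction: float = 0.20
    latency_threshold_s: float = 1.1
    fir_window: tuple = (17.6, 15.4)     # s before / after the pulse peak
    smooth_fwhm_surface: float = 6.0     # mm
    smooth_fwhm_volume: float = 4.7      # mm
    map_top_fraction: float = 0.30
    task_top_fraction: float = 0.01
    n_surrogates: int = 1000
    snr_denominator: str = "variance"    # or "sd"
    two_sided: bool = False              # cluster test tail
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        positive = [
            "fd_threshold", "z_pulse", "motion_r_max", "motion_window_s",
            "n_perm", "n_cluster_thresholds", "min_thresholds_passed",
            "alpha", "latency_threshold_s", "smooth_fwhm_surface",
            "smooth_fwhm_volume", "n_surrogates",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("detectability_top_fraction", "map_top_fraction",
                     "task_top_fraction", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < lo < hi")
        if self.filter_mode not in ("bandpass", "highpass_only"):
            raise ValueError("filter_mode must be bandpass or highpass_only")
        if self.snr_denominator not in ("variance", "sd"):
            raise ValueError("snr_denominator must be variance or sd")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = {}
        names = {f.name for f in fields(cls)}
        for k, v in d.items():
            if k not in names:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)
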