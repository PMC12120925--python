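"""Detection of spontaneous disuse pulses from paired left/right ROI series.

A pulse is a lateralized BOLD transient: the left-minus-right ROI
difference must exceed ``z`` times its own SD while the left series itself
also rises above ``z`` SD. Candidate events highly correlated with head
motion over an 18-s window around the peak are screened out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import BoldRun, MotionTrace

MERGE_WINDOW_S = 8.8  # one HRF width: suprathreshold frames this close merge


@dataclass
class PulseEvent:
    run_id: str
    peak_frame: int
    peak_time_s: float
    z_diff: float
    z_left: float
    motion_r: float = np.nan
    screened: bool = False
    edge: bool = False

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id, "peak_frame": self.peak_frame,
            "peak_time_s": self.peak_time_s, "z_diff": self.z_diff,
            "z_left": self.z_left, "motion_r": self.motion_r,
            "screened": self.screened, "edge": self.edge,
        }


def roi_series(runs: list[BoldRun], roi_ids: np.ndarray) -> list[np.ndarray]:
    """Per-run ROI mean series, demeaned per run and variance-normalized by
    the pooled across-run SD (so the concatenated series has unit SD)."""
    roi_ids = np.asarray(roi_ids, dtype=int)
    if roi_ids.size == 0:
        raise ValueError("empty ROI")
    series = [r.data[roi_ids].mean(axis=0) for r in runs]
    series = [s - s.mean() for s in series]
    concat = np.concatenate(series)
    sd = concat.std(ddof=0)
    if sd == 0:
        raise ValueError("ROI series has zero variance")
    return [s / sd for s in series]


def detect_pulses(
    left: np.ndarray,
    right: np.ndarray,
    z: float = 2.3,
    tr_seconds: float = 1.1,
    run_id: str = "",
    sd_diff: float | None = None,
    sd_left: float | None = None,
    left_criterion: str = "left_sd",
    merge_window_s: float = MERGE_WINDOW_S,
) -> list[PulseEvent]:
    """Threshold the lateralized difference at ``z`` SD.

    ``sd_diff`` / ``sd_left`` allow SDs pooled over all runs of a study
    (the across-run normalization); when omitted they are computed from the
    given series. ``left_criterion`` selects whether the left-increase
    criterion uses the SD of the left series (default) or of the difference.
    Contiguous suprathreshold frames within one HRF width merge into a
    single event at the frame of maximal difference.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right series must have equal length")
    T = left.size
    if T < 10:
        raise ValueError("series shorter than 10 frames")
    # thresholds are deviations from the series mean: detection is
    # invariant to a common offset of both series
    left = left - left.mean()
    right = right - right.mean()
    diff = left - right
    sd_d = float(np.std(diff, ddof=0)) if sd_diff is None else float(sd_diff)
    if left_criterion == "left_sd":
        sd_l = float(np.std(left, ddof=0)) if sd_left is None else float(sd_left)
    elif left_criterion == "diff_sd":
        sd_l = sd_d
    else:
        raise ValueError("left_criterion must be 'left_sd' or 'diff_sd'")
    if sd_d == 0:
        return []
    cand = (diff > z * sd_d) & (left > z * sd_l)
    frames = np.flatnonzero(cand)
    if frames.size == 0:
        return []
    merge_frames = max(1, int(round(merge_window_s / tr_seconds)))
    groups: list[list[int]] = [[int(frames[0])]]
    for f in frames[1:]:
        if f - groups[-1][-1] <= merge_frames:
            groups[-1].append(int(f))
        else:
            groups.append([int(f)])
    events = []
    edge_frames = int(round(17.6 / tr_seconds))
    for g in groups:
        g = np.asarray(g)
        peak = int(g[np.argmax(diff[g])])
        events.append(PulseEvent(
            run_id=run_id,
            peak_frame=peak,
            peak_time_s=peak * tr_seconds,
            z_diff=float(diff[peak] / sd_d),
            z_left=float(left[peak] / sd_l) if sd_l > 0 else np.inf,
            edge=bool(peak < edge_frames
                      or peak > T - int(round(15.4 / tr_seconds)) - 1),
        ))
    return events


def motion_screen(
    events: list[PulseEvent],
    motion: MotionTrace,
    left_series: np.ndarray,
    tr_seconds: float,
    r_max: float = 0.8,
    window_s: float = 18.0,
) -> list[PulseEvent]:
    """Flag events whose left-ROI series correlates > ``r_max`` (absolute)
    with any rigid-body motion parameter over a window centered on the
    peak. Windows are truncated at run edges; a constant motion trace in
    the window gives r = 0 (event retained). Returns the same events with
    ``motion_r`` and ``screened`` set."""
    left_series = np.asarray(left_series, dtype=float)
    half = max(1, int(round(window_s / 2.0 / tr_seconds)))
    T = left_series.size
    for ev in events:
        lo = max(0, ev.peak_frame - half)
        hi = min(T, ev.peak_frame + half + 1)
        seg = left_series[lo:hi]
        best = 0.0
        if np.std(seg) > 0:
            for j in range(motion.params6.shape[1]):
                m = motion.params6[lo:hi, j]
                if np.std(m) == 0:
                    continue
                r = np.corrcoef(seg, m)[0, 1]
                best = max(best, abs(float(r)))
        ev.motion_r = best
        ev.screened = best > r_max
    return events


def retained(events: list[PulseEvent]) -> list[PulseEvent]:
    return [e for e in events if not e.screened]


@dataclass
class PulseDetectionResult:
    """All events across runs, with pooled-SD diagnostics."""

    events: list[PulseEvent]
    sd_diff: float
    sd_left: float
    series_left: dict = field(default_factory=dict)
    series_right: dict = field(default_factory=dict)

    @property
    def retained(self) -> list[PulseEvent]:
        return [e for e in self.events if not e.screened]


def detect_study(
    runs: list[BoldRun],
    left_roi: np.ndarray,
    right_roi: np.ndarray,
    z: float = 2.3,
    r_max: float = 0.8,
    window_s: float = 18.0,
    left_criterion: str = "left_sd",
) -> PulseDetectionResult:
    """Across-run detection: ROI series variance-normalized across runs,
    thresholds computed from the pooled concatenated series, detection and
    motion screening applied per run."""
    lefts = roi_series(runs, left_roi)
    rights = roi_series(runs, right_roi)
    all_left = np.concatenate(lefts)
    all_diff = np.concatenate([l - r for l, r in zip(lefts, rights)])
    sd_left = float(np.std(all_left, ddof=0))
    sd_diff = float(np.std(all_diff, ddof=0))
    events: list[PulseEvent] = []
    series_l, series_r = {}, {}
    for run, l, r in zip(runs, lefts, rights):
        evs = detect_pulses(
            l, r, z=z, tr_seconds=run.tr_seconds, run_id=run.session_id,
            sd_diff=sd_diff, sd_left=sd_left, left_criterion=left_criterion,
        )
        motion_screen(evs, run.motion, l, run.tr_seconds,
                      r_max=r_max, window_s=window_s)
        events.extend(evs)
        series_l[run.session_id] = l
        series_r[run.session_id] = r
    return PulseDetectionResult(events=events, sd_diff=sd_diff,
                                sd_left=sd_left, series_left=series_l,
                                series_right=series_r)
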