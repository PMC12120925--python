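"""Recovery dynamics: motor-circuit ROI selection and the two-rate
exponential model of FC change across sessions.

The model (the package's definition of the two-alpha exponential):

    FC(t) = baseline                                            t < t_cast
    FC(t) = baseline + A (1 - exp(-a1 (t - t_cast)))            cast
    FC(t) = baseline + A_end exp(-a2 (t - t_off))               post-cast

with A_end = A (1 - exp(-a1 (t_off - t_cast))), so the curve is continuous
at the cast-off boundary. a1 (1/day) is the rate of FC change during
casting, a2 the recovery rate after cast removal; sessions are daily and
time is measured in days from cast onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._utils import child_seed
from .fc_change import ClusterResult
from .pulse_model import top_fraction_mask
from .space import GrayordinateSpace
from .task_glm import TStatMap


@dataclass
class DynamicsROI:
    """Voxels of one structure showing both a significant FC-change
    cluster and top-percentile motor-task activation."""

    structure: str
    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def select_roi(
    clusters: ClusterResult,
    task_t: TStatMap,
    space: GrayordinateSpace,
    structure: str,
    task_top: float = 0.01,
) -> DynamicsROI:
    """Intersection of significant-cluster voxels (>= 2 of the cluster
    thresholds) with the structure's top ``task_top`` task t-values."""
    idx = space.indices(structure)
    in_cluster = np.zeros(space.n, dtype=bool)
    for c in clusters.clusters:
        if c.structure == structure:
            in_cluster[c.members] = True
    t_struct = np.asarray(task_t.t, dtype=float)[idx]
    top_local = top_fraction_mask(t_struct, task_top)
    top = np.zeros(space.n, dtype=bool)
    top[idx[top_local]] = True
    sel = np.flatnonzero(in_cluster & top)
    if sel.size == 0:
        raise ValueError(f"no dynamics ROI in {structure!r}: "
                         "cluster and task selections do not overlap")
    return DynamicsROI(structure=structure, indices=sel)


@dataclass
class DecayFit:
    """Two-rate exponential fit of a per-session FC time course."""

    a1_rate: float
    a2_rate: float
    amplitude: float
    baseline: float
    rss: float
    fitted: np.ndarray
    days: np.ndarray
    t_cast: float
    t_off: float
    identifiable: bool = True

    def predict(self, days: np.ndarray) -> np.ndarray:
        return _curve(np.asarray(days, dtype=float), self.t_cast, self.t_off,
                      self.baseline, self.amplitude, self.a1_rate, self.a2_rate)

    def summary(self) -> dict:
        return {
            "a1_rate_per_day": self.a1_rate,
            "a2_rate_per_day": self.a2_rate,
            "amplitude": self.amplitude,
            "baseline": self.baseline,
            "rss": self.rss,
            "identifiable": self.identifiable,
        }


def _curve(t, t_cast, t_off, baseline, amp, a1, a2):
    out = np.full(t.shape, baseline, dtype=float)
    cast = (t >= t_cast) & (t <= t_off)
    post = t > t_off
    out[cast] = baseline + amp * (1.0 - np.exp(-a1 * (t[cast] - t_cast)))
    a_end = amp * (1.0 - np.exp(-a1 * (t_off - t_cast)))
    out[post] = baseline + a_end * np.exp(-a2 * (t[post] - t_off))
    return out


def fit_decay(
    days: np.ndarray,
    values: np.ndarray,
    phases: np.ndarray,
    t_cast: float | None = None,
    t_off: float | None = None,
    seed: int = 0,
    min_sessions_per_phase: int = 3,
) -> DecayFit:
    """Least-squares fit of the two-rate model to per-session FC values.

    Multi-start optimization over a grid of rate initializations (plus a
    flat start, so the fitted RSS never exceeds the baseline-only model's).
    A fit whose amplitude is negligible against the residual scale is
    flagged unidentifiable (the rates are then meaningless).
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    phases = np.asarray(phases)
    for ph in np.unique(phases):
        if np.sum(phases == ph) < min_sessions_per_phase:
            raise ValueError(f"need >= {min_sessions_per_phase} sessions in "
                             f"phase {ph!r}")
    if t_cast is None:
        cast_days = days[phases == "cast"]
        t_cast = float(cast_days.min()) - 0.5 if cast_days.size else 0.0
    if t_off is None:
        cast_days = days[phases == "cast"]
        t_off = float(cast_days.max()) + 0.5 if cast_days.size else t_cast

    def resid(p):
        baseline, amp, a1, a2 = p
        return _curve(days, t_cast, t_off, baseline, amp, a1, a2) - values

    v0 = float(np.mean(values[phases == "pre"])) if np.any(phases == "pre") \
        else float(values.mean())
    amp0 = float(np.mean(values[phases == "cast"]) - v0) if np.any(phases == "cast") else 0.0
    rng = np.random.default_rng(child_seed(seed, "decay-fit"))
    starts = [(v0, 0.0, 0.5, 0.5), (v0, amp0, 0.5, 0.5)]
    for a1 in (0.1, 0.5, 2.0):
        for a2 in (0.1, 0.5, 2.0):
            starts.append((v0, amp0 if amp0 else 0.1, a1, a2))
    for _ in range(4):
        starts.append((
            v0 + rng.normal(0, 0.05),
            (amp0 or 0.1) * rng.uniform(0.5, 1.5),
            rng.uniform(0.05, 3.0),
            rng.uniform(0.05, 3.0),
        ))
    lo = [-np.inf, -np.inf, 0.0, 0.0]
    hi = [np.inf, np.inf, 20.0, 20.0]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf"
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("decay fit failed to converge from all starts")
    baseline, amp, a1, a2 = best.x
    fitted = _curve(days, t_cast, t_off, baseline, amp, a1, a2)
    rss = float(np.sum((fitted - values) ** 2))
    scale = float(np.std(values - fitted, ddof=0))
    identifiable = abs(amp) > max(3.0 * scale / np.sqrt(len(values)), 1e-12)
    return DecayFit(
        a1_rate=float(a1), a2_rate=float(a2), amplitude=float(amp),
        baseline=float(baseline), rss=rss, fitted=fitted, days=days,
        t_cast=t_cast, t_off=t_off, identifiable=identifiable,
    )
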