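"""Seed-based functional connectivity and cast-vs-pre effect-size mapping.

Per-session seed FC maps are compared between experimental phases with
Cohen's d at each grayordinate; significance is assessed within individual
by randomizing session-phase labels and applying a multi-threshold,
per-structure cluster-size correction (clusters must pass the size
criterion at p < alpha for at least ``min_pass`` of the decile thresholds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from ._utils import rng_for
from .datamodel import BoldRun
from .space import GrayordinateSpace


@dataclass
class FCMap:
    """Seed FC of one session: Pearson r with the seed per grayordinate."""

    r: np.ndarray
    session_id: str
    phase: str
    day_index: float = 0.0


@dataclass
class EffectSizeMap:
    """Cohen's d of phase A vs phase B session FC per grayordinate; NaN
    where undefined (zero pooled spread or too few sessions)."""

    d: np.ndarray
    phase_a: str
    phase_b: str
    n_a: int
    n_b: int


@dataclass
class Cluster:
    structure: str
    members: np.ndarray
    size: int
    peak_index: int
    peak_coord_mm: np.ndarray
    peak_d: float
    n_thresholds_passed: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "size_nvox": int(self.size),
            "peak_xyz_mm": [float(v) for v in self.peak_coord_mm],
            "peak_d": float(self.peak_d),
            "n_thresholds_passed": int(self.n_thresholds_passed),
            "p_value": float(self.p_value),
        }


@dataclass
class ClusterResult:
    """Significant clusters (>= min_pass thresholds) plus diagnostics."""

    clusters: list
    d_map: np.ndarray
    thresholds: np.ndarray
    n_perm: int
    alpha: float
    min_pass: int
    pass_count: np.ndarray = field(default=None)

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    def by_structure(self) -> dict:
        out: dict[str, list] = {}
        for c in self.clusters:
            out.setdefault(c.structure, []).append(c)
        return out


def seed_fc_map(run: BoldRun, seed_ids: np.ndarray) -> FCMap:
    """Average of the whole-brain correlation maps of each seed voxel.

    A seed voxel's own (unit) self-correlation is excluded from its own
    seed average; zero-variance seed voxels are excluded with a warning.
    """
    seed_ids = np.asarray(seed_ids, dtype=int)
    if seed_ids.size < 1:
        raise ValueError("seed must contain at least one voxel")
    if run.T < 10:
        raise ValueError("need at least 10 retained frames")
    X = run.data - run.data.mean(axis=1, keepdims=True)
    norms = np.sqrt((X**2).sum(axis=1))
    seed_norms = norms[seed_ids]
    good = seed_norms > 0
    if not good.all():
        warnings.warn(f"{(~good).sum()} zero-variance seed voxels excluded")
    seed_ids = seed_ids[good]
    if seed_ids.size == 0:
        raise ValueError("all seed voxels have zero variance")
    m = seed_ids.size
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = X / norms[:, None]
    Z[norms == 0] = 0.0
    C = Z @ Z[seed_ids].T            # (n, m) correlation with each seed voxel
    total = C.sum(axis=1)
    r = total / m
    if m > 1:
        # remove self-correlation from seed voxels' own averages
        self_corr = C[seed_ids, np.arange(m)]
        r[seed_ids] = (total[seed_ids] - self_corr) / (m - 1)
    else:
        pass  # single-voxel seed: definition collapses to its own corr map
    return FCMap(r=r, session_id=run.session_id, phase=run.phase,
                 day_index=run.day_index)


def _cohens_d(R: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Vectorized per-column Cohen's d with classical pooled SD."""
    A, B = R[mask_a], R[mask_b]
    na, nb = len(A), len(B)
    var_a = A.var(axis=0, ddof=1)
    var_b = B.var(axis=0, ddof=1)
    pooled = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (A.mean(axis=0) - B.mean(axis=0)) / pooled
    d[pooled == 0] = np.nan
    return d


def phase_effect_size(
    fc_by_session: list[FCMap], phase_a: str = "cast", phase_b: str = "pre"
) -> EffectSizeMap:
    """Cohen's d = (mean_A - mean_B) / pooled SD per grayordinate."""
    R = np.stack([m.r for m in fc_by_session])
    phases = np.array([m.phase for m in fc_by_session])
    mask_a, mask_b = phases == phase_a, phases == phase_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need >= 2 sessions in each phase")
    d = _cohens_d(R, mask_a, mask_b)
    return EffectSizeMap(d=d, phase_a=phase_a, phase_b=phase_b,
                         n_a=int(mask_a.sum()), n_b=int(mask_b.sum()))


def _components(sub_adj, mask_local: np.ndarray) -> list[np.ndarray]:
    """Connected components of a boolean mask within one structure's
    adjacency; returns lists of local indices."""
    idx = np.flatnonzero(mask_local)
    if idx.size == 0:
        return []
    if idx.size == 1:
        return [idx]
    A = sub_adj[np.ix_(idx, idx)]
    ncomp, lab = connected_components(A, directed=False)
    return [idx[lab == k] for k in range(ncomp)]


def _neighbor_lists(sub_adj) -> list[np.ndarray]:
    A = sub_adj.tocsr()
    return [A.indices[A.indptr[i]:A.indptr[i + 1]] for i in range(A.shape[0])]


def _find(parent, i):
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


def _max_sizes_at_thresholds(
    values: np.ndarray, thresholds: np.ndarray, neighbors: list[np.ndarray]
) -> np.ndarray:
    """Max connected suprathreshold component size at each threshold.

    Incremental union-find: voxels are activated in decreasing value
    order, so all thresholds are answered in one pass. ``thresholds`` in
    any order; activation uses strict ``value > threshold``.
    """
    n = values.size
    order = np.argsort(-values, kind="stable")
    desc = np.argsort(-thresholds, kind="stable")
    out = np.zeros(thresholds.size, dtype=int)
    parent = np.arange(n)
    size = np.ones(n, dtype=int)
    active = np.zeros(n, dtype=bool)
    best = 0
    ptr = 0
    for k in desc:
        thr = thresholds[k]
        while ptr < n and values[order[ptr]] > thr:
            i = order[ptr]
            ptr += 1
            active[i] = True
            ri = _find(parent, i)
            for j in neighbors[i]:
                if active[j]:
                    rj = _find(parent, j)
                    if rj != ri:
                        if size[ri] < size[rj]:
                            ri, rj = rj, ri
                        parent[rj] = ri
                        size[ri] += size[rj]
            if size[ri] > best:
                best = size[ri]
        out[k] = best
    return out


def permutation_cluster_correct(
    fc_by_session: list[FCMap],
    space: GrayordinateSpace,
    phase_a: str = "cast",
    phase_b: str = "pre",
    n_perm: int = 1000,
    n_thresholds: int = 10,
    min_pass: int = 2,
    alpha: float = 0.05,
    seed: int = 0,
    two_sided: bool = False,
    family_control: bool = True,
) -> ClusterResult:
    """Session-label permutation test with multi-threshold cluster-size
    correction, estimated independently per anatomical structure.

    Thresholds are the ``n_thresholds`` upper deciles of the observed
    suprazero d distribution (every 10% of the value distribution). A
    cluster is retained when its size exceeds the per-(structure,
    threshold) permutation null-quantile critical size at >= ``min_pass``
    thresholds. With ``family_control`` (default) the per-cell quantile
    level is jointly calibrated on the permutation ensemble
    (Westfall-Young style) so that ``alpha`` is the *family-wise* rate of
    reporting any cluster anywhere; with ``family_control=False`` each
    (structure, threshold) cell uses the (1 - alpha) quantile directly,
    which controls each cell at alpha but not the whole family. Default is
    one-sided (phase-A > phase-B increases); ``two_sided`` thresholds |d|
    instead.
    """
    if n_perm == 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100: null poorly resolved")
    R = np.stack([m.r for m in fc_by_session])
    phases = np.array([m.phase for m in fc_by_session])
    mask_a, mask_b = phases == phase_a, phases == phase_b
    used = mask_a | mask_b
    if used.sum() < 4:
        raise ValueError("need >= 4 sessions in total")
    R, phases = R[used], phases[used]
    mask_a, mask_b = phases == phase_a, phases == phase_b

    d_obs = _cohens_d(R, mask_a, mask_b)
    v_obs = np.abs(d_obs) if two_sided else d_obs
    pos = v_obs[np.isfinite(v_obs) & (v_obs > 0)]
    percentiles = np.arange(1, n_thresholds + 1) * (100.0 / n_thresholds)
    if pos.size == 0:
        return ClusterResult([], d_obs, np.array([]), n_perm, alpha, min_pass,
                             np.zeros(len(d_obs), dtype=int))
    thresholds = np.percentile(pos, percentiles)

    structures = space.structures
    subs = {s: space.sub_adjacency(s) for s in structures}
    nbrs = {s: _neighbor_lists(subs[s][1]) for s in structures}

    # null max-cluster-size per (structure, threshold) over permutations
    rng = rng_for(seed, "cluster-perm")
    null_max = np.empty((len(structures), n_thresholds, n_perm))
    labels = mask_a.copy()
    for p in range(n_perm):
        pa = labels[rng.permutation(len(labels))]
        d_p = _cohens_d(R, pa, ~pa)
        v_p = np.abs(d_p) if two_sided else d_p
        v_p = np.nan_to_num(v_p, nan=-np.inf)
        # each permutation map is thresholded at its *own* deciles — the
        # same adaptive rule applied to the observed map — so observed and
        # null cluster sizes at decile k are exchangeable
        pos_p = v_p[np.isfinite(v_p) & (v_p > 0)]
        thr_p = np.percentile(pos_p, percentiles) if pos_p.size else \
            np.full(n_thresholds, np.inf)
        for si, s in enumerate(structures):
            idx, _ = subs[s]
            null_max[si, :, p] = _max_sizes_at_thresholds(
                v_p[idx], thr_p, nbrs[s]
            )

    # cluster sizes are made comparable across (structure, threshold)
    # cells by studentizing against the cell's permutation null
    mu = null_max.mean(axis=2)
    sd = np.maximum(null_max.std(axis=2, ddof=1), 1.0)

    def studentize(sizes_sk: np.ndarray) -> np.ndarray:
        return (sizes_sk - mu) / sd

    if family_control:
        # omnibus max-statistic calibration: a map's family statistic is
        # the largest, over structures, of the min_pass-th largest
        # studentized cell size across thresholds. A cell criterion of
        # "studentized size > t*", with t* the (1 - alpha) rank of the
        # permutation family statistics, makes alpha the family-wise rate
        # of reporting any cluster anywhere (exact by exchangeability).
        T_perm = np.empty(n_perm)
        for p in range(n_perm):
            z = studentize(null_max[:, :, p])
            T_perm[p] = np.sort(z, axis=1)[:, -min_pass].max()
        order = np.sort(T_perm)
        m = int(np.ceil((1.0 - alpha) * (n_perm + 1))) - 1
        t_star = order[min(m, n_perm - 1)]
    else:
        # per-cell (1 - alpha) criterion, no family control
        t_star = None
        crit_cell = np.quantile(null_max, 1.0 - alpha, axis=2)

    v_clean = np.nan_to_num(v_obs, nan=-np.inf)
    pass_count = np.zeros(len(d_obs), dtype=int)
    for si, s in enumerate(structures):
        idx, A = subs[s]
        vs = v_clean[idx]
        for k, thr in enumerate(thresholds):
            for comp in _components(A, vs > thr):
                if family_control:
                    ok = (len(comp) - mu[si, k]) / sd[si, k] > t_star
                else:
                    ok = len(comp) > crit_cell[si, k]
                if ok:
                    pass_count[idx[comp]] += 1

    clusters = []
    for si, s in enumerate(structures):
        idx, A = subs[s]
        for comp in _components(A, pass_count[idx] >= min_pass):
            members = idx[comp]
            dv = np.nan_to_num(np.abs(d_obs[members]), nan=-np.inf)
            best = members[np.lexsort((members, -dv))[0]]
            size = len(members)
            pvals = (1.0 + (null_max[si] >= size).sum(axis=1)) / (n_perm + 1.0)
            clusters.append(Cluster(
                structure=s, members=members, size=size,
                peak_index=int(best),
                peak_coord_mm=space.coords[best].copy(),
                peak_d=float(d_obs[best]),
                n_thresholds_passed=int(pass_count[members].max()),
                p_value=float(pvals.min()),
            ))
    clusters.sort(key=lambda c: -c.size)
    return ClusterResult(clusters, d_obs, thresholds, n_perm, alpha, min_pass,
                         pass_count)
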