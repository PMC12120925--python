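"""Spatially constrained null testing and anatomical quantification.

Map-similarity statements (e.g. "does the FC-change map correlate with the
motor-task map in the thalamus?") cannot be tested against naive
permutation nulls because fMRI maps are spatially autocorrelated. Moran
spectral randomization builds surrogate maps that preserve a map's spatial
autocorrelation spectrum on the structure's adjacency graph; observed map
correlations are then compared with the surrogate distribution. Null
distributions are constructed per anatomical structure, and tests across
families are FDR-corrected (Benjamini-Hochberg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from ._utils import rng_for
from .space import GrayordinateSpace


# ---------------------------------------------------------------------------
# Moran spectral randomization

def moran_weights(space: GrayordinateSpace, structure: str):
    """(indices, row-normalized binary adjacency restricted to the
    structure)."""
    idx, A = space.sub_adjacency(structure)
    A = A.astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-12), 0.0)
    W = A.multiply(inv[:, None]).tocsr()
    return idx, W


def morans_i(x: np.ndarray, W) -> float:
    """Moran's I of a map on a weight matrix (asymmetric weights allowed)."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    s0 = float(W.sum())
    if denom == 0 or s0 == 0:
        return 0.0
    return float(len(x) / s0 * (xc @ (W @ xc)) / denom)


@dataclass
class SurrogateEnsemble:
    """Autocorrelation-preserving surrogate maps for one structure."""

    maps: np.ndarray            # (n_surrogates, n_structure_voxels)
    indices: np.ndarray         # grayordinate indices of the structure
    structure: str
    original: np.ndarray
    i_original: float
    i_surrogates: np.ndarray

    @property
    def n(self) -> int:
        return self.maps.shape[0]


def moran_surrogates(
    values: np.ndarray,
    space: GrayordinateSpace,
    structure: str,
    n: int = 1000,
    seed: int = 0,
    preserve_values: bool = False,
) -> SurrogateEnsemble:
    """Moran spectral randomization on one structure.

    The doubly-centered symmetrized weight matrix is eigendecomposed
    (Moran eigenvector maps); the map's coordinates in that basis have
    their signs randomized (the singular procedure), which preserves the
    map's variance and its Moran's I exactly while scrambling the spatial
    arrangement. With ``preserve_values`` each surrogate is additionally
    rank-remapped onto the original value multiset (the autocorrelation is
    then preserved only approximately).
    """
    idx, W = moran_weights(space, structure)
    if idx.size < 10:
        raise ValueError(f"structure {structure!r} has fewer than 10 grayordinates")
    x = np.asarray(values, dtype=float)[idx]
    rng = rng_for(seed, f"moran:{structure}")
    i_obs = morans_i(x, W)
    if np.ptp(x) == 0:
        maps = np.tile(x, (n, 1))
        return SurrogateEnsemble(maps, idx, structure, x, i_obs,
                                 np.full(n, i_obs))
    m = idx.size
    Ws = 0.5 * (W + W.T).toarray()
    ncomp, _ = connected_components(W, directed=False)
    if ncomp > 1:
        warnings.warn(
            f"structure {structure!r} subgraph has {ncomp} components; "
            "spectral basis spans all of them"
        )
    H = np.eye(m) - 1.0 / m
    M = H @ Ws @ H
    _, V = np.linalg.eigh(M)
    xc = x - x.mean()
    a = V.T @ xc
    signs = rng.choice([-1.0, 1.0], size=(n, m))
    maps = (signs * a) @ V.T + x.mean()
    if preserve_values:
        order = np.argsort(maps, axis=1)
        ranked = np.sort(x)
        out = np.empty_like(maps)
        rows = np.arange(n)[:, None]
        out[rows, order] = ranked[None, :]
        maps = out
    i_sur = np.array([morans_i(s, W) for s in maps])
    return SurrogateEnsemble(maps, idx, structure, x, i_obs, i_sur)


def map_similarity_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    ensemble: SurrogateEnsemble,
    tail: str = "upper",
) -> tuple[float, float]:
    """Pearson correlation of two maps within a structure, tested against
    the surrogate ensemble built on ``map_a``.

    p = (1 + #{surrogate r at least as extreme}) / (n + 1).
    """
    idx = ensemble.indices
    a = np.asarray(map_a, dtype=float)[idx]
    b = np.asarray(map_b, dtype=float)[idx]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance map in similarity test")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    S = ensemble.maps - ensemble.maps.mean(axis=1, keepdims=True)
    bn = b - b.mean()
    denom = np.linalg.norm(S, axis=1) * np.linalg.norm(bn)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_sur = np.where(denom > 0, (S @ bn) / denom, 0.0)
    if tail == "upper":
        k = int(np.sum(r_sur >= r_obs))
    elif tail == "lower":
        k = int(np.sum(r_sur <= r_obs))
    elif tail == "two":
        k = int(np.sum(np.abs(r_sur) >= abs(r_obs)))
    else:
        raise ValueError("tail must be 'upper', 'lower' or 'two'")
    p = (1.0 + k) / (ensemble.n + 1.0)
    return r_obs, float(p)


def fdr_correct(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# atlas-nucleus quantification

@dataclass
class NucleusTable:
    """Per-atlas-label statistics of a t-map (e.g. thalamic nuclei)."""

    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def nucleus_means(
    tmap: np.ndarray,
    labels: np.ndarray,
    ensemble: SurrogateEnsemble | None = None,
    top_fraction: float | None = None,
) -> NucleusTable:
    """Mean t-statistic and voxel count per atlas label, with optional
    surrogate-based one-sided p-values and BH q-values.

    ``labels`` is a per-grayordinate label array; entries equal to 0 / ""
    are unlabeled and excluded. ``top_fraction`` restricts the map to its
    top values before averaging (display convention)."""
    tmap = np.asarray(tmap, dtype=float)
    labels = np.asarray(labels)
    mask = ~pd.isna(labels)
    if labels.dtype.kind in "iuf":
        mask &= labels != 0
    else:
        mask &= (labels != "") & (labels != "0")
    values = tmap.copy()
    if top_fraction is not None:
        k = int(round(top_fraction * np.sum(mask)))
        thr_vals = np.sort(values[mask])[::-1]
        cut = thr_vals[max(k - 1, 0)] if k > 0 else np.inf
        values = np.where(values >= cut, values, np.nan)
    rows = []
    uniq = [u for u in pd.unique(labels[mask])]
    for lab in uniq:
        sel = mask & (labels == lab)
        vals = values[sel]
        mean_t = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
        row = {"label": lab, "mean_t": mean_t, "n_vox": int(sel.sum())}
        if ensemble is not None:
            local = np.flatnonzero(np.isin(ensemble.indices, np.flatnonzero(sel)))
            if local.size == 0:
                warnings.warn(f"label {lab!r} absent from ensemble structure")
                row["p"] = np.nan
            else:
                sur_means = ensemble.maps[:, local].mean(axis=1)
                obs = float(np.mean(tmap[ensemble.indices[local]]))
                row["p"] = (1.0 + np.sum(sur_means >= obs)) / (ensemble.n + 1.0)
        rows.append(row)
    df = pd.DataFrame(rows)
    if ensemble is not None and len(df):
        ok = np.isfinite(df["p"].to_numpy(dtype=float))
        q = np.full(len(df), np.nan)
        if ok.any():
            q[ok] = fdr_correct(df.loc[ok, "p"].to_numpy())
        df["q"] = q
    return NucleusTable(table=df)


# ---------------------------------------------------------------------------
# geometric VIM localization

@dataclass
class VIMBox:
    """Indirect (landmark-based) ventral-intermediate-nucleus box."""

    voxels_mm: np.ndarray       # (m, 3), both hemispheres
    bounds: dict                # per-hemisphere {x: (lo, hi), y: ..., z: ...}
    landmarks: dict


def vim_box(
    pc_mm: tuple,
    ventricle_length_mm: float,
    third_ventricle_center_x_mm: float,
    third_ventricle_border_x_mm: float,
    resolution_mm: float = 3.0,
) -> VIMBox:
    """Guiot-style VIM localization from AC-PC landmarks.

    The anterior-posterior anchor sits a quarter of the third-ventricle
    length anterior to the PC point. The lateral band runs, per
    hemisphere, from 11 mm lateral of the ventricle border to 14 mm
    lateral of the ventricle center (both published criteria honored as
    the medial/lateral bounds). The box extends 3 mm superior and 2 mm
    anterior from the anchor. Voxels are returned at the stated grid
    resolution (a voxel is included when its cell overlaps the box).
    """
    pc = np.asarray(pc_mm, dtype=float)
    if ventricle_length_mm <= 0:
        raise ValueError("ventricle length must be positive")
    center, border = float(third_ventricle_center_x_mm), float(third_ventricle_border_x_mm)
    half_w = border - center
    if half_w < 0:
        raise ValueError("inconsistent landmarks: border medial to center")
    y0 = pc[1] + 0.25 * ventricle_length_mm
    x_lo = border + 11.0          # medial bound (distance from border)
    x_hi = center + 14.0          # lateral bound (distance from center)
    if x_lo > x_hi:
        raise ValueError(
            "inconsistent landmarks: lateral criteria give an empty band"
        )
    h = float(resolution_mm)

    def grid_cells(lo, hi, anchor):
        k_lo = int(np.floor((lo - anchor) / h - 0.5))
        k_hi = int(np.ceil((hi - anchor) / h + 0.5))
        ks = np.arange(k_lo, k_hi + 1)
        centers = anchor + ks * h
        keep = (centers + h / 2.0 > lo) & (centers - h / 2.0 < hi)
        return centers[keep]

    bounds = {}
    voxels = []
    for hemi, sign in (("right", 1.0), ("left", -1.0)):
        xs = grid_cells(x_lo, x_hi, center)
        ys = grid_cells(y0, y0 + 2.0, pc[1])
        zs = grid_cells(pc[2], pc[2] + 3.0, pc[2])
        bounds[hemi] = {
            "x": (sign * x_lo, sign * x_hi) if sign > 0 else (-x_hi, -x_lo),
            "y": (y0, y0 + 2.0),
            "z": (pc[2], pc[2] + 3.0),
        }
        for x in sign * xs:
            for y in ys:
                for z in zs:
                    voxels.append((x, y, z))
    return VIMBox(
        voxels_mm=np.array(sorted(voxels)),
        bounds=bounds,
        landmarks={
            "pc_mm": pc.tolist(),
            "ventricle_length_mm": float(ventricle_length_mm),
            "third_ventricle_center_x_mm": center,
            "third_ventricle_border_x_mm": border,
        },
    )
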