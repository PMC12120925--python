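"""Block-design motor-task GLM with onset/offset transient regressors.

Each movement condition contributes a boxcar and an onset impulse, blocks
share (by default) an offset impulse, all convolved with the canonical
double-gamma HRF; polynomial drift terms complete the design. Run-level
fits use AR(1) pre-whitened least squares; the second level combines runs
within participant by fixed effects (inverse-variance weighting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import BoldRun
from .hrf import double_gamma


@dataclass
class TaskDesign:
    matrix: np.ndarray            # (T, p)
    columns: list[str]
    conditions: list[str]
    tr_seconds: float

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def contrast_vector(self, spec) -> np.ndarray:
        """Build a contrast vector from a dict {column_name: weight} or
        pass a full-length vector through."""
        if isinstance(spec, dict):
            c = np.zeros(self.p)
            for name, w in spec.items():
                if name not in self.columns:
                    raise KeyError(f"no design column {name!r}")
                c[self.columns.index(name)] = w
        else:
            c = np.asarray(spec, dtype=float)
            if c.shape != (self.p,):
                raise ValueError(f"contrast length {c.shape} != p={self.p}")
        if not np.any(c != 0):
            raise ValueError("contrast vector is all zeros")
        return c


@dataclass
class TStatMap:
    """t-statistic per grayordinate for one named contrast."""

    t: np.ndarray
    df: float
    level: str                    # "run" or "second"
    contrast_name: str = ""
    beta: np.ndarray | None = None
    beta_var: np.ndarray | None = None


def build_design(
    schedule: list[tuple[str, float, float]],
    tr: float,
    T: int,
    drift_order: int = 2,
    offset_per_condition: bool = False,
) -> TaskDesign:
    """Deterministic design matrix: per-condition boxcar (x)HRF +
    per-condition onset impulse (x)HRF + (shared or per-condition) offset
    impulse (x)HRF + polynomial drift. ``schedule`` rows are
    (condition, onset_s, duration_s)."""
    t_grid = np.arange(T) * tr
    run_len = T * tr
    by_cond: dict[str, list] = {}
    for cond, onset, dur in schedule:
        if onset + dur > run_len:
            raise ValueError(
                f"block ({cond!r}, {onset}, {dur}) extends beyond run end"
            )
        by_cond.setdefault(str(cond), []).append((float(onset), float(dur)))
    hrf = double_gamma(np.arange(0.0, 32.0, tr))
    cols, names = [], []

    def conv(series):
        return np.convolve(series, hrf)[:T]

    offsets_all = np.zeros(T)
    for cond in sorted(by_cond):
        box = np.zeros(T)
        onsets = np.zeros(T)
        offs = np.zeros(T)
        for o, d in sorted(by_cond[cond]):
            box[(t_grid >= o) & (t_grid < o + d)] = 1.0
            onsets[int(round(o / tr))] = 1.0
            f_off = int(round((o + d) / tr))
            if f_off < T:
                offs[f_off] = 1.0
        cols += [conv(box), conv(onsets)]
        names += [f"{cond}:block", f"{cond}:onset"]
        if offset_per_condition:
            cols.append(conv(offs))
            names.append(f"{cond}:offset")
        else:
            offsets_all += offs
    if not offset_per_condition and offsets_all.any():
        cols.append(conv(offsets_all))
        names.append("offset")
    x = np.linspace(-1.0, 1.0, T)
    for k in range(drift_order + 1):
        cols.append(x**k)
        names.append(f"drift{k}")
    X = np.column_stack(cols)
    return TaskDesign(matrix=X, columns=names,
                      conditions=sorted(by_cond), tr_seconds=tr)


def fit_glm(run: BoldRun, design: TaskDesign, contrast,
            contrast_name: str = "") -> TStatMap:
    """AR(1)-pre-whitened ordinary least squares; t = c'beta / SE."""
    X = design.matrix
    if X.shape[0] != run.T:
        raise ValueError("design rows must equal retained T")
    c = design.contrast_vector(contrast)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.T)
        bad = [design.columns[i] for i in range(X.shape[1])
               for j in range(i)
               if abs(corr[i, j]) > 0.999]
        raise ValueError(f"singular design; collinear columns: {bad}")
    Y = run.data.T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    num = float((resid[1:] * resid[:-1]).sum())
    den = float((resid**2).sum())
    rho = np.clip(num / den if den > 0 else 0.0, -0.95, 0.95)
    Xw = X.copy()
    Yw = Y.copy()
    Xw[1:] = X[1:] - rho * X[:-1]
    Yw[1:] = Y[1:] - rho * Y[:-1]
    s = np.sqrt(max(1.0 - rho**2, 1e-12))
    Xw[0] *= s
    Yw[0] *= s
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    beta = XtX_inv @ Xw.T @ Yw
    resid = Yw - Xw @ beta
    df = run.T - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    cvar = float(c @ XtX_inv @ c)
    cbeta = c @ beta
    var = cvar * sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, cbeta / np.sqrt(var), np.nan)
    return TStatMap(t=t, df=df, level="run", contrast_name=contrast_name,
                    beta=cbeta, beta_var=var)


def second_level(run_maps: list[TStatMap], contrast_name: str = "") -> TStatMap:
    """Fixed-effects (inverse-variance weighted) combination across runs
    within participant."""
    if len(run_maps) == 0:
        raise ValueError("no run maps")
    if len(run_maps) == 1:
        warnings.warn("single run: second level is a passthrough")
        m = run_maps[0]
        return TStatMap(t=m.t.copy(), df=m.df, level="second",
                        contrast_name=contrast_name or m.contrast_name,
                        beta=m.beta, beta_var=m.beta_var)
    for m in run_maps:
        if m.beta is None or m.beta_var is None:
            raise ValueError("run maps must carry beta and beta_var")
    W = np.stack([1.0 / m.beta_var for m in run_maps])
    B = np.stack([m.beta for m in run_maps])
    wsum = W.sum(axis=0)
    beta_fe = (W * B).sum(axis=0) / wsum
    var_fe = 1.0 / wsum
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_fe / np.sqrt(var_fe)
    df = float(sum(m.df for m in run_maps))
    return TStatMap(t=t, df=df, level="second",
                    contrast_name=contrast_name or run_maps[0].contrast_name,
                    beta=beta_fe, beta_var=var_fe)
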