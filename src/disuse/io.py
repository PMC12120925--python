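"""Readers and writers: NIfTI volumes, TSV tables, JSON results.

Volume grayordinates are written as NIfTI-1 with a diagonal affine derived
from the space's voxel grid (0-based voxel indices, voxel->mm affine, RAS);
full grayordinate vectors (surface + volume) are written as TSV with
structure labels so every map round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datamodel import BoldRun, MotionTrace
from .space import VOLUME, GrayordinateSpace


# ---------------------------------------------------------------------------
# maps

def _volume_grid(space: GrayordinateSpace):
    """Voxel indices and affine for the volume-like grayordinates."""
    vol = np.flatnonzero(space.kind == VOLUME)
    h = space.voxel_size_mm
    origin = space.coords[vol].min(axis=0) if vol.size else np.zeros(3)
    ijk = np.round((space.coords[vol] - origin) / h).astype(int)
    shape = tuple(ijk.max(axis=0) + 1) if vol.size else (1, 1, 1)
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = origin
    return vol, ijk, shape, affine


def write_map(values: np.ndarray, space: GrayordinateSpace, path: str | Path) -> list[Path]:
    """Write a per-grayordinate map as NIfTI (volume part) + TSV (full
    vector with structure labels). ``path`` is a prefix; returns the files
    written."""
    values = np.asarray(values, dtype=float)
    if values.shape != (space.n,):
        raise ValueError(f"map length {values.shape} != n={space.n}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    tsv = path.with_suffix(".tsv")
    pd.DataFrame({
        "grayordinate": np.arange(space.n),
        "structure": space.structure_label,
        "x_mm": space.coords[:, 0],
        "y_mm": space.coords[:, 1],
        "z_mm": space.coords[:, 2],
        "value": values,
    }).to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    written.append(tsv)
    vol, ijk, shape, affine = _volume_grid(space)
    if vol.size:
        img_data = np.zeros(shape, dtype=np.float64)
        img_data[tuple(ijk.T)] = values[vol]
        nii = path.with_suffix(".nii")
        nib.save(nib.Nifti1Image(img_data, affine), nii)
        written.append(nii)
    return written


def read_map(path: str | Path) -> np.ndarray:
    """Reload the full grayordinate vector from the TSV written by
    :func:`write_map`."""
    df = pd.read_csv(Path(path).with_suffix(".tsv"), sep="\t")
    return df["value"].to_numpy()


# ---------------------------------------------------------------------------
# runs

def write_bold_run(run: BoldRun, prefix: str | Path) -> list[Path]:
    """Write one run as dense TSV (grayordinate x time), motion TSV and a
    JSON sidecar with the session metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data_path = prefix.with_suffix(".data.tsv")
    np.savetxt(data_path, run.data, delimiter="\t", fmt="%.17g")
    motion_path = prefix.with_suffix(".motion.tsv")
    mot = pd.DataFrame(
        run.motion.params6,
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    mot.insert(0, "fd_mm", run.motion.fd_mm)
    mot.to_csv(motion_path, sep="\t", index=False, float_format="%.17g")
    meta_path = prefix.with_suffix(".json")
    meta = {
        "tr_seconds": run.tr_seconds,
        "session_id": run.session_id,
        "phase": run.phase,
        "day_index": run.day_index,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return [data_path, motion_path, meta_path]


def load_bold_run(
    path: str | Path,
    meta: dict | None = None,
    mask_path: str | Path | None = None,
    motion_path: str | Path | None = None,
) -> BoldRun:
    """Load a run from a 4-D NIfTI volume (with an optional mask) or from a
    dense TSV matrix with its JSON sidecar.

    ``meta`` overrides sidecar metadata; tr_seconds, session_id and phase
    must be available from one of the two. A motion TSV whose row count
    differs from the frame count is an error.
    """
    path = Path(path)
    meta = dict(meta or {})
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 4:
            raise ValueError("expected a 4-D NIfTI volume")
        if mask_path is not None:
            mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        else:
            mask = np.ones(arr.shape[:3], dtype=bool)
        # canonical flattening: linear voxel index (C order) within the mask
        data = arr[mask]
    else:
        sidecar = path.with_suffix("").with_suffix(".json")
        if path.name.endswith(".data.tsv"):
            sidecar = Path(str(path)[: -len(".data.tsv")] + ".json")
        if sidecar.exists():
            loaded = json.loads(sidecar.read_text())
            loaded.update(meta)
            meta = loaded
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if "tr_seconds" not in meta or meta["tr_seconds"] is None:
        raise ValueError("metadata incomplete: tr_seconds missing")
    T = data.shape[1]
    if motion_path is None and not str(path).endswith(".nii"):
        cand = Path(str(path).replace(".data.tsv", ".motion.tsv"))
        if cand.exists():
            motion_path = cand
    if motion_path is not None:
        mot = pd.read_csv(motion_path, sep="\t")
        if len(mot) != T:
            raise ValueError(
                f"motion trace has {len(mot)} rows for T={T} frames"
            )
        params = mot[["trans_x", "trans_y", "trans_z",
                      "rot_x", "rot_y", "rot_z"]].to_numpy()
        motion = MotionTrace(fd_mm=mot["fd_mm"].to_numpy(), params6=params)
    else:
        motion = MotionTrace(fd_mm=np.zeros(T), params6=np.zeros((T, 6)))
    return BoldRun(
        data=data,
        tr_seconds=float(meta["tr_seconds"]),
        session_id=str(meta.get("session_id", path.stem)),
        phase=meta.get("phase", "pre"),
        motion=motion,
        day_index=float(meta.get("day_index", 0.0)),
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
    return path
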