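"""The spatial substrate: grayordinates, structure labels, adjacency.

A *grayordinate* is a unified analysis unit — a cortical surface vertex or a
subcortical voxel. Maps and time series are indexed by a single canonical
grayordinate order (sorted by structure label, then linear voxel index) so
that every stage of the pipeline joins on the same axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

SURFACE = "surface"
VOLUME = "volume"


@dataclass
class GrayordinateSpace:
    """Coordinates, structure labels and neighbor graph for all grayordinates.

    Parameters
    ----------
    coords : (n, 3) float array
        Position of each grayordinate in mm (RAS, MNI-like).
    structure_label : (n,) array of str
        One anatomical structure per grayordinate, e.g. ``"cortex-left"``,
        ``"thalamus-left"``.
    adjacency : (n, n) sparse bool matrix
        Symmetric, irreflexive neighbor relation. Surface-like structures use
        a 4-neighborhood, volume-like a 6-neighborhood; neighbors never cross
        structure boundaries.
    kind : (n,) array of str
        ``"surface"`` or ``"volume"`` per grayordinate.
    snr : (n,) float array, optional
        Relative signal amplitude profile (1 at periphery, lower toward the
        brain center, emulating coil-distance signal loss).
    """

    coords: np.ndarray
    structure_label: np.ndarray
    adjacency: sp.spmatrix
    kind: np.ndarray
    snr: np.ndarray | None = None
    voxel_size_mm: float = 3.0
    _struct_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.structure_label = np.asarray(self.structure_label)
        self.kind = np.asarray(self.kind)
        n = self.n
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        A = sp.csr_matrix(self.adjacency).astype(bool)
        if A.shape != (n, n):
            raise ValueError("adjacency must be n x n")
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        self.adjacency = A
        if self.snr is not None:
            self.snr = np.asarray(self.snr, dtype=float)
            if self.snr.shape != (n,):
                raise ValueError("snr must have length n")
        self._struct_index = {
            s: np.flatnonzero(self.structure_label == s)
            for s in self.structures
        }

    @property
    def n(self) -> int:
        return len(self.structure_label)

    @property
    def structures(self) -> list[str]:
        return sorted(set(self.structure_label.tolist()))

    def indices(self, structure: str) -> np.ndarray:
        """Grayordinate indices belonging to one structure."""
        try:
            return self._struct_index[structure]
        except KeyError:
            raise KeyError(f"unknown structure {structure!r}") from None

    def sub_adjacency(self, structure: str) -> tuple[np.ndarray, sp.csr_matrix]:
        """(indices, adjacency restricted to one structure)."""
        idx = self.indices(structure)
        return idx, self.adjacency[np.ix_(idx, idx)].tocsr()


def lattice_adjacency(shape: tuple[int, ...]) -> sp.csr_matrix:
    """Adjacency of a regular lattice: 4-neighborhood in 2-D, 6 in 3-D."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    rows, cols = [], []
    for axis in range(len(shape)):
        a = np.moveaxis(idx, axis, 0)
        rows.append(a[:-1].ravel())
        cols.append(a[1:].ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = idx.size
    A = sp.coo_matrix(
        (np.ones(2 * len(r), dtype=bool), (np.r_[r, c], np.r_[c, r])),
        shape=(n, n),
    )
    return A.tocsr()


def block_diag_spaces(blocks: list[sp.spmatrix]) -> sp.csr_matrix:
    return sp.block_diag(blocks, format="csr").astype(bool)
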