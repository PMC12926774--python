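"""Slice-wise PCA of noise-ROI voxel timeseries.

Voxel timeseries from the noise ROI of one slice are arranged as a T x V
matrix (rows: time points, columns: voxels), columns are mean-centered,
and the principal components are obtained by singular value
decomposition. The component scores (left singular vectors scaled by the
singular values) are the candidate nuisance regressor timeseries; the
number to retain is decided separately by parallel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MaskVolume, RegressorTable, VolumeSeries

__all__ = ["SliceTimeseriesMatrix", "PCResult", "extract_slice_matrix",
           "slice_pca", "pc_regressors", "EmptySliceError"]


class EmptySliceError(ValueError):
    """Raised when a slice has too few usable noise-ROI voxels."""


@dataclass
class SliceTimeseriesMatrix:
    """T x V matrix of noise-ROI voxel timeseries for one slice."""

    values: np.ndarray                 # (T, V)
    voxel_coords: np.ndarray           # (V, 2) int (x, y), lexicographic
    slice_index: int
    dropped_coords: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (T, V) matrix")
        if self.voxel_coords.shape != (self.values.shape[1], 2):
            raise ValueError("voxel_coords must be (V, 2)")

    @property
    def T(self) -> int:  # noqa: N802 - T is the field's conventional name
        return self.values.shape[0]

    @property
    def V(self) -> int:  # noqa: N802
        return self.values.shape[1]


@dataclass
class PCResult:
    """Principal components of one slice matrix.

    scores: T x N component timeseries (U * s). eigenvalues: s^2/(T-1),
    descending — the variance explained by each component. loadings:
    V x N spatial weights (right singular vectors). N = min(T-1, V).
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    singular_values: np.ndarray
    loadings: np.ndarray
    n_components: int

    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


def extract_slice_matrix(v: VolumeSeries, roi: MaskVolume,
                         slice_index: int) -> SliceTimeseriesMatrix:
    """Gather noise-ROI voxel timeseries of one slice into a T x V matrix.

    Columns are ordered lexicographically by (x, y). Voxels with zero
    temporal variance are dropped (they carry no information and would
    make the matrix degenerate) and reported in ``dropped_coords``.
    """
    if roi.shape != v.shape[:3]:
        raise ValueError("ROI grid does not match the volume grid")
    coords = roi.slice_coords(slice_index)
    if coords.shape[0] == 0:
        raise EmptySliceError(f"slice {slice_index}: no ROI voxels")
    mat = v.data[coords[:, 0], coords[:, 1], slice_index, :].T  # (T, V)
    variances = mat.var(axis=0)
    keep = variances > 0
    dropped = coords[~keep]
    mat = mat[:, keep]
    coords = coords[keep]
    if mat.shape[1] < 2:
        raise EmptySliceError(
            f"slice {slice_index}: fewer than 2 non-constant ROI voxels")
    return SliceTimeseriesMatrix(values=mat, voxel_coords=coords,
                                 slice_index=slice_index,
                                 dropped_coords=dropped)


def _fix_signs(scores: np.ndarray, loadings: np.ndarray) -> None:
    """Make each component's largest-magnitude loading positive (in place).

    SVD signs are arbitrary; this pins them deterministically.
    """
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def slice_pca(m: SliceTimeseriesMatrix) -> PCResult:
    """PCA of one slice matrix by SVD of the column-centered data.

    With T timepoints and V voxels the centered matrix has rank at most
    min(T-1, V); exactly that many components are returned.
    """
    X = m.values
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need T >= 3 and V >= 2")
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("matrix contains non-finite entries")
    T, V = X.shape
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = min(T - 1, V)
    U, s, Vt = U[:, :n], s[:n], Vt[:n]
    scores = U * s
    loadings = Vt.T.copy()
    _fix_signs(scores, loadings)
    eigenvalues = s ** 2 / (T - 1)
    return PCResult(scores=scores, eigenvalues=eigenvalues,
                    singular_values=s, loadings=loadings, n_components=n)


def pca_eigenvalues(values: np.ndarray) -> np.ndarray:
    """Eigenvalues only, for callers that do not need scores/loadings."""
    T = values.shape[0]
    Xc = values - values.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    n = min(T - 1, values.shape[1])
    return s[:n] ** 2 / (T - 1)


def pc_regressors(pc: PCResult, k: int) -> RegressorTable:
    """First ``k`` component timeseries as unit-variance nuisance regressors.

    Columns are named PC1..PCk in group "pca". Variance normalisation
    only conditions the design matrix; it does not change fitted models.
    """
    if k < 0 or k > pc.n_components:
        raise IndexError(f"k={k} out of range [0, {pc.n_components}]")
    if k == 0:
        return RegressorTable()
    cols = {}
    for j in range(k):
        col = pc.scores[:, j]
        sd = col.std(ddof=1)
        cols[f"PC{j + 1}"] = col / sd if sd > 0 else col
    return RegressorTable(pd.DataFrame(cols),
                          {name: "pca" for name in cols})
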