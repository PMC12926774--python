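"""Voxel-wise GLM fitting and F-tests.

Models are fit slice-by-slice inside a cord mask, after projecting a
discrete-cosine high-pass basis (default cutoff 100 s) out of both the
data and the regressors — the identical operator on both sides, so
fitting filtered data against filtered regressors is equivalent to
including the basis as confound regressors. Inference uses nested
F-tests between a full and a reduced model, or omnibus F-tests dropping
a whole regressor group; F maps are converted to z through the
upper-tail survival function evaluated in log space.

Ordinary least squares is the default. A single-lag autoregressive
prewhitening option (estimate rho from OLS residuals per voxel,
Cochrane-Orcutt transform, refit) is available as an approximation to
full prewhitening and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .core import MaskVolume, RegressorTable, VolumeSeries
from .nuisance import DesignMatrix

__all__ = ["GLMResult", "FTestResult", "highpass_filter", "dct_highpass_basis",
           "fit_glm", "nested_f_test", "omnibus_f_test",
           "significant_proportion"]

DEFAULT_HIGHPASS_S = 100.0


# ---------------------------------------------------------------------------
# High-pass filtering


def dct_highpass_basis(T: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Orthonormal basis of the constant plus slow cosines.

    Includes cos(pi*k*(t+0.5)/T) for every k whose period 2*T*tr/k is at
    least ``cutoff_s``. Projecting this basis out removes fluctuations
    slower than the cutoff.
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff_s must exceed twice the TR")
    n_cos = int(np.floor(2 * T * tr_s / cutoff_s))
    if n_cos + 1 >= T:
        raise ValueError(
            f"cutoff {cutoff_s}s leaves no residual dof for T={T}")
    t = np.arange(T)
    cols = [np.ones(T) / np.sqrt(T)]
    for k in range(1, n_cos + 1):
        c = np.cos(np.pi * k * (t + 0.5) / T)
        cols.append(c / np.linalg.norm(c))
    return np.column_stack(cols)


def highpass_filter(series, tr_s: float,
                    cutoff_s: float = DEFAULT_HIGHPASS_S):
    """Project the high-pass basis out of a vector, matrix, or table.

    The same operator must be applied to the data and the regressors of
    a model; :func:`fit_glm` does this internally.
    """
    if isinstance(series, RegressorTable):
        filt = highpass_filter(series.values(), tr_s, cutoff_s)
        data = series.data.copy()
        data[:] = filt
        return RegressorTable(data, dict(series.groups))
    x = np.asarray(series, dtype=np.float64)
    vec = x.ndim == 1
    if vec:
        x = x[:, None]
    B = dct_highpass_basis(x.shape[0], tr_s, cutoff_s)
    out = x - B @ (B.T @ x)
    return out[:, 0] if vec else out


# ---------------------------------------------------------------------------
# GLM fit


@dataclass
class GLMResult:
    """Voxel-wise least-squares fit inside a mask.

    Voxels are stored flat in ``coords`` order (sorted by slice, then
    x, y). ``residual_dof`` = T - design rank - filter basis size,
    because the filter is a projection applied to both sides.
    """

    coords: np.ndarray              # (nvox, 3) int (x, y, slice)
    betas: np.ndarray               # (nvox, p)
    residuals: np.ndarray           # (nvox, T)
    rss: np.ndarray                 # (nvox,)
    column_names: list[str]
    design_rank: int
    filter_dim: int
    residual_dof: int
    mask: MaskVolume
    designs: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    model_kind: str = ""
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.residuals.shape[1]

    def filtered_data(self, slice_index: int,
                      idx: np.ndarray) -> np.ndarray:
        """Reconstruct the filtered data of given voxel rows: X@beta + r."""
        X = self.designs[slice_index]
        return (X @ self.betas[idx].T) + self.residuals[idx].T

    def to_map(self, values: np.ndarray,
               fill: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3D grid."""
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = values
        return out


def _mask_coords(mask: MaskVolume) -> np.ndarray:
    xs, ys, zs = np.nonzero(mask.data)
    order = np.lexsort((ys, xs, zs))
    return np.column_stack([xs[order], ys[order], zs[order]])


def fit_glm(v: VolumeSeries,
            design: DesignMatrix | dict[int, DesignMatrix],
            mask: MaskVolume,
            prewhiten: str = "none",
            hp_cutoff_s: float | None = DEFAULT_HIGHPASS_S) -> GLMResult:
    """Fit a design to every masked voxel, slice by slice.

    ``design`` may be a single DesignMatrix used for all slices or a
    per-slice mapping (slice-wise CSF/RETROICOR/PCA regressors differ by
    slice). Data and regressors pass through the same high-pass
    projection before the fit.
    """
    if prewhiten not in ("none", "ar1"):
        raise ValueError("prewhiten must be 'none' or 'ar1'")
    if not mask.data.any():
        raise ValueError("mask is empty")
    coords = _mask_coords(mask)
    T = v.n_timepoints

    def design_for(s: int) -> DesignMatrix:
        return design[s] if isinstance(design, dict) else design

    any_design = design_for(int(coords[0, 2]))
    if any_design.n_timepoints != T:
        raise ValueError("design length does not match the series")
    names = any_design.regressors.names
    groups = dict(any_design.regressors.groups)
    p = len(names)

    if hp_cutoff_s is not None:
        B = dct_highpass_basis(T, v.tr_s, hp_cutoff_s)
        filter_dim = B.shape[1]
    else:
        B = None
        filter_dim = 0

    betas = np.empty((coords.shape[0], p))
    residuals = np.empty((coords.shape[0], T))
    rss = np.empty(coords.shape[0])
    designs: dict[int, np.ndarray] = {}
    ranks: set[int] = set()

    for s in np.unique(coords[:, 2]):
        rows = np.nonzero(coords[:, 2] == s)[0]
        c = coords[rows]
        Y = v.data[c[:, 0], c[:, 1], s, :].T             # (T, nvox_s)
        d = design_for(int(s))
        if d.regressors.names != names:
            raise ValueError("per-slice designs must share column names")
        X = d.matrix()
        if B is not None:
            Y = Y - B @ (B.T @ Y)
            X = X - B @ (B.T @ X)
        designs[int(s)] = X
        rank = int(np.linalg.matrix_rank(X))
        ranks.add(rank)
        beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        if prewhiten == "ar1":
            beta, resid = _refit_ar1(X, Y, resid)
        betas[rows] = beta.T
        residuals[rows] = resid.T
        rss[rows] = np.einsum("ij,ij->j", resid, resid)

    rank = max(ranks)
    residual_dof = T - rank - filter_dim
    if residual_dof <= 0:
        raise ValueError("no residual degrees of freedom")
    return GLMResult(coords=coords, betas=betas, residuals=residuals,
                     rss=rss, column_names=names, design_rank=rank,
                     filter_dim=filter_dim, residual_dof=residual_dof,
                     mask=mask, designs=designs,
                     model_kind=any_design.model_kind, groups=groups)


def _refit_ar1(X: np.ndarray, Y: np.ndarray,
               resid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-lag Cochrane-Orcutt refit per voxel (approximate whitening)."""
    T, p = X.shape
    beta_out = np.empty((p, Y.shape[1]))
    resid_out = np.empty_like(Y)
    for j in range(Y.shape[1]):
        r = resid[:, j]
        denom = float(r[:-1] @ r[:-1])
        rho = float(r[1:] @ r[:-1]) / denom if denom > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
        w0 = np.sqrt(1 - rho ** 2)
        Xw = np.vstack([w0 * X[:1], X[1:] - rho * X[:-1]])
        yw = np.concatenate([w0 * Y[:1, j], Y[1:, j] - rho * Y[:-1, j]])
        b, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        beta_out[:, j] = b
        resid_out[:, j] = yw - Xw @ b
    return beta_out, resid_out


# ---------------------------------------------------------------------------
# F-tests


@dataclass
class FTestResult:
    """Voxel-wise F, p, and z for one contrast."""

    coords: np.ndarray
    F: np.ndarray
    p: np.ndarray
    z: np.ndarray
    df_num: int
    df_den: int
    mask: MaskVolume

    def to_map(self, which: str = "z", fill: float = np.nan) -> np.ndarray:
        values = getattr(self, which)
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = values
        return out


def _f_to_pz(F: np.ndarray, df_num: int,
             df_den: int) -> tuple[np.ndarray, np.ndarray]:
    logp = stats.f.logsf(F, df_num, df_den)
    p = np.exp(logp)
    # z = Phi^{-1}(1 - p) computed from log p to stay finite for huge F
    z = -special.ndtri_exp(logp)
    return p, z


def nested_f_test(full: GLMResult, reduced: GLMResult) -> FTestResult:
    """F-test comparing a full model with a nested reduced model.

    F = ((rss_r - rss_f)/df_num) / (rss_f/df_den), with df_num the rank
    added by the extra columns and df_den the full model's residual dof.
    """
    if not set(reduced.column_names) < set(full.column_names):
        raise ValueError("reduced design columns must be a strict subset "
                         "of the full design columns")
    if full.coords.shape != reduced.coords.shape or \
            not np.array_equal(full.coords, reduced.coords):
        raise ValueError("models were fit on different masks")
    if full.filter_dim != reduced.filter_dim:
        raise ValueError("models were filtered differently")
    df_num = full.design_rank - reduced.design_rank
    if df_num <= 0:
        raise ValueError("designs are not nested (no added rank)")
    df_den = full.residual_dof
    num = np.maximum(reduced.rss - full.rss, 0.0) / df_num
    den = full.rss / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(den > 0, num / den, 0.0)
    p, z = _f_to_pz(F, df_num, df_den)
    return FTestResult(coords=full.coords.copy(), F=F, p=p, z=z,
                       df_num=df_num, df_den=df_den, mask=full.mask)


def omnibus_f_test(glm: GLMResult, group: str) -> FTestResult:
    """Joint F-test that an entire regressor group explains no variance.

    Equivalent to the nested test against the model with the whole
    group removed; df_num is the rank the group adds to the design.
    """
    drop = [c for c in glm.column_names if glm.groups.get(c) == group]
    if not drop:
        raise ValueError(f"group {group!r} is empty in this design")
    keep_idx = [i for i, c in enumerate(glm.column_names) if c not in drop]
    rss_r = np.empty(glm.n_voxels)
    rank_r: set[int] = set()
    for s, X in glm.designs.items():
        rows = np.nonzero(glm.coords[:, 2] == s)[0]
        Yf = glm.filtered_data(s, rows)
        Xr = X[:, keep_idx]
        rank_r.add(int(np.linalg.matrix_rank(Xr)))
        beta, _, _, _ = np.linalg.lstsq(Xr, Yf, rcond=None)
        r = Yf - Xr @ beta
        rss_r[rows] = np.einsum("ij,ij->j", r, r)
    df_num = glm.design_rank - max(rank_r)
    if df_num <= 0:
        raise ValueError(f"group {group!r} adds no rank after filtering")
    df_den = glm.residual_dof
    num = np.maximum(rss_r - glm.rss, 0.0) / df_num
    den = glm.rss / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(den > 0, num / den, 0.0)
    p, z = _f_to_pz(F, df_num, df_den)
    return FTestResult(coords=glm.coords.copy(), F=F, p=p, z=z,
                       df_num=df_num, df_den=df_den, mask=glm.mask)


def significant_proportion(ft: FTestResult, roi: MaskVolume,
                           alpha: float = 0.05) -> tuple[float, float]:
    """Fraction of ROI voxels with p < alpha, and the median F in the ROI.

    Uncorrected voxel-wise threshold; the proportion and median are the
    summary statistics extracted per tissue mask.
    """
    inroi = roi.data[ft.coords[:, 0], ft.coords[:, 1], ft.coords[:, 2]]
    if not inroi.any():
        raise ValueError("ROI does not overlap the result mask")
    p = ft.p[inroi]
    F = ft.F[inroi]
    return float(np.mean(p < alpha)), float(np.median(F))
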