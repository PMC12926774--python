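"""Post-fit evaluation metrics.

tSNR of denoised data, spatial Spearman agreement of statistical maps,
Dice overlap and activation-change counts between significance masks,
and slice-wise seed connectivity between gray-matter horn ROIs with
Fisher r-to-z transformed correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import MaskVolume, VolumeSeries
from .glm import GLMResult

__all__ = ["TsnrMap", "ConnectivityResult", "tsnr", "spatial_spearman",
           "dice", "activation_change", "seed_connectivity"]

HORN_NAMES = ("left_ventral", "left_dorsal", "right_ventral", "right_dorsal")
PAIR_CLASSES = ("VV", "DD", "VD_within", "VD_between")
_R_CLIP = 1.0 - 1e-7


@dataclass
class TsnrMap:
    """Temporal SNR per voxel: mean / sd of (residual + functional mean)."""

    coords: np.ndarray
    tsnr: np.ndarray
    mean_map: np.ndarray
    resid_sd: np.ndarray
    flagged: np.ndarray  # zero-variance voxels; tsnr is NaN there
    mask: MaskVolume

    def to_map(self, fill: float = np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.coords[:, 0], self.coords[:, 1],
            self.coords[:, 2]] = self.tsnr
        return out

    def mean_tsnr(self) -> float:
        return float(np.nanmean(self.tsnr[~self.flagged]))


def tsnr(glm: GLMResult, mean_map: np.ndarray) -> TsnrMap:
    """tSNR of model-denoised data.

    The functional mean is added back to the residuals, then
    tsnr = mean / sd over time (sd with the n-1 denominator). Voxels
    whose residual variance is zero are flagged rather than valued.
    """
    mu = np.asarray(mean_map, dtype=float)
    vox_mean = mu[glm.coords[:, 0], glm.coords[:, 1], glm.coords[:, 2]]
    series = glm.residuals + vox_mean[:, None]
    m = series.mean(axis=1)
    sd = series.std(axis=1, ddof=1)
    flagged = sd == 0
    out = np.full(glm.n_voxels, np.nan)
    out[~flagged] = m[~flagged] / sd[~flagged]
    return TsnrMap(coords=glm.coords.copy(), tsnr=out, mean_map=vox_mean,
                   resid_sd=sd, flagged=flagged, mask=glm.mask)


def spatial_spearman(map_a: np.ndarray, map_b: np.ndarray,
                     mask: MaskVolume) -> float:
    """Spearman rank correlation of two maps over masked voxels."""
    a = np.asarray(map_a)[mask.data]
    b = np.asarray(map_b)[mask.data]
    if a.size < 3:
        raise ValueError("need at least 3 voxels in the mask")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant map")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def dice(mask_a: MaskVolume, mask_b: MaskVolume) -> float:
    """Dice similarity coefficient 2|A.B| / (|A|+|B|); 1 if both empty."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks are on different grids")
    a, b = mask_a.data, mask_b.data
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def activation_change(base_mask: MaskVolume, other_mask: MaskVolume,
                      roi: MaskVolume) -> dict[str, int]:
    """Voxels gained/lost/kept between two significance masks in an ROI."""
    if base_mask.shape != other_mask.shape or base_mask.shape != roi.shape:
        raise ValueError("masks are on different grids")
    b, o, r = base_mask.data, other_mask.data, roi.data
    return {
        "now_active": int((o & ~b & r).sum()),
        "no_longer_active": int((b & ~o & r).sum()),
        "both": int((b & o & r).sum()),
    }


@dataclass
class ConnectivityResult:
    """Slice-wise horn-to-horn connectivity with run-level summaries.

    ``r`` and ``z`` map slice -> 4x4 matrices ordered as HORN_NAMES;
    ``class_mean_z`` averages Fisher z over slices for the four pair
    classes (ventral-ventral, dorsal-dorsal, ventral-dorsal within and
    between hemicords).
    """

    r: dict[int, np.ndarray]
    z: dict[int, np.ndarray]
    class_mean_z: dict[str, float]
    skipped_slices: list[int]


def _pair_class_values(z: np.ndarray) -> dict[str, float]:
    # index order: 0 LV, 1 LD, 2 RV, 3 RD
    return {
        "VV": z[0, 2],
        "DD": z[1, 3],
        "VD_within": 0.5 * (z[0, 1] + z[2, 3]),
        "VD_between": 0.5 * (z[0, 3] + z[2, 1]),
    }


def seed_connectivity(residual: VolumeSeries,
                      horn_masks: dict[str, MaskVolume],
                      ) -> ConnectivityResult:
    """Slice-wise full-correlation connectivity between horn ROIs.

    Per slice: the mean timeseries of each horn, the 4x4 Pearson
    correlation matrix, and its Fisher z transform (|r| clipped at
    1 - 1e-7 to keep z finite). Slices where any horn is empty, or any
    mean series constant, are skipped and reported. Class summaries
    average z across retained slices.
    """
    missing = [h for h in HORN_NAMES if h not in horn_masks]
    if missing:
        raise ValueError(f"missing horn masks: {missing}")
    r_by_slice: dict[int, np.ndarray] = {}
    z_by_slice: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    for s in range(residual.n_slices):
        series = []
        ok = True
        for name in HORN_NAMES:
            coords = horn_masks[name].slice_coords(s)
            if coords.shape[0] == 0:
                ok = False
                break
            ts = residual.data[coords[:, 0], coords[:, 1], s, :].mean(axis=0)
            if np.ptp(ts) == 0:
                ok = False
                break
            series.append(ts)
        if not ok:
            skipped.append(s)
            continue
        r = np.corrcoef(np.asarray(series))
        z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
        r_by_slice[s] = r
        z_by_slice[s] = z
    if not r_by_slice:
        raise ValueError("every slice lacked a usable horn ROI")
    sums = {c: 0.0 for c in PAIR_CLASSES}
    for z in z_by_slice.values():
        for c, val in _pair_class_values(z).items():
            sums[c] += val
    n = len(z_by_slice)
    class_mean_z = {c: sums[c] / n for c in PAIR_CLASSES}
    return ConnectivityResult(r=r_by_slice, z=z_by_slice,
                              class_mean_z=class_mean_z,
                              skipped_slices=skipped)
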