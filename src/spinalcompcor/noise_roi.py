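"""Noise-ROI construction outside the spinal cord/CSF region.

The noise ROI is built slice-by-slice: the manually drawn cord/CSF mask
is dilated in-plane by a physical radius (default 18 mm, rounded to
whole voxels per axis), the original mask is subtracted, and a border of
voxels at the edge of the in-plane field of view (default 3) is trimmed.
Voxels in this ring are assumed to carry only non-neural fluctuations
(vascular pulsation, respiration, motion, scanner drift) and are the
source of the PCA nuisance regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MaskVolume

__all__ = ["NoiseRoiSpec", "dilate_mask", "build_noise_roi", "EmptyRoiError"]


class EmptyRoiError(ValueError):
    """Raised when the constructed noise ROI contains no voxels."""


@dataclass(frozen=True)
class NoiseRoiSpec:
    """Parameters of noise-ROI construction.

    dilation_mm: in-plane dilation radius in millimetres (default 18,
    chosen to reach the approximate image boundary of a reduced-FOV
    acquisition). edge_trim_voxels: width of the in-plane border removed
    from the ROI (default 3).
    """

    dilation_mm: float = 18.0
    edge_trim_voxels: int = 3

    def __post_init__(self) -> None:
        if self.dilation_mm <= 0:
            raise ValueError("dilation_mm must be positive")
        if self.edge_trim_voxels < 0:
            raise ValueError("edge_trim_voxels must be non-negative")


def _elliptical_footprint(rx: int, ry: int) -> np.ndarray:
    """Binary in-plane structuring element with voxel radii (rx, ry).

    A voxel offset (dx, dy) is inside iff (dx/rx)^2 + (dy/ry)^2 <= 1,
    which reduces to a circle when rx == ry.
    """
    dx = np.arange(-rx, rx + 1)[:, None]
    dy = np.arange(-ry, ry + 1)[None, :]
    rx_ = max(rx, 1)
    ry_ = max(ry, 1)
    return (dx / rx_) ** 2 + (dy / ry_) ** 2 <= 1.0 + 1e-12


def dilate_mask(mask: MaskVolume, radius_mm: float) -> MaskVolume:
    """Dilate a mask in-plane by a physical radius.

    The radius is rounded to the nearest whole voxel independently per
    in-plane axis, giving an elliptical footprint under anisotropic
    voxels. No dilation crosses slices.
    """
    if not mask.data.any():
        raise ValueError("mask is empty on every slice")
    vx, vy = mask.voxel_size_mm[0], mask.voxel_size_mm[1]
    rx = int(round(radius_mm / vx))
    ry = int(round(radius_mm / vy))
    if rx == 0 and ry == 0:
        warnings.warn(
            f"dilation radius {radius_mm} mm rounds to 0 voxels; "
            "mask returned unchanged", stacklevel=2)
        return MaskVolume(data=mask.data.copy().astype(np.uint8),
                          voxel_size_mm=mask.voxel_size_mm,
                          affine=mask.affine.copy())
    footprint = _elliptical_footprint(rx, ry)
    out = np.zeros_like(mask.data, dtype=bool)
    for s in range(mask.data.shape[2]):
        sl = mask.data[:, :, s]
        if sl.any():
            out[:, :, s] = ndimage.binary_dilation(sl, structure=footprint)
    return MaskVolume(data=out.astype(np.uint8),
                      voxel_size_mm=mask.voxel_size_mm,
                      affine=mask.affine.copy())


def build_noise_roi(cord_csf_mask: MaskVolume,
                    spec: NoiseRoiSpec | None = None) -> MaskVolume:
    """Construct the noise ROI from the cord/CSF mask.

    noise ROI = dilate(mask, dilation_mm)  minus  mask  minus  an
    edge_trim_voxels-wide in-plane border. The output is disjoint from
    the cord/CSF mask by construction.
    """
    spec = spec or NoiseRoiSpec()
    dilated = dilate_mask(cord_csf_mask, spec.dilation_mm)
    roi = dilated.data & ~cord_csf_mask.data
    t = spec.edge_trim_voxels
    if t > 0:
        border = np.ones(roi.shape[:2], dtype=bool)
        if roi.shape[0] > 2 * t and roi.shape[1] > 2 * t:
            border[t:-t, t:-t] = False
        roi &= ~border[:, :, None]
    if not roi.any():
        raise EmptyRoiError("noise ROI is empty on every slice")
    return MaskVolume(data=roi.astype(np.uint8),
                      voxel_size_mm=cord_csf_mask.voxel_size_mm,
                      affine=cord_csf_mask.affine.copy())
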