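"""Physiological and nuisance regressor construction.

Builds the regressor sets entering the subject-level models:

* RETROICOR — low-order Fourier expansions of cardiac and respiratory
  phase, evaluated at each slice's acquisition times (order 4 gives
  8 cardiac + 8 respiratory columns).
* CSF — mean timeseries of the highest-temporal-variance CSF voxels on
  a slice (top 20% by default).
* Motion and task regressors are consumed as prepared tables.

Three model variants are assembled from these groups:
Base = task + motion + CSF + RETROICOR (19 nuisance regressors with
2 motion + 1 CSF + order-4 RETROICOR); Extended = Base + PCA;
SpinalCompCor = task + motion + CSF + PCA (no recording-based
physiological regressors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import MaskVolume, PhysioTrace, RegressorTable, VolumeSeries

__all__ = ["RetroicorBasis", "DesignMatrix", "detect_peaks", "cardiac_phase",
           "respiratory_phase", "retroicor_regressors", "csf_regressor",
           "assemble_design"]

MODEL_KINDS = ("base", "extended", "spinalcompcor")


# ---------------------------------------------------------------------------
# Peak detection and phase estimation


def detect_peaks(trace: PhysioTrace, min_interval_s: float) -> np.ndarray:
    """Peak times (seconds) of a physiological trace.

    Local maxima above the trace's rolling median, with a refractory
    period of ``min_interval_s`` between accepted peaks. Returns a
    strictly increasing array; empty (with a warning) if no peaks.
    """
    if trace.duration_s <= 2 * min_interval_s:
        raise ValueError("trace shorter than twice the minimum interval")
    x = trace.samples
    distance = max(1, int(round(min_interval_s * trace.fs_hz)))
    win = 2 * int(round(min_interval_s * trace.fs_hz)) + 1
    rolling_med = ndimage.median_filter(x, size=win, mode="nearest")
    idx, _ = signal.find_peaks(x, distance=distance)
    idx = idx[x[idx] > rolling_med[idx]]
    if idx.size == 0:
        warnings.warn("no peaks detected", stacklevel=2)
        return np.empty(0)
    return trace.t0_s + idx / trace.fs_hz


def cardiac_phase(peak_times: np.ndarray,
                  sample_times: np.ndarray) -> np.ndarray:
    """Cardiac phase in [0, 2*pi) at each sample time.

    Phase is the elapsed fraction of the beat-to-beat interval,
    phi(t) = 2*pi*(t - t_prev)/(t_next - t_prev). Samples before the
    first or after the last peak use the nearest interval's rate,
    extrapolated (phase wraps modulo 2*pi).
    """
    peaks = np.asarray(peak_times, dtype=float)
    t = np.asarray(sample_times, dtype=float)
    if peaks.size < 2:
        raise ValueError("need at least 2 peaks to define cardiac phase")
    phi = np.empty_like(t)
    inside = (t >= peaks[0]) & (t < peaks[-1])
    if inside.any():
        k = np.searchsorted(peaks, t[inside], side="right") - 1
        frac = (t[inside] - peaks[k]) / (peaks[k + 1] - peaks[k])
        phi[inside] = 2 * np.pi * frac
    before = t < peaks[0]
    if before.any():
        p0 = peaks[1] - peaks[0]
        phi[before] = 2 * np.pi * (((t[before] - peaks[0]) / p0) % 1.0)
    after = t >= peaks[-1]
    if after.any():
        p1 = peaks[-1] - peaks[-2]
        phi[after] = 2 * np.pi * (((t[after] - peaks[-1]) / p1) % 1.0)
    return phi


def respiratory_phase(belt: PhysioTrace, sample_times: np.ndarray,
                      n_bins: int = 100) -> np.ndarray:
    """Respiratory phase in [-pi, pi] at each sample time.

    Histogram-equalised belt amplitude signed by the belt derivative:
    phi(t) = pi * H(b(t)) * sign(db/dt), where H is the cumulative
    amplitude-histogram fraction over the whole belt recording. Deep
    expiration maps near 0, peak inspiration near +pi, peak expiration
    (falling belt) near -pi.
    """
    b = belt.samples
    if np.ptp(b) == 0:
        raise ValueError("belt trace is constant")
    t = np.asarray(sample_times, dtype=float)
    bt = np.interp(t, belt.times, b)
    counts, edges = np.histogram(b, bins=n_bins)
    cdf = np.concatenate([[0.0], np.cumsum(counts)]) / b.size
    frac = np.interp(bt, edges, cdf)
    deriv = np.gradient(b) * belt.fs_hz
    dt = np.interp(t, belt.times, deriv)
    sgn = np.where(dt >= 0, 1.0, -1.0)
    return np.pi * frac * sgn


# ---------------------------------------------------------------------------
# RETROICOR


def retroicor_regressors(phi_c: np.ndarray, phi_r: np.ndarray,
                         order: int = 4) -> RegressorTable:
    """Fourier expansion of cardiac and respiratory phase.

    Columns cos(k*phi_c), sin(k*phi_c), cos(k*phi_r), sin(k*phi_r) for
    k = 1..order; 4*order columns in group "retro" (order 4 gives the
    standard 8 cardiac + 8 respiratory set).
    """
    phi_c = np.asarray(phi_c, dtype=float)
    phi_r = np.asarray(phi_r, dtype=float)
    if phi_c.shape != phi_r.shape or phi_c.ndim != 1:
        raise ValueError("phase vectors must be 1D and the same length")
    cols: dict[str, np.ndarray] = {}
    for k in range(1, order + 1):
        cols[f"card_cos{k}"] = np.cos(k * phi_c)
        cols[f"card_sin{k}"] = np.sin(k * phi_c)
    for k in range(1, order + 1):
        cols[f"resp_cos{k}"] = np.cos(k * phi_r)
        cols[f"resp_sin{k}"] = np.sin(k * phi_r)
    return RegressorTable(pd.DataFrame(cols), {c: "retro" for c in cols})


@dataclass
class RetroicorBasis:
    """Slice-resolved RETROICOR regressors for a whole run.

    Phases are evaluated at volume_onset + slice_times[slice], so each
    slice gets genuinely slice-wise columns.
    """

    order: int
    phi_c: np.ndarray  # (n_slices, T)
    phi_r: np.ndarray  # (n_slices, T)

    @classmethod
    def from_traces(cls, v: VolumeSeries, cardiac_peaks: np.ndarray,
                    belt: PhysioTrace, order: int = 4) -> "RetroicorBasis":
        n_s, T = v.n_slices, v.n_timepoints
        phi_c = np.empty((n_s, T))
        phi_r = np.empty((n_s, T))
        for s in range(n_s):
            t = v.slice_sample_times(s)
            phi_c[s] = cardiac_phase(cardiac_peaks, t)
            phi_r[s] = respiratory_phase(belt, t)
        return cls(order=order, phi_c=phi_c, phi_r=phi_r)

    def for_slice(self, slice_index: int) -> RegressorTable:
        return retroicor_regressors(self.phi_c[slice_index],
                                    self.phi_r[slice_index], self.order)


# ---------------------------------------------------------------------------
# CSF regressor


def csf_regressor(v: VolumeSeries, csf_mask: MaskVolume, slice_index: int,
                  top_fraction: float = 0.2) -> RegressorTable:
    """Slice-wise CSF nuisance regressor.

    CSF voxels on the slice are ranked by temporal variance; the
    timeseries of the top ceil(top_fraction * count) voxels are
    averaged into a single column (group "csf"). High-variance CSF
    voxels are the ones dominated by pulsatile flow.
    """
    coords = csf_mask.slice_coords(slice_index)
    if coords.shape[0] == 0:
        raise ValueError(f"no CSF voxels on slice {slice_index}")
    series = v.data[coords[:, 0], coords[:, 1], slice_index, :]  # (V, T)
    variances = series.var(axis=1, ddof=1)
    n_top = math.ceil(top_fraction * coords.shape[0])
    top = np.argsort(-variances, kind="stable")[:n_top]
    reg = series[top].mean(axis=0)
    return RegressorTable(pd.DataFrame({"csf": reg}), {"csf": "csf"})


# ---------------------------------------------------------------------------
# Design assembly


@dataclass
class DesignMatrix:
    """A named design for one slice: task columns plus grouped nuisance."""

    regressors: RegressorTable
    model_kind: str
    slice_index: int = 0

    @property
    def n_timepoints(self) -> int:
        return self.regressors.n_timepoints

    @property
    def task_columns(self) -> list[str]:
        return self.regressors.columns_in_group("task")

    @property
    def nuisance_columns(self) -> list[str]:
        return [c for c in self.regressors.names
                if self.regressors.groups[c] != "task"]

    @property
    def nuisance_count(self) -> int:
        return len(self.nuisance_columns)

    def matrix(self) -> np.ndarray:
        return self.regressors.values()


def _demean(table: RegressorTable) -> RegressorTable:
    data = table.data - table.data.mean(axis=0)
    return RegressorTable(data, dict(table.groups))


def assemble_design(task: RegressorTable | None,
                    motion: RegressorTable,
                    csf: RegressorTable,
                    retro: RegressorTable | None,
                    pca: RegressorTable | None,
                    model_kind: str,
                    slice_index: int = 0) -> DesignMatrix:
    """Assemble one of the three model designs from labelled groups.

    base = task+motion+csf+retro; extended = base + pca;
    spinalcompcor = task+motion+csf+pca. Nuisance columns are demeaned
    at assembly; the nuisance count excludes task columns.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    task = task or RegressorTable()
    retro = retro or RegressorTable()
    pca = pca or RegressorTable()
    if model_kind in ("extended", "spinalcompcor") and len(pca) == 0:
        raise ValueError(f"{model_kind} model requires PCA regressors")
    if model_kind in ("base", "extended") and len(retro) == 0:
        raise ValueError(f"{model_kind} model requires RETROICOR regressors")
    parts = [task, _demean(motion), _demean(csf)]
    if model_kind in ("base", "extended"):
        parts.append(_demean(retro))
    if model_kind in ("extended", "spinalcompcor"):
        parts.append(_demean(pca))
    table = RegressorTable.concat(parts)
    return DesignMatrix(regressors=table, model_kind=model_kind,
                        slice_index=slice_index)
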