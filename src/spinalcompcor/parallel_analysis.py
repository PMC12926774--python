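"""Parallel analysis: how many principal components to retain per slice.

For each slice, the template eigenvalue scree curve is compared with the
mean eigenvalue curve over many surrogate matrices (each built by
sampling one IAAFT surrogate per voxel). The cutoff is the component
index at which the curves intersect — the last template component that
explains more variance than surrogate (chance) components do. The
run-level summary is the median cutoff across slices, rounded half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MaskVolume, VolumeSeries, truncate_volume
from .slice_pca import (EmptySliceError, SliceTimeseriesMatrix,
                        extract_slice_matrix, pca_eigenvalues)
from .surrogates import SurrogateSet, build_surrogate_set

__all__ = ["ScreeCurves", "ParallelAnalysisResult", "sample_surrogate_matrix",
           "slice_cutoff", "run_parallel_analysis"]

DEFAULT_N_PER_VOXEL = 50
DEFAULT_N_MATRICES = 500


@dataclass
class ScreeCurves:
    """Template and mean-surrogate eigenvalue curves for one slice."""

    template_eigs: np.ndarray
    surrogate_mean_eigs: np.ndarray
    n_matrices: int
    cutoff: int


@dataclass
class ParallelAnalysisResult:
    """Per-slice scree curves and cutoffs, plus the run-level median."""

    per_slice: dict[int, ScreeCurves]
    median_cutoff: int
    truncated_to: int | None = None
    skipped_slices: list[int] = field(default_factory=list)

    def cutoffs(self) -> dict[int, int]:
        return {s: c.cutoff for s, c in self.per_slice.items()}


def sample_surrogate_matrix(s: SurrogateSet,
                            draw_seed: int | np.random.Generator,
                            ) -> SliceTimeseriesMatrix:
    """One surrogate slice matrix: an independent uniform surrogate pick
    per voxel (with replacement across matrices); column order preserved."""
    rng = (draw_seed if isinstance(draw_seed, np.random.Generator)
           else np.random.default_rng(draw_seed))
    picks = rng.integers(0, s.n_per_voxel, size=s.n_voxels)
    values = s.surrogates[np.arange(s.n_voxels), picks, :].T  # (T, V)
    coords = np.column_stack([np.arange(s.n_voxels),
                              np.zeros(s.n_voxels, dtype=int)])
    return SliceTimeseriesMatrix(values=values, voxel_coords=coords,
                                 slice_index=s.slice_index)


def slice_cutoff(template_eigs: np.ndarray,
                 surrogate_mean_eigs: np.ndarray) -> int:
    """Count of leading components whose template eigenvalue strictly
    exceeds the mean surrogate eigenvalue, up to the first violation.

    This operationalises the scree-curve intersection: 0 if the first
    component already fails; crossings after the first are ignored.
    """
    t = np.asarray(template_eigs, dtype=float)
    s = np.asarray(surrogate_mean_eigs, dtype=float)
    if t.shape != s.shape:
        raise ValueError("eigenvalue curves have different lengths")
    exceeds = t > s
    if exceeds.all():
        return int(t.size)
    return int(np.argmin(exceeds))


def _analyze_slice(matrix: SliceTimeseriesMatrix, n_per_voxel: int,
                   n_matrices: int, base_seed: int,
                   max_iter: int) -> ScreeCurves:
    template_eigs = pca_eigenvalues(matrix.values)
    sset = build_surrogate_set(matrix, n_per_voxel=n_per_voxel,
                               base_seed=base_seed, max_iter=max_iter)
    acc = np.zeros_like(template_eigs)
    for m in range(n_matrices):
        draw = np.random.default_rng(
            np.random.SeedSequence(
                [base_seed, matrix.slice_index, 982_451_653, m]))
        sm = sample_surrogate_matrix(sset, draw)
        acc += pca_eigenvalues(sm.values)
    mean_eigs = acc / n_matrices
    cutoff = slice_cutoff(template_eigs, mean_eigs)
    return ScreeCurves(template_eigs=template_eigs,
                       surrogate_mean_eigs=mean_eigs,
                       n_matrices=n_matrices, cutoff=cutoff)


def median_round_half_up(values) -> int:
    """Median of integer cutoffs; a half-integral median rounds up."""
    med = float(np.median(np.asarray(values, dtype=float)))
    return int(math.floor(med + 0.5))


def run_parallel_analysis(v: VolumeSeries, roi: MaskVolume,
                          n_per_voxel: int = DEFAULT_N_PER_VOXEL,
                          n_matrices: int = DEFAULT_N_MATRICES,
                          truncate_to: int | None = None,
                          base_seed: int = 0,
                          max_iter: int = 500,
                          ) -> ParallelAnalysisResult:
    """Full parallel analysis of a run.

    Optionally truncates to the first ``truncate_to`` volumes first (so
    scan length does not influence the component count), then per slice:
    extract the noise-ROI matrix, build surrogates, sample
    ``n_matrices`` surrogate matrices, run PCA on the template and each
    surrogate matrix, and find the scree intersection. Slices with too
    few usable voxels are skipped and reported.
    """
    if truncate_to is not None:
        v = truncate_volume(v, truncate_to)
    per_slice: dict[int, ScreeCurves] = {}
    skipped: list[int] = []
    for s in range(v.n_slices):
        try:
            matrix = extract_slice_matrix(v, roi, s)
        except EmptySliceError:
            skipped.append(s)
            continue
        per_slice[s] = _analyze_slice(matrix, n_per_voxel, n_matrices,
                                      base_seed, max_iter)
    if not per_slice:
        raise EmptySliceError("noise ROI unusable on every slice")
    median = median_round_half_up([c.cutoff for c in per_slice.values()])
    return ParallelAnalysisResult(per_slice=per_slice, median_cutoff=median,
                                  truncated_to=truncate_to,
                                  skipped_slices=skipped)
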