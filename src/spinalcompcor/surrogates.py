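"""IAAFT surrogate timeseries.

The iterative amplitude-adjusted Fourier transform produces, for a
template timeseries, surrogates that preserve the template's amplitude
distribution exactly and its power spectrum approximately, while
randomising phase. Surrogates are therefore, on average, uncorrelated
with the template and serve as a null for parallel analysis: principal
components of surrogate data capture what eigenvalue magnitudes arise
by chance from voxels with the observed spectra.

Algorithm: start from a random permutation of the template; iterate
(a) spectral adjustment — replace the current Fourier amplitudes with
the template's, keeping current phases (the zero-frequency term is taken
from the template), then (b) amplitude adjustment — rank-order remap the
values onto the template's sorted values. Stop when the rank ordering no
longer changes, or after ``max_iter`` iterations (default 500). The
final step is always the amplitude adjustment, so the output's value
multiset equals the template's exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurrogateSet", "iaaft_surrogate", "build_surrogate_set"]

DEFAULT_MAX_ITER = 500


@dataclass
class SurrogateSet:
    """All surrogates for one slice matrix.

    surrogates: array (V, n_per_voxel, T); surrogate (v, j) was built
    from voxel v's template with a seed substream derived from
    (base_seed, slice_index, v, j), so results do not depend on
    execution order.
    """

    surrogates: np.ndarray
    n_per_voxel: int
    base_seed: int
    slice_index: int
    iterations_used: np.ndarray  # (V, n_per_voxel) int

    @property
    def n_voxels(self) -> int:
        return self.surrogates.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.surrogates.shape[2]


def _surrogate_rng(base_seed: int, slice_index: int, voxel: int,
                   replicate: int) -> np.random.Generator:
    ss = np.random.SeedSequence([base_seed, slice_index, voxel, replicate])
    return np.random.default_rng(ss)


def _iaaft_batch(templates: np.ndarray, inits: np.ndarray,
                 max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Iterate IAAFT on a batch of series sharing nothing but shape.

    templates, inits: (B, T). Returns (surrogates (B, T), iterations (B,)).
    Rows converge independently; converged rows stop updating.
    """
    B, T = templates.shape
    sorted_t = np.sort(templates, axis=1)
    F = np.fft.rfft(templates, axis=1)
    amp = np.abs(F)
    dc = F[:, 0].copy()

    cur = inits.copy()
    # rank ordering of the initial surrogate; convergence is "ranks
    # unchanged between consecutive iterations"
    prev_idx = np.argsort(cur, axis=1, kind="stable")
    iters = np.zeros(B, dtype=int)
    active = np.ones(B, dtype=bool)

    for it in range(1, max_iter + 1):
        idx_a = np.nonzero(active)[0]
        if idx_a.size == 0:
            break
        sub = cur[idx_a]
        # (a) spectral adjustment: template amplitudes, current phases
        Fc = np.fft.rfft(sub, axis=1)
        mag = np.abs(Fc)
        phase = np.where(mag > 0, Fc / np.where(mag > 0, mag, 1.0), 1.0)
        Fnew = amp[idx_a] * phase
        Fnew[:, 0] = dc[idx_a]
        sub = np.fft.irfft(Fnew, n=T, axis=1)
        # (b) amplitude adjustment: rank-order remap onto template values
        idx = np.argsort(sub, axis=1, kind="stable")
        remapped = np.empty_like(sub)
        np.put_along_axis(remapped, idx, sorted_t[idx_a], axis=1)
        cur[idx_a] = remapped
        iters[idx_a] = it
        converged = np.all(idx == prev_idx[idx_a], axis=1)
        prev_idx[idx_a] = idx
        active[idx_a[converged]] = False
    return cur, iters


def iaaft_surrogate(x: np.ndarray,
                    seed: int | np.random.Generator,
                    max_iter: int = DEFAULT_MAX_ITER,
                    ) -> tuple[np.ndarray, int]:
    """One IAAFT surrogate of a template timeseries.

    Returns the surrogate and the number of iterations performed. A
    constant template is its own surrogate (0 iterations).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 8:
        raise ValueError("template must have at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("template contains non-finite values")
    if np.ptp(x) == 0:
        return x.copy(), 0
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    init = rng.permutation(x)
    sur, iters = _iaaft_batch(x[None, :], init[None, :], max_iter)
    return sur[0], int(iters[0])


def build_surrogate_set(matrix, n_per_voxel: int = 50,
                        base_seed: int = 0,
                        max_iter: int = DEFAULT_MAX_ITER) -> SurrogateSet:
    """Generate ``n_per_voxel`` IAAFT surrogates for every matrix column.

    ``matrix`` is a SliceTimeseriesMatrix (or any object with ``values``
    (T, V) and ``slice_index``). Reproducible bit-exactly from
    ``base_seed``: each surrogate's initial permutation is drawn from a
    per-(voxel, replicate) substream and the iteration itself is
    deterministic, so batched and one-at-a-time execution agree.
    """
    values = np.asarray(matrix.values, dtype=np.float64)
    slice_index = int(getattr(matrix, "slice_index", 0))
    T, V = values.shape
    templates = np.repeat(values.T, n_per_voxel, axis=0)       # (V*n, T)
    inits = np.empty_like(templates)
    row = 0
    for v in range(V):
        x = values[:, v]
        for j in range(n_per_voxel):
            rng = _surrogate_rng(base_seed, slice_index, v, j)
            inits[row] = rng.permutation(x)
            row += 1
    constant = np.ptp(templates, axis=1) == 0
    sur = templates.copy()
    iters = np.zeros(templates.shape[0], dtype=int)
    if (~constant).any():
        s, it = _iaaft_batch(templates[~constant], inits[~constant],
                             max_iter)
        sur[~constant] = s
        iters[~constant] = it
    return SurrogateSet(
        surrogates=sur.reshape(V, n_per_voxel, T),
        n_per_voxel=n_per_voxel,
        base_seed=base_seed,
        slice_index=slice_index,
        iterations_used=iters.reshape(V, n_per_voxel),
    )
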