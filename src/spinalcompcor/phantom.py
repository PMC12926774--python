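"""Synthetic cervical-cord fMRI phantom with known ground truth.

The phantom emulates, per axial slice, a concentric geometry — spinal
cord, surrounding CSF, and outer tissue — and a noise structure typical
of spinal cord fMRI at TR ~ 2 s:

* K planted spatially-coherent noise components supported in the
  tissue ring (the future noise ROI), recoverable by slice-wise PCA;
* quasi-periodic cardiac contamination (an order-4 Fourier series of
  the true cardiac phase, sampled at each slice's acquisition times)
  concentrated in CSF and vessel voxels — note 1 Hz cardiac activity
  sampled at TR 2 s aliases, as in real acquisitions;
* slower respiratory contamination in muscle, with a small global part;
* low-order polynomial drift;
* bulk-motion spikes with edge-weighted spatial profile;
* white thermal noise; and an optional block task in the ventral horns.

Matching pulse and respiratory-belt traces are generated from the same
event times, so recording-based regressors (RETROICOR) target exactly
the injected physiological contamination. Every planted quantity is
returned in :class:`PhantomTruth` for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MaskVolume, PhysioTrace, VolumeSeries

__all__ = ["PhantomConfig", "PhantomTruth", "simulate_phantom",
           "simulate_physio", "simulate_connectivity_phantom"]

# seed substream tags shared by simulate_phantom and simulate_physio so
# that the same seed yields the same cardiac/respiratory event times
_TAG_BEATS = 11
_TAG_BREATHS = 12
_TAG_COMPONENTS = 21
_TAG_THERMAL = 22
_TAG_MAPS = 23
_TAG_PHYSIO_WAVE = 24


@dataclass
class PhantomConfig:
    """All knobs of the phantom. Defaults give a 32x32x6x160 run at
    1x1x3 mm and TR 2 s that simulates in seconds."""

    nx: int = 32
    ny: int = 32
    n_slices: int = 6
    n_timepoints: int = 160
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    tr_s: float = 2.0
    cord_radius_mm: float = 4.0
    csf_outer_radius_mm: float = 7.0
    baseline: float = 1000.0

    n_components: int = 5            # K planted noise components
    component_amplitude: float = 4.0  # sd units per unit map weight

    cardiac_rate_hz: float = 1.0
    cardiac_amplitude: float = 0.0
    cardiac_jitter: float = 0.03
    resp_rate_hz: float = 0.25
    resp_amplitude: float = 0.0
    resp_jitter: float = 0.05
    drift_amplitude: float = 0.0
    spike_volumes: tuple[int, ...] = ()
    spike_amplitude: float = 0.0
    thermal_sd: float = 1.0

    task_block_s: float = 0.0        # 0 disables the task
    task_rest_s: float = 0.0
    task_amplitude: float = 0.0
    task_correlated_noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 0:
            raise ValueError("n_components must be >= 0")
        if self.cord_radius_mm >= self.csf_outer_radius_mm:
            raise ValueError("cord radius must be below the CSF outer radius")
        for name in ("component_amplitude", "cardiac_amplitude",
                     "resp_amplitude", "drift_amplitude", "spike_amplitude",
                     "thermal_sd", "task_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth of one simulated run."""

    component_timecourses: np.ndarray      # (K, T), mutually orthogonal
    component_maps: np.ndarray             # (K, nx, ny, n_slices)
    component_variance: np.ndarray         # (K, nx, ny, n_slices)
    task_regressor: np.ndarray             # (T,)
    task_betas: np.ndarray                 # (nx, ny, n_slices)
    beat_times: np.ndarray
    breath_times: np.ndarray
    cardiac_fourier_coeffs: np.ndarray     # (4, 2) cos/sin weights
    thermal_sd: float
    masks: dict[str, MaskVolume] = field(default_factory=dict)


def _event_times(duration_s: float, rate_hz: float, jitter: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic event times covering [−period, duration+period]."""
    period = 1.0 / rate_hz
    times = [-period]
    t = float(rng.uniform(0, period))
    while t < duration_s + 2 * period:
        times.append(t)
        step = period * (1.0 + jitter * float(rng.standard_normal()))
        t += max(step, 0.3 * period)
    return np.asarray(times)


def _phase_from_events(events: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear phase 0..2*pi between consecutive event times."""
    k = np.clip(np.searchsorted(events, t, side="right") - 1, 0,
                events.size - 2)
    frac = (t - events[k]) / (events[k + 1] - events[k])
    return 2 * np.pi * frac


def _disc(nx: int, ny: int, cx: float, cy: float, r_vox_x: float,
          r_vox_y: float) -> np.ndarray:
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    return ((x - cx) / r_vox_x) ** 2 + ((y - cy) / r_vox_y) ** 2 <= 1.0


def _geometry(cfg: PhantomConfig) -> dict[str, np.ndarray]:
    vx, vy, _ = cfg.voxel_size_mm
    cx, cy = (cfg.nx - 1) / 2.0, (cfg.ny - 1) / 2.0
    cord2d = _disc(cfg.nx, cfg.ny, cx, cy,
                   cfg.cord_radius_mm / vx, cfg.cord_radius_mm / vy)
    csf_outer = _disc(cfg.nx, cfg.ny, cx, cy,
                      cfg.csf_outer_radius_mm / vx,
                      cfg.csf_outer_radius_mm / vy)
    csf2d = csf_outer & ~cord2d
    tissue2d = ~csf_outer
    # vessels: four voxels just outside the CSF ring
    vr = int(round(cfg.csf_outer_radius_mm / vx)) + 1
    vessel2d = np.zeros_like(cord2d)
    for dx, dy in ((vr, 0), (-vr, 0), (0, vr), (0, -vr)):
        ix, iy = int(round(cx + dx)), int(round(cy + dy))
        if 0 <= ix < cfg.nx and 0 <= iy < cfg.ny:
            vessel2d[ix, iy] = True
    vessel2d &= tissue2d
    # muscle: lateral tissue bands
    muscle2d = tissue2d.copy()
    muscle2d[:, int(cy) - 6:int(cy) + 7] = False
    # horns: small blobs inside the cord; ventral at smaller y
    horn_off = max(1, int(round(2.0 / vx)))
    horns2d = {}
    for name, (dx, dy) in {
        "left_ventral": (-horn_off, -horn_off),
        "left_dorsal": (-horn_off, horn_off),
        "right_ventral": (horn_off, -horn_off),
        "right_dorsal": (horn_off, horn_off),
    }.items():
        m = np.zeros_like(cord2d)
        ix, iy = int(round(cx + dx)), int(round(cy + dy))
        m[ix - 1:ix + 1, iy - 1:iy + 1] = True
        horns2d[name] = m & cord2d
    out = {"cord": cord2d, "csf": csf2d, "cord_csf": cord2d | csf2d,
           "tissue": tissue2d, "vessel": vessel2d, "muscle": muscle2d}
    out.update(horns2d)
    return out


def _stack(mask2d: np.ndarray, n_slices: int) -> np.ndarray:
    return np.repeat(mask2d[:, :, None], n_slices, axis=2)


def _orthonormal_timecourses(K: int, T: int,
                             rng: np.random.Generator) -> np.ndarray:
    """K smooth, mutually orthogonal, unit-sample-variance timecourses."""
    raw = rng.standard_normal((T, K + 2))
    # mild smoothing gives autocorrelated, physiologically plausible shapes
    kernel = np.array([0.25, 0.5, 0.25])
    for j in range(raw.shape[1]):
        raw[:, j] = np.convolve(raw[:, j], kernel, mode="same")
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    q = q[:, :K]
    q = q / q.std(axis=0, ddof=1)
    return q.T


def simulate_phantom(cfg: PhantomConfig,
                     ) -> tuple[VolumeSeries, dict[str, MaskVolume],
                                PhantomTruth]:
    """Build the phantom run, its masks, and the ground-truth record."""
    nx, ny, ns, T = cfg.nx, cfg.ny, cfg.n_slices, cfg.n_timepoints
    geo = _geometry(cfg)
    masks = {
        name: MaskVolume(_stack(m, ns).astype(np.uint8),
                         cfg.voxel_size_mm)
        for name, m in geo.items()
    }

    slice_times = np.linspace(0, cfg.tr_s, ns, endpoint=False)
    vol_times = np.arange(T) * cfg.tr_s
    duration = T * cfg.tr_s

    data = np.full((nx, ny, ns, T), cfg.baseline, dtype=np.float64)

    # --- planted PCA-recoverable components in the tissue ring ---------
    rng_c = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _TAG_COMPONENTS]))
    rng_m = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _TAG_MAPS]))
    K = cfg.n_components
    comps = (_orthonormal_timecourses(K, T, rng_c) if K else
             np.empty((0, T)))
    comp_maps = np.zeros((K, nx, ny, ns))
    tissue_xy = np.argwhere(geo["tissue"])
    for k in range(K):
        # each component loads on a distinct random subset of the ring,
        # with smoothly varying weights, identically across slices
        n_sup = max(10, tissue_xy.shape[0] // max(K, 1))
        pick = rng_m.choice(tissue_xy.shape[0], size=n_sup, replace=False)
        w2d = np.zeros((nx, ny))
        w2d[tissue_xy[pick, 0], tissue_xy[pick, 1]] = \
            rng_m.uniform(0.5, 1.5, size=n_sup)
        comp_maps[k] = cfg.component_amplitude * w2d[:, :, None]
    for k in range(K):
        data += comp_maps[k][..., None] * comps[k]

    # --- cardiac: order-4 Fourier series of the true phase -------------
    rng_beats = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _TAG_BEATS]))
    beat_times = _event_times(duration, cfg.cardiac_rate_hz,
                              cfg.cardiac_jitter, rng_beats)
    coeffs = np.array([[1.0, 0.5], [0.5, 0.25], [0.25, 0.125],
                       [0.125, 0.0625]])
    card_weight = (geo["csf"].astype(float) +
                   geo["vessel"].astype(float))[:, :, None] * np.ones(ns)
    if cfg.cardiac_amplitude > 0:
        for s in range(ns):
            phi = _phase_from_events(beat_times, vol_times + slice_times[s])
            wave = np.zeros(T)
            for k in range(4):
                wave += (coeffs[k, 0] * np.cos((k + 1) * phi) +
                         coeffs[k, 1] * np.sin((k + 1) * phi))
            data[:, :, s, :] += (cfg.cardiac_amplitude *
                                 card_weight[:, :, s, None] * wave)

    # --- respiratory: slower oscillation in muscle + weak global -------
    rng_breaths = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _TAG_BREATHS]))
    breath_times = _event_times(duration, cfg.resp_rate_hz,
                                cfg.resp_jitter, rng_breaths)
    if cfg.resp_amplitude > 0:
        resp_weight = geo["muscle"].astype(float) + 0.1
        for s in range(ns):
            phi = _phase_from_events(breath_times,
                                     vol_times + slice_times[s])
            wave = np.cos(phi) + 0.3 * np.cos(2 * phi)
            data[:, :, s, :] += (cfg.resp_amplitude *
                                 resp_weight[:, :, None, None] *
                                 wave)[:, :, 0, :]

    # --- drift and motion spikes ---------------------------------------
    if cfg.drift_amplitude > 0:
        u = np.linspace(-1, 1, T)
        drift = 0.7 * u + 0.3 * (1.5 * u ** 2 - 0.5)
        data += cfg.drift_amplitude * drift

    if cfg.spike_amplitude > 0 and cfg.spike_volumes:
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        edge = np.hypot(xx - cx, yy - cy)
        edge /= edge.max()
        for t0 in cfg.spike_volumes:
            data[:, :, :, t0] += (cfg.spike_amplitude *
                                  edge[:, :, None])

    # --- task -----------------------------------------------------------
    task = np.zeros(T)
    task_betas = np.zeros((nx, ny, ns))
    if cfg.task_amplitude > 0 and cfg.task_block_s > 0:
        cycle = cfg.task_block_s + cfg.task_rest_s
        task = ((vol_times % cycle) < cfg.task_block_s).astype(float)
        task_2d = geo["left_ventral"] | geo["right_ventral"]
        if not (task_2d & geo["cord"]).any():
            raise ValueError("task voxels fall outside the cord")
        task_betas = (cfg.task_amplitude *
                      _stack(task_2d, ns).astype(float))
        data += task_betas[..., None] * task
    if cfg.task_correlated_noise_amplitude > 0 and task.any():
        w2d = geo["tissue"].astype(float)
        data += (cfg.task_correlated_noise_amplitude *
                 w2d[:, :, None, None] * (task - task.mean()))

    # --- thermal noise ---------------------------------------------------
    rng_n = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _TAG_THERMAL]))
    if cfg.thermal_sd > 0:
        data += cfg.thermal_sd * rng_n.standard_normal(data.shape)

    vol = VolumeSeries(data=data, voxel_size_mm=cfg.voxel_size_mm,
                       tr_s=cfg.tr_s, slice_times_s=slice_times)
    comp_var = comp_maps ** 2 * (comps.var(axis=1, ddof=1)[:, None, None,
                                                           None]
                                 if K else 1.0)
    truth = PhantomTruth(
        component_timecourses=comps,
        component_maps=comp_maps,
        component_variance=comp_var if K else np.zeros((0, nx, ny, ns)),
        task_regressor=task,
        task_betas=task_betas,
        beat_times=beat_times,
        breath_times=breath_times,
        cardiac_fourier_coeffs=coeffs,
        thermal_sd=cfg.thermal_sd,
        masks=masks,
    )
    return vol, masks, truth


def simulate_physio(duration_s: float, fs_hz: float = 100.0,
                    hr_bpm: float = 60.0, rr_bpm: float = 15.0,
                    jitter: float = 0.03, seed: int = 0,
                    ) -> tuple[PhysioTrace, PhysioTrace, dict]:
    """Pulse and respiratory-belt traces with recorded true event times.

    Sharing ``seed`` (and rates/jitter) with :func:`simulate_phantom`
    reproduces the phantom's beat and breath times exactly, so
    peak-detection and RETROICOR can be validated against the phantom's
    injected contamination.
    """
    if fs_hz < 20:
        raise ValueError("fs_hz must be at least 20 Hz")
    rng_beats = np.random.default_rng(
        np.random.SeedSequence([seed, _TAG_BEATS]))
    rng_breaths = np.random.default_rng(
        np.random.SeedSequence([seed, _TAG_BREATHS]))
    beat_times = _event_times(duration_s, hr_bpm / 60.0, jitter, rng_beats)
    breath_times = _event_times(duration_s, rr_bpm / 60.0, jitter,
                                rng_breaths)
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    # pulse: narrow bump at each beat over a flat baseline
    pulse = np.zeros_like(t)
    width = 0.06 * 60.0 / hr_bpm
    for bt in beat_times:
        pulse += np.exp(-0.5 * ((t - bt) / width) ** 2)
    # belt: smooth oscillation peaking at each breath time
    phi = _phase_from_events(breath_times, t)
    belt = np.cos(phi) + 0.2 * np.cos(2 * phi)
    truth = {
        "beat_times": beat_times[(beat_times >= 0)
                                 & (beat_times < duration_s)],
        "breath_times": breath_times[(breath_times >= 0)
                                     & (breath_times < duration_s)],
    }
    return (PhysioTrace(pulse, fs_hz, 0.0, "pulse"),
            PhysioTrace(belt, fs_hz, 0.0, "respiratory"),
            truth)


def simulate_connectivity_phantom(n_slices: int = 6, T: int = 434,
                                  r_vv: float = 0.6,
                                  voxel_noise_sd: float = 0.05,
                                  seed: int = 0,
                                  ) -> tuple[VolumeSeries,
                                             dict[str, MaskVolume]]:
    """Residual-like volume with a planted ventral-ventral correlation.

    The two ventral horns receive signals built as
    sqrt(r)*g + sqrt(1-r)*e with a shared g, so their population
    correlation is exactly ``r_vv``; dorsal horns get independent
    noise. Voxel-level thermal noise is kept small so horn-mean series
    preserve the planted correlation.
    """
    if not 0 <= r_vv < 1:
        raise ValueError("r_vv must be in [0, 1)")
    cfg = PhantomConfig(n_slices=n_slices, n_timepoints=T, seed=seed,
                        n_components=0, thermal_sd=0.0)
    geo = _geometry(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    data = np.zeros((cfg.nx, cfg.ny, n_slices, T))
    horn_masks = {}
    for s in range(n_slices):
        g = rng.standard_normal(T)
        sig = {
            "left_ventral": np.sqrt(r_vv) * g +
            np.sqrt(1 - r_vv) * rng.standard_normal(T),
            "right_ventral": np.sqrt(r_vv) * g +
            np.sqrt(1 - r_vv) * rng.standard_normal(T),
            "left_dorsal": rng.standard_normal(T),
            "right_dorsal": rng.standard_normal(T),
        }
        for name, ts in sig.items():
            xy = np.argwhere(geo[name])
            for x, y in xy:
                data[x, y, s, :] = ts + voxel_noise_sd * \
                    rng.standard_normal(T)
    for name in ("left_ventral", "left_dorsal", "right_ventral",
                 "right_dorsal"):
        horn_masks[name] = MaskVolume(
            _stack(geo[name], n_slices).astype(np.uint8),
            cfg.voxel_size_mm)
    vol = VolumeSeries(data=data, voxel_size_mm=cfg.voxel_size_mm,
                       tr_s=cfg.tr_s)
    return vol, horn_masks
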