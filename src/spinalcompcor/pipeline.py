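"""End-to-end pipeline: noise ROI -> PCA -> parallel analysis -> designs
-> GLMs -> evaluation, driven by one configuration with one seed.

The component count for modeling can be fixed or "auto"; auto runs the
parallel analysis on the full (untruncated) series before selecting the
number of component regressors, while the reported parallel-analysis
summary itself is computed on series truncated to a common length so
scan duration does not influence the cutoff comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, glm as glm_mod
from .core import (MaskVolume, RegressorTable, VolumeSeries, binarize_mask,
                   read_mask, read_physio, read_regressors, read_volume,
                   write_mask)
from .noise_roi import NoiseRoiSpec, build_noise_roi
from .nuisance import (RetroicorBasis, assemble_design, csf_regressor,
                       detect_peaks)
from .parallel_analysis import run_parallel_analysis
from .phantom import PhantomConfig, simulate_phantom, simulate_physio
from .slice_pca import extract_slice_matrix, pc_regressors, slice_pca

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("spinalcompcor")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``phantom`` is set (inputs are simulated) or the ``*_path``
    fields point at NIfTI/TSV inputs on a shared grid.
    """

    out_dir: str = "spinalcompcor_out"
    phantom: PhantomConfig | None = None
    func_path: str | None = None
    cord_csf_mask_path: str | None = None
    cord_mask_path: str | None = None
    csf_mask_path: str | None = None
    pulse_path: str | None = None
    resp_path: str | None = None
    physio_fs_hz: float | None = None
    motion_path: str | None = None
    task_path: str | None = None

    noise_roi: NoiseRoiSpec = field(default_factory=NoiseRoiSpec)
    n_per_voxel: int = 50
    n_matrices: int = 500
    truncate_to: int | None = 160
    models: tuple[str, ...] = ("base", "extended", "spinalcompcor")
    k: int | str = "auto"
    alpha: float = 0.05
    hp_cutoff_s: float = 100.0
    retro_order: int = 4
    seed: int = 0
    write_volumes: bool = False

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model must be requested")
        if self.k == "auto" and self.n_matrices < 1:
            raise ValueError("k='auto' requires the parallel analysis")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.phantom is not None:
        vol, masks, truth = simulate_phantom(cfg.phantom)
        pulse, resp, _ = simulate_physio(
            duration_s=vol.n_timepoints * vol.tr_s,
            hr_bpm=cfg.phantom.cardiac_rate_hz * 60.0,
            rr_bpm=cfg.phantom.resp_rate_hz * 60.0,
            jitter=cfg.phantom.cardiac_jitter,
            seed=cfg.phantom.seed)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 41]))
        moco = np.cumsum(0.02 * rng.standard_normal((vol.n_timepoints, 2)),
                         axis=0)
        motion = RegressorTable(
            pd.DataFrame({"moco_x": moco[:, 0], "moco_y": moco[:, 1]}),
            {"moco_x": "motion", "moco_y": "motion"})
        if truth.task_regressor.any():
            task = RegressorTable(
                pd.DataFrame({"task": truth.task_regressor}),
                {"task": "task"})
        else:
            task = RegressorTable()
        return vol, masks, pulse, resp, motion, task, truth
    vol = read_volume(cfg.func_path)
    masks = {
        "cord_csf": read_mask(cfg.cord_csf_mask_path),
        "cord": read_mask(cfg.cord_mask_path),
        "csf": read_mask(cfg.csf_mask_path),
    }
    fs = cfg.physio_fs_hz
    if fs is None:
        raise ValueError("physio_fs_hz is required for recorded traces")
    pulse = read_physio(cfg.pulse_path, fs, "pulse")
    resp = read_physio(cfg.resp_path, fs, "respiratory")
    motion = read_regressors(cfg.motion_path, group="motion")
    task = (read_regressors(cfg.task_path, group="task")
            if cfg.task_path else RegressorTable())
    return vol, masks, pulse, resp, motion, task, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write a JSON manifest; returns the manifest."""
    t_start = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "metrics": {}, "seed": cfg.seed}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = {"order": len(manifest["stages"])}
        return manifest["stages"][name]

    # ---- inputs --------------------------------------------------------
    st = stage("inputs")
    vol, masks, pulse, resp, motion, task, truth = _load_inputs(cfg)
    st["T"] = vol.n_timepoints
    st["shape"] = list(vol.shape)
    st["func_sha"] = _hash_array(vol.data)

    # ---- noise ROI -----------------------------------------------------
    st = stage("noise_roi")
    roi = build_noise_roi(masks["cord_csf"], cfg.noise_roi)
    st["n_voxels"] = roi.count()
    st["sha"] = _hash_array(roi.data)
    if cfg.write_volumes:
        write_mask(roi, out / "noise_roi.nii")
        st["path"] = "noise_roi.nii"

    # ---- parallel analysis --------------------------------------------
    st = stage("parallel_analysis")
    pa_trunc = run_parallel_analysis(
        vol, roi, n_per_voxel=cfg.n_per_voxel, n_matrices=cfg.n_matrices,
        truncate_to=(min(cfg.truncate_to, vol.n_timepoints)
                     if cfg.truncate_to else None),
        base_seed=cfg.seed)
    st["per_slice_cutoffs"] = {str(s): c for s, c
                               in pa_trunc.cutoffs().items()}
    st["median_cutoff"] = pa_trunc.median_cutoff
    if cfg.k == "auto":
        need_full = (cfg.truncate_to is not None
                     and cfg.truncate_to < vol.n_timepoints)
        if need_full:
            pa_full = run_parallel_analysis(
                vol, roi, n_per_voxel=cfg.n_per_voxel,
                n_matrices=cfg.n_matrices, truncate_to=None,
                base_seed=cfg.seed)
        else:
            pa_full = pa_trunc
        k = pa_full.median_cutoff
        st["median_cutoff_full"] = pa_full.median_cutoff
    else:
        k = int(cfg.k)
    k = max(k, 1)
    manifest["metrics"]["k_selected"] = k

    # ---- slice-wise regressors ----------------------------------------
    st = stage("regressors")
    cardiac_peaks = detect_peaks(pulse, min_interval_s=0.4)
    retro = RetroicorBasis.from_traces(vol, cardiac_peaks, resp,
                                       order=cfg.retro_order)
    pca_by_slice: dict[int, RegressorTable] = {}
    csf_by_slice: dict[int, RegressorTable] = {}
    usable = []
    for s in range(vol.n_slices):
        try:
            matrix = extract_slice_matrix(vol, roi, s)
        except Exception:
            continue
        pc = slice_pca(matrix)
        pca_by_slice[s] = pc_regressors(pc, min(k, pc.n_components))
        csf_by_slice[s] = csf_regressor(vol, masks["csf"], s)
        usable.append(s)
    st["usable_slices"] = usable
    st["n_cardiac_peaks"] = int(cardiac_peaks.size)

    # ---- designs and GLMs ---------------------------------------------
    cord = masks["cord"]
    cord_usable = MaskVolume(
        np.where(np.isin(np.arange(cord.shape[2]), usable)[None, None, :],
                 cord.data, False).astype(np.uint8),
        cord.voxel_size_mm)
    glms: dict[str, glm_mod.GLMResult] = {}
    for kind in cfg.models:
        st = stage(f"glm_{kind}")
        designs = {}
        for s in usable:
            designs[s] = assemble_design(
                task=task, motion=motion, csf=csf_by_slice[s],
                retro=retro.for_slice(s), pca=pca_by_slice[s],
                model_kind=kind, slice_index=s)
        glms[kind] = glm_mod.fit_glm(vol, designs, cord_usable,
                                     hp_cutoff_s=cfg.hp_cutoff_s)
        st["nuisance_count"] = designs[usable[0]].nuisance_count
        st["design_rank"] = glms[kind].design_rank
        st["rss_sha"] = _hash_array(glms[kind].rss)
        manifest["metrics"][f"nuisance_count_{kind}"] = \
            designs[usable[0]].nuisance_count

    # ---- evaluation ----------------------------------------------------
    st = stage("evaluation")
    mean_map = vol.data.mean(axis=3)
    sig_masks: dict[str, MaskVolume] = {}
    for kind, g in glms.items():
        ts = evaluation.tsnr(g, mean_map)
        manifest["metrics"][f"tsnr_mean_{kind}"] = ts.mean_tsnr()
        if cfg.write_volumes:
            from .core import write_map
            write_map(ts.to_map(), cord, out / f"tsnr_{kind}.nii")

    if "base" in glms and "extended" in glms:
        nested = glm_mod.nested_f_test(glms["extended"], glms["base"])
        prop, med_f = glm_mod.significant_proportion(nested, cord_usable,
                                                     cfg.alpha)
        manifest["metrics"]["nested_prop_significant"] = prop
        manifest["metrics"]["nested_median_F"] = med_f
        manifest["metrics"]["nested_df"] = [nested.df_num, nested.df_den]
    if "base" in glms:
        omni_retro = glm_mod.omnibus_f_test(glms["base"], "retro")
        sig_masks["base"] = binarize_mask(
            np.nan_to_num(omni_retro.to_map("F")) *
            (omni_retro.to_map("p", fill=1.0) < cfg.alpha),
            threshold=0.0, voxel_size_mm=cord.voxel_size_mm)
    if "spinalcompcor" in glms:
        omni_pca = glm_mod.omnibus_f_test(glms["spinalcompcor"], "pca")
        sig_masks["spinalcompcor"] = binarize_mask(
            np.nan_to_num(omni_pca.to_map("F")) *
            (omni_pca.to_map("p", fill=1.0) < cfg.alpha),
            threshold=0.0, voxel_size_mm=cord.voxel_size_mm)
    if "base" in glms and "spinalcompcor" in glms:
        manifest["metrics"]["retro_vs_pca_spearman"] = \
            evaluation.spatial_spearman(omni_retro.to_map("z"),
                                        omni_pca.to_map("z"), cord_usable)
        manifest["metrics"]["retro_vs_pca_dice"] = evaluation.dice(
            sig_masks["base"], sig_masks["spinalcompcor"])
        change = evaluation.activation_change(
            sig_masks["base"], sig_masks["spinalcompcor"], cord_usable)
        manifest["metrics"]["activation_change"] = change

    horn_names = ("left_ventral", "left_dorsal", "right_ventral",
                  "right_dorsal")
    if truth is not None and all(h in masks for h in horn_names):
        ref = glms.get("extended") or next(iter(glms.values()))
        resid_vol = VolumeSeries(
            data=_residual_volume(ref),
            voxel_size_mm=vol.voxel_size_mm, tr_s=vol.tr_s)
        try:
            conn = evaluation.seed_connectivity(
                resid_vol, {h: masks[h] for h in horn_names})
            manifest["metrics"]["connectivity_mean_z"] = conn.class_mean_z
        except ValueError:
            manifest["metrics"]["connectivity_mean_z"] = None

    # wall time is logged, not stored: the manifest must be byte-identical
    # across reruns with the same config and seed
    log.info("pipeline finished in %.2fs", time.perf_counter() - t_start)
    manifest["content_sha"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _residual_volume(g: glm_mod.GLMResult) -> np.ndarray:
    out = np.zeros(g.mask.shape + (g.n_timepoints,))
    out[g.coords[:, 0], g.coords[:, 1], g.coords[:, 2], :] = g.residuals
    return out
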