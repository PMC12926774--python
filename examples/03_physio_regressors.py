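"""Build recording-based nuisance regressors and assemble the three
model designs.

RETROICOR expands cardiac and respiratory phase into low-order Fourier
regressors (order 4: 8 cardiac + 8 respiratory columns), evaluated at
each slice's acquisition times. A slice-wise CSF regressor averages the
top-20%-variance CSF voxels. With 2 motion columns that makes the
19-nuisance-regressor Base design; Extended adds the PCA components;
the SpinalCompCor design replaces RETROICOR with PCA components.
"""

import numpy as np
import pandas as pd

from spinalcompcor import (PhantomConfig, RegressorTable, assemble_design,
                           csf_regressor, detect_peaks, simulate_phantom,
                           simulate_physio)
from spinalcompcor.nuisance import RetroicorBasis
from spinalcompcor.slice_pca import pc_regressors, slice_pca, \
    extract_slice_matrix
from spinalcompcor import build_noise_roi

cfg = PhantomConfig(n_components=3, cardiac_amplitude=1.0, seed=3)
vol, masks, truth = simulate_phantom(cfg)
pulse, belt, ptruth = simulate_physio(
    duration_s=vol.n_timepoints * vol.tr_s,
    hr_bpm=cfg.cardiac_rate_hz * 60, rr_bpm=cfg.resp_rate_hz * 60,
    jitter=cfg.cardiac_jitter, seed=cfg.seed)

peaks = detect_peaks(pulse, min_interval_s=0.4)
print(f"detected {peaks.size} cardiac peaks "
      f"({len(ptruth['beat_times'])} true beats)")

retro = RetroicorBasis.from_traces(vol, peaks, belt, order=4)
retro_slice0 = retro.for_slice(0)
print(f"RETROICOR slice 0: {len(retro_slice0)} columns "
      f"({retro_slice0.names[:2]} ... {retro_slice0.names[-2:]})")

csf = csf_regressor(vol, masks["csf"], slice_index=0)
print(f"CSF regressor: {len(csf)} column from top-20%-variance voxels")

roi = build_noise_roi(masks["cord_csf"])
pc = slice_pca(extract_slice_matrix(vol, roi, 0))
pca_regs = pc_regressors(pc, 3)

rng = np.random.default_rng(0)
motion = RegressorTable(
    pd.DataFrame({"mx": rng.standard_normal(vol.n_timepoints),
                  "my": rng.standard_normal(vol.n_timepoints)}),
    {"mx": "motion", "my": "motion"})
task = RegressorTable()

for kind in ("base", "extended", "spinalcompcor"):
    d = assemble_design(task, motion, csf,
                        retro_slice0 if kind != "spinalcompcor" else None,
                        pca_regs if kind != "base" else None, kind)
    print(f"{kind:14s}: {d.nuisance_count} nuisance regressors")
# base = 2 motion + 1 CSF + 16 RETROICOR = 19; extended = 19 + k;
# spinalcompcor = 3 + k (no recording-based physiological columns)
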