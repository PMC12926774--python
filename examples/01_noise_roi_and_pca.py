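"""Build a noise ROI around a simulated cord and inspect its principal
components.

The noise ROI is the ring of tissue obtained by dilating the cord/CSF
mask 18 mm in-plane, subtracting the mask, and trimming 3 voxels at the
field-of-view edge. Slice-wise PCA of its voxel timeseries yields
candidate nuisance regressors; planted components should dominate the
eigenvalue spectrum.
"""

import numpy as np

from spinalcompcor import (PhantomConfig, build_noise_roi,
                           extract_slice_matrix, pc_regressors,
                           simulate_phantom, slice_pca)

cfg = PhantomConfig(n_components=3, seed=42)
vol, masks, truth = simulate_phantom(cfg)
print(f"phantom: grid {vol.shape}, TR {vol.tr_s}s, "
      f"{cfg.n_components} planted noise components")

roi = build_noise_roi(masks["cord_csf"])
print(f"noise ROI: {roi.count()} voxels, "
      f"disjoint from cord/CSF: {not (roi.data & masks['cord_csf'].data).any()}")

matrix = extract_slice_matrix(vol, roi, slice_index=0)
pc = slice_pca(matrix)
print(f"slice 0 matrix: {matrix.T} timepoints x {matrix.V} voxels "
      f"-> {pc.n_components} components")
print("leading eigenvalues:", np.round(pc.eigenvalues[:6], 1))
print("explained variance ratio:",
      np.round(pc.explained_variance_ratio()[:6], 3))
# the first 3 eigenvalues stand far above the thermal bulk: those are
# the planted components; the rest is the noise floor
regs = pc_regressors(pc, 3)
print(f"regressor table: columns {regs.names}, "
      f"unit variance: {np.allclose(regs.values().var(axis=0, ddof=1), 1)}")
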