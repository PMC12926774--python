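# Methods

This note documents the models and numerical choices behind
`spinalcompcor`, the assumptions they rest on, and what the synthetic
phantom does and does not establish about real data.

## Noise ROI

The noise ROI is constructed slice-wise: the cord/CSF mask is dilated
in-plane and subtracted, and a fixed-width in-plane border is trimmed.

* `dilation_mm` (default 18): physical dilation radius, rounded to the
  nearest whole voxel independently per in-plane axis. Under
  anisotropic voxels this gives an elliptical footprint, tested with
  squared voxel-normalised distance <= 1. The default reaches the
  approximate image boundary of a reduced-FOV cervical acquisition.
* `edge_trim_voxels` (default 3): removes edge voxels whose timeseries
  are corrupted by FOV truncation effects. The trim is a fixed border
  on both in-plane axes.
* Dilation is strictly 2D. The processing model is slice-wise
  throughout (regressors, PCA, GLM designs), slices are thick
  (3–5 mm) relative to in-plane voxels, and a per-slice ROI keeps each
  slice's regressors local to its own tissue; a 3D dilation would only
  blur that locality.

## Slice-wise PCA

ROI voxel timeseries form a T x V matrix (columns ordered
lexicographically by (x, y); zero-variance voxels dropped). Columns are
mean-centered but not variance-scaled — the components should weight
high-variance (i.e. noisier) voxels more, which is the behaviour wanted
from a noise model. SVD of the centered matrix yields
N = min(T-1, V) components with eigenvalues s_i^2/(T-1). Component
signs are pinned by making each component's largest-magnitude loading
positive, so results are platform-independent. Regressors are the score
timeseries normalised to unit sample variance; normalisation only
conditions the design matrix and cannot change fitted models.

## IAAFT surrogates

Surrogates preserve a voxel's amplitude distribution exactly and its
power spectrum approximately while randomising phase, which makes them
an appropriate null for "how large an eigenvalue arises by chance from
voxels with these spectra". Starting from a random permutation of the
template, each iteration (a) imposes the template's Fourier amplitudes
on the current surrogate (keeping current phases; the zero-frequency
term is copied from the template), then (b) rank-order remaps values
onto the template's sorted values. Iteration stops when the rank
ordering stops changing — a true fixed point of the map — or after 500
iterations; typical convergence at T = 160 is 10–30 iterations. Ending
on the amplitude step makes the value multiset exact.

Two accuracy regimes matter. The mean amplitude spectrum of a
50-surrogate ensemble matches the template to well under 2% RMS
relative error; this ensemble accuracy is what the mean surrogate
eigencurve inherits. A single surrogate carries irreducible scatter
from the final rank remap (~2% for strongly autocorrelated templates),
which averages out across surrogates and matrices.

Each surrogate's random initialisation comes from a dedicated
`SeedSequence([base_seed, slice, voxel, replicate])` substream, so
results are independent of execution order and the vectorised batch
path is bit-identical to scalar calls.

## Parallel analysis

Surrogate matrices draw, per voxel independently, one of its surrogates
uniformly with replacement. The slice cutoff is the prefix rule: the
count of leading components whose template eigenvalue strictly exceeds
the mean surrogate eigenvalue, stopping at the first violation —
crossings beyond the first are ignored, which makes the "scree
intersection" deterministic. The run summary is the median cutoff
across slices, rounded half-up when half-integral. Truncation (when
comparing runs of different lengths) takes the initial contiguous
segment.

Defaults are 50 surrogates per voxel and 500 surrogate matrices. Tests
and the acceptance script use 10–20 surrogates per voxel and 20–100
matrices on 300-voxel single-slice problems; at the planted
signal-to-noise ratios exercised there the cutoff estimate is already
stable at those sizes, which keeps the default suite in minutes.

## Nuisance regressors and designs

* Peak detection: local maxima above the trace's rolling median with a
  refractory period (0.4 s cardiac, 1.5 s respiratory). The original
  peak-detection procedure for such traces is a matter of lab
  convention; this one is deterministic and validated against
  simulated traces with known event times.
* Cardiac phase: linear 0..2*pi between consecutive beats; outside the
  detected span the nearest interval's rate is extrapolated.
* Respiratory phase: amplitude-histogram equalisation (100 bins)
  signed by the belt derivative, in [-pi, pi].
* RETROICOR: cos/sin of k x phase for k = 1..4, per slice, evaluated
  at volume onset + slice offset — genuinely slice-timed columns.
* CSF regressor: mean of the ceil(0.2 x count) highest-temporal-
  variance CSF voxels on the slice, variance computed on the input
  series before filtering.
* Designs: Base = task + motion + CSF + RETROICOR; Extended = Base +
  PCA; SpinalCompCor = task + motion + CSF + PCA. Nuisance columns are
  demeaned at assembly; nuisance counts exclude task columns. Motion
  regressors are consumed as-is (two in-plane translation columns, no
  derivatives or expansions).

## GLM and inference

A discrete-cosine basis spanning periods >= 100 s (plus the constant)
is projected out of both the data and the regressors — the identical
operator on both sides, so the fit equals an unfiltered fit with the
basis as confounds, and residual dof = T − design rank − basis size.
Fits are ordinary least squares per slice inside the cord mask. OLS is
exact for the white-thermal-noise phantom used throughout the tests; a
single-lag AR(1) Cochrane–Orcutt option approximates full
autocorrelation prewhitening for real data and is documented as
approximate.

Nested F: F = ((RSS_r − RSS_f)/df_num)/(RSS_f/df_den) with df_num the
rank added by the extra columns. Omnibus tests drop a whole regressor
group and are computed as the equivalent nested test. p-values come
from the F survival function; z-maps use the one-sided upper tail,
evaluated in log space (`ndtri_exp`) so large F never overflow to
infinite z.

## Evaluation metrics

tSNR adds the functional mean back to residuals and divides mean by
standard deviation (n−1 denominator; zero-variance voxels are flagged,
not valued). Dice is 2|A∩B|/(|A|+|B|), defined as 1 for two empty
masks. Spearman correlations average ranks on ties. Connectivity uses
full Pearson correlation of horn-mean timeseries per slice, Fisher
z-transformed with |r| clipped at 1 − 1e−7; pair classes are V–V
(LV↔RV), D–D (LD↔RD), V–D within (LV↔LD, RV↔RD averaged) and V–D
between (LV↔RD, RV↔LD averaged); slices missing a horn are skipped,
not zero-filled.

## The phantom

`simulate_phantom` builds a concentric cord/CSF/tissue geometry
(default 32 x 32 x 6 x 160 at 1 x 1 x 3 mm, TR 2 s — simulates in
seconds) with:

* K planted, mutually orthogonal, smoothly autocorrelated component
  timecourses with disjointly supported spatial maps in the tissue
  ring — the PCA-recoverable ground truth;
* cardiac contamination as an order-4 Fourier series of the true
  cardiac phase (quasi-periodic, jittered beats), concentrated in CSF
  and vessel voxels and sampled at slice-acquisition times. A 1 Hz
  cardiac rate sampled at TR 2 s aliases deliberately, matching the
  regime of long-TR acquisitions;
* slower respiratory oscillation (muscle-weighted plus a weak global
  part), polynomial drift, edge-weighted motion spikes, white thermal
  noise, and an optional ventral-horn block task.

Matching pulse/belt traces are generated from the same event-time
substreams, so detect-peaks -> RETROICOR can be validated against the
injected contamination. The truth record carries all timecourses,
maps, per-voxel planted variance, beat/breath times and masks.

What the phantom does **not** emulate: EPI distortion and B0 effects,
non-white (autocorrelated) thermal noise, partial-volume mixtures,
motion as actual spatial displacement (spikes are intensity offsets),
and subject-to-subject anatomical variability. Passing tests therefore
establish the correctness and calibration of the algorithms under
their stated assumptions, not performance on real cord data.

`simulate_connectivity_phantom` plants an exact population correlation
r between the two ventral horns (sqrt(r) shared + sqrt(1-r) private
signal) with small voxel noise, for connectivity-recovery checks.

## Pipeline

`run_pipeline` executes all stages from one config with one seed; all
randomness flows through named `SeedSequence` substreams, outputs are
content-hashed, and the manifest contains no timestamps, so a rerun
with the same config and seed is byte-identical. With `k="auto"` the
component count for modeling comes from a parallel analysis of the
full-length series, while the reported parallel-analysis summary uses
the truncated series (so length does not bias cross-run comparisons).

## Known limitations

* The scree intersection uses the integer prefix rule; no
  interpolation between component indices.
* FILM-style locally regularised prewhitening is not replicated; the
  AR(1) option is a one-parameter approximation.
* The noise-ROI edge trim is a fixed border, not limited to sides
  where a reduced FOV abuts the image boundary.
* CLI subcommands cover simulation, ROI, PCA, parallel analysis and
  the full pipeline; design/GLM/evaluation stages are reached through
  `run` or the Python API.
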