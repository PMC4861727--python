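# Methods

This note documents the models, parameter choices and numerical conventions
behind `voxdc`, and what validation on synthetic cohorts does and does not
establish about real data.

## Synthetic signal model

The generator produces BOLD-like data whose degree-centrality (DC)
structure is analytically controllable:

```
y_v(t) = Σ_k L[v,k] · s_k(t)  +  d_v · trend(t)  +  c · w_v · a(t)  +  ε_v(t)
```

- `s_k` are `n_latents` (default 6) independent **latent network time
  courses**, generated by placing random complex coefficients only in
  Fourier bins inside 0.01–0.08 Hz, so they are exactly band-limited (the
  band the pipeline's filter retains).
- Each in-mask voxel belongs to one community and loads (default 0.9) on
  that community's latent. Within-community correlations are strong
  (~0.75 at the default noise level); between-community correlations are
  near zero.
- A fraction (default 2%) of voxels are **hubs**: each hub loads on its own
  random *half* of the latents with total gain 1.8. Hubs therefore show
  supra-threshold (r > 0.25) correlations with several communities and get
  elevated DC. Hubs deliberately do *not* load on all latents: a voxel
  loading uniformly on every latent is nearly proportional to the global
  mean signal, and global-signal regression in preprocessing would erase
  it — an instructive failure mode the default configuration avoids.
- **Group effect**: patient-like (group B) subjects have the community
  loadings inside a configured spherical region scaled by a multiplier
  (default 0.5). Scaling loadings relative to noise lowers within-community
  correlations there (~0.76 → ~0.59), suppressing regional weighted DC.
- **Clinical score**: each subject receives a lognormal loading gain
  (sd 0.25 on the log scale) in a separate score region, and
  `score = 36 − 20·(gain − 1) + N(0, 2)`, clamped to the 0–48 scale used
  by ALS functional rating. Higher regional centrality thus accompanies a
  lower (more severe) score: the planted correlation between regional DC
  z-scores and the score is negative by construction.
- **Motion** is a mean-reverting random walk (AR(1), ρ = 0.95) with
  per-step amplitude 0.05 mm (rotations 0.6°/mm of that), giving realistic
  sub-exclusion excursions; a motion-derivative-coupled spatial artifact
  (coupling 0.2) and per-voxel linear drift (sd 0.3) complete the nuisance
  structure.

What the generator does **not** emulate: scanner physics (k-space,
susceptibility), physiological (cardiac/respiratory) noise, spatial
autocorrelation of the noise floor, anatomical tissue geometry, or
registration error. Passing recovery tests therefore demonstrates the
*statistical machinery* — preprocessing, DC mapping, cluster inference,
partial correlation — is correct and calibrated, not that effect sizes in
real cohorts match the defaults here.

## Preprocessing conventions

- Stage order is fixed: discard (default 10 volumes) → motion QC and
  framewise displacement → nuisance regression → band-pass. All temporal
  operations run on the post-discard grid (230 volumes at defaults).
- Motion exclusion uses **strict** inequalities (> 1.5 mm, > 1.5°) on the
  raw per-volume parameters; boundary values are retained.
- Jenkinson FD integrates rotation over an 80 mm sphere:
  `FD(t) = sqrt(R²/5 · tr(ΔAᵀΔA) + Δbᵀ Δb)` for the relative transform
  `T_t T_{t-1}^{-1}`; rotations compose as `Rx·Ry·Rz` and are stored in
  degrees in TSVs (matching the degree-valued exclusion criterion),
  converted internally.
- The Friston 24-parameter expansion orders columns `[p, p(t−1), p²,
  p(t−1)²]` with the first lagged row zero-padded (no wraparound).
- The nuisance design has 30 columns: intercept + 24 motion + WM + CSF +
  global mean + linear + quadratic trend. Mean FD is a per-subject scalar
  — constant within a subject's time series — so it is absorbed by the
  intercept at subject level and carried in the QC record as a group-level
  covariate instead. WM/CSF/global regression happens **simultaneously**
  in one multiple regression. OLS uses the Moore–Penrose pseudo-inverse so
  collinear columns degrade gracefully.
- On synthetic data, which has no genuine tissue compartments, the WM and
  CSF series are proxies: means over the 0.10–0.20 and 0.02–0.10 shells of
  the gray-matter probability taper.
- The band-pass is an **ideal frequency-domain boxcar** (bins outside
  [0.01, 0.08] Hz zeroed, DC bin always zeroed): exactly idempotent,
  exactly energy-preserving on retained bins, and matching the behavior of
  the resting-state toolkits this pipeline family descends from, rather
  than an FIR/IIR approximation.

## Degree centrality conventions

- Gray-matter mask: probability **strictly greater** than 0.20.
- Connections are **positive-side only**: r > 0.25 strictly; negative
  correlations never count. Weights are raw r values (no Fisher z).
- Zero-variance voxels are dropped from the mask with a warning instead of
  propagating NaN correlations.
- The correlation is computed blockwise (default 2048 voxels per block):
  memory stays O(block × n) and the result is bit-identical to the full
  matrix computation (tested against a brute-force oracle).
- z-standardization uses the population (divide-by-n) standard deviation;
  a `ddof=1` switch exists, with sub-0.1% impact at realistic mask sizes.
- Smoothing (4 mm FWHM, σ = FWHM/(2√(2 ln 2))) is applied after
  z-scoring, over the whole grid with zero boundary after zeroing
  out-of-mask values — the standard volumetric-toolkit behavior; the
  kernel is truncated at 4σ.

## Cluster-extent inference

- The null simulation draws standard Gaussian fields on the analysis grid,
  smooths them with the stated FWHM using **periodic** convolution (keeps
  the field stationary to the grid edge), and restandardizes to zero mean
  and unit variance — without restandardization, smoothing deflates the
  variance and the voxel-p threshold would be miscalibrated.
- Thresholding of the simulated field is **one-sided** at Φ⁻¹(1 − p) by
  default, the construction used by the AFNI AlphaSim program whose
  threshold conventions this reproduces; with 10,000 iterations on the
  61×73×61 / 3 mm / 4 mm-FWHM configuration this yields an extent
  threshold of 17–18 voxels at voxel p = 0.01, cluster α = 0.01. A
  `two_sided` flag thresholds at |z| ≥ Φ⁻¹(1 − p/2) and takes the
  per-iteration maximum over both sign sets (yielding ~13 voxels on the
  same configuration — the two conventions genuinely differ, and the
  one-sided null is the published-threshold-compatible default).
- The real t-map is always thresholded **two-sidedly** at its own t
  quantile (|t| ≥ t₁₋p/₂,df), with positive and negative suprathreshold
  sets clustered separately — group differences in either direction are
  reported.
- rmm = 5 mm adjacency on a 3 mm grid gives 18-connectivity (6 faces +
  12 edges; corners at 5.196 mm excluded). Cluster labels are ordered by
  descending size, ties by smallest raster index; peaks are the max-|t|
  voxel, ties again by raster index.
- A documented inconsistency in the published parameterization this
  follows: an extent of 18 voxels at 27 mm³/voxel is 486 mm³, not the
  405 mm³ (= 15 voxels) sometimes quoted alongside it. The voxel count
  (18) is treated as primary; the cluster table reports
  `volume = extent × voxel volume`.
- Group t-tests use the equal-variance pooled statistic by default (the
  resting-state-toolkit convention), with a Welch switch.
- Partial correlation residualizes both variables on [intercept,
  covariates] and tests the residual Pearson r against t with
  df = n − n_covariates − 2.

## Problem sizes in the shipped validation

Chosen as the package's own desk-scale defaults: unit tests run on
12–18-voxel-per-side grids; the planted-effect recovery study uses 20
cohorts of 15+15 subjects on an 18×22×18 grid (≈2200-voxel mask, full 240
volumes at TR 2 s) with a 500-iteration shared null; the extent-threshold
reproduction uses the full 61×73×61 grid at 1000 iterations in the test
suite and 10,000 iterations in the acceptance script; family-wise error is
measured on a 30×36×30 grid with 300 independent null replicates.

## Known limitations

- The AlphaSim-style null assumes Gaussian smoothness equal to the applied
  kernel; it does not estimate smoothness from residuals.
- The null simulation runs unmasked on the full rectangular grid by
  default (a `mask` argument exists); masked simulation yields smaller
  search volumes and smaller thresholds.
- No voxel-wise covariate GLM beyond the two-sample t; no permutation or
  TFCE inference; no anatomical labeling of cluster peaks.
- The generator's community partition is a raster-order slab partition —
  spatially compact but not anatomically shaped.
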