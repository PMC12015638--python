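# Methods

This note documents the models, estimators, and design choices behind
`gradientflow`: what each stage computes, what the synthetic-cohort
generator does and does not emulate, and which decisions were genuinely
open.

## Pipeline estimators

### Windowing and connectivity

`plan_windows` lays half-open sample ranges `[k·step, k·step + window)` with
`count = ⌊(T − window)/step⌋ + 1`; the defaults (40 s windows, 20 s steps,
300 s series, 1 s sampling) give 14 windows. Connectivity is the Pearson
correlation of the ROI rows within the window (series are de-meaned per
window by construction of the correlation). Windowed correlations from 40
samples are noisy (sd ≈ 0.16 per entry near zero correlation); everything
downstream is designed around that noise floor.

Binarization is row-wise: each row keeps its top `⌈density·(R−1)⌉`
off-diagonal entries (density 0.10, the "sparsity = 0.9" convention of
gradient toolboxes), ties broken toward the lower column index. The result
need not be symmetric; the affinity kernel resolves that. Global (matrix-
wide) thresholding is deliberately not used — row-wise selection guarantees
every ROI retains edges, so the affinity graph stays connected.

### Affinity and embedding

The normalized-angle affinity is `1 − arccos(clamp(ρ, −1, 1))/π` applied to
the cosine similarity `ρ` between binarized connectivity profiles; values
lie in [0, 1] with orthogonal profiles at 0.5. Diffusion-map embedding uses
anisotropic normalization `W = D^−α A D^−α` with α = 0.5 (halves the
influence of degree/sampling density), row-normalizes to a Markov matrix,
and eigendecomposes via the similar symmetric matrix
`D₂^½ M D₂^−½` — numerically symmetric-stable and identical in exact
arithmetic to the Markov eigenproblem (the test suite checks this
equivalence against a direct non-symmetric eigendecomposition to a
Procrustes residual below 1e−6). Eigenvectors are normalized in the
stationary-distribution inner product so the trivial eigenvector is the
constant 1, and components are scaled by λ/(1−λ) (the automatic diffusion
time, `diffusion_time = 0`); a positive `diffusion_time` t switches to λᵗ.
Sign is fixed deterministically (largest-magnitude entry positive).
Near-degenerate eigenvalues are flagged with a warning because components
are then defined only up to rotation within the tied subspace.

### Alignment and binning

Eigenvector sign, and under near-degeneracy rotation, is arbitrary across
windows and subjects, so all window- and subject-level gradient sets are
aligned by orthogonal Procrustes rotation (no scaling) to one template:
the control group's static group-level gradient. Comparing bins across
windows without a common frame would be meaningless; a flag
(`align_windows=False`) disables alignment for sensitivity analyses.

"Equally sized bins" is read as equal-count (quantile) bins: ROIs sorted by
principal-gradient value (ties broken by ROI index) and cut into runs of
⌈R/K⌉ or ⌊R/K⌋, K = 20 by default (K = 7 as a sensitivity setting). Equal
count keeps allegiance and recruitment denominators comparable across
windows and subjects; an equal-width alternative sits behind
`method="width"`. A consequence worth knowing: equal-count bins are a pure
function of value *ranks*, which couples networks — if one network's ROIs
move along the axis, the bin edges of every other network shift too.

### Dynamic measures and the static null

Allegiance pools all (subject, window) assignments of a group:
`P_ij = #{bin_i = bin_j}/(S·W)`. Flexibility and recruitment are computed
per subject (then voxel-weighted into network means and compared between
groups); recruitment for ROIs in singleton networks is undefined and
reported as missing, excluded from network means rather than zero-filled.

The static null model is multivariate phase randomization: one common
random phase vector added to every ROI's Fourier phases (conjugate-
symmetric, DC/Nyquist untouched) preserves each amplitude spectrum and all
cross-spectra — hence the full static second-order structure — while
destroying genuine nonstationarity. Each of the `n_surrogates` replicates
(default 20) phase-randomizes every subject and runs the identical
windowed-gradient pipeline, giving one null allegiance matrix per
replicate. An alternative degenerate null (replicating each subject's
static bin assignment across windows) sits behind
`null_model="replicate-static"`.

The comparison reports the two-sample Kolmogorov–Smirnov statistic D on the
upper-triangle allegiance values (real vs pooled nulls) with its asymptotic
p-value, and additionally an *empirical* p: the rank of the real KS
distance among leave-one-out null-vs-null distances, with the +1
correction. The upper-triangle entries are mutually dependent (R(R−1)/2
values derive from S·W assignments), so the asymptotic p-value is
anticonservative under the null; D and the empirical p are the quantities
to trust. Under a truly static process, real and surrogate allegiance
matrices are exchangeable, so the empirical p is exactly calibrated — with
19 surrogates the 5 % test rejects iff the real distance is strictly
maximal. "More widespread" is operationalized as a larger interquartile
range of the real distribution.

### Activation and coupling tests

Betas are per-ROI OLS coefficients of the block regressor in
`[intercept, linear drift, regressor]`; the regressor is the binary design
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1:6) normalized to unit sum so a sustained block keeps its plateau
amplitude. Loading scores are `beta_i · g_i` against a reference gradient —
by default an independently supplied resting-state-style axis rather than
the task gradient, to avoid correlating a quantity with itself — aggregated
by voxel-weighted network means.

Two permutation tests, both two-sided with the (1 + #{|Δr*| ≥ |Δr|})/(1+n)
convention: the group-coupling test permutes subject group labels around
the statistic `r(mean betas A, g) − r(mean betas B, g)` (a per-subject-r
variant sits behind `statistic="mean_r"`); the gradient-preference test
compares one group's mean betas against two gradients and builds its null
by swapping `g1_i ↔ g2_i` per ROI — a sign-exchange of the paired
difference, appropriate because under no preference the two gradients are
ROI-wise exchangeable.

### Group statistics

Network measures are compared with a rank-based ANCOVA: rank the response
and each covariate over all subjects, residualize the ranked response on an
intercept plus the ranked covariates by least squares, then a one-way
ANOVA F on the residuals with df (k−1, n−k). With no covariates this is a
one-way ANOVA on ranks. The nonparametric path is always taken for network
measures (no normality gate), for determinism. Default covariates: age,
sex (0/1), education years, MoCA. The FDR family is the seven networks
within one measure type (Benjamini–Hochberg step-up, monotone, capped at
1); raw and adjusted p-values are both reported. Mann–Whitney U uses the
exact null for groups of ≤ 12 without ties, otherwise the tie-corrected
normal approximation without continuity correction (identical samples then
give p = 1 exactly). Covariate-adjusted correlations residualize both
variables on [intercept, covariates] and refer the Pearson correlation of
the residuals to t with n − #covariates − 2 df.

## The synthetic cohort

### What it emulates

A two-group verbal-fluency-style block design: 5 blocks of 30 s rest +
30 s task at 1 s sampling (T = 300), 400 ROIs in the seven canonical
networks (voxel counts uniform in 50–500), 29 controls and 30 patients,
subject covariates (age, sex, education, MoCA; the patient group's MoCA is
shifted −2.5 points, mirroring a cognitively affected cohort, while the
other covariates are matched).

ROI *i* has a latent hierarchy position `g*_i ∈ [0, 1]`, laid out in
contiguous network bands in the canonical unimodal→transmodal order. The
baseline covariance has three positive semi-definite parts:

    C = exp(−|g_i − g_j| / 0.3)          short-range axis kernel
      + 2.0 · a_i a_j,  a = 2g − 1       rank-one global hierarchy mode
      + 0.1 · 1[same network]            within-network boost

The rank-one mode makes transmodal regions covary and anticorrelate with
unimodal ones — the task-positive/default-mode antagonism — and is what
gives the planted axis a spectrally separated principal component. This
matters: without it the binarized connectivity graph is a pure 1-D
k-nearest-neighbour band whose leading diffusion eigenvalues are nearly
degenerate (gap ≈ 2 %), and the estimated principal gradient rotates
arbitrarily under sampling noise. Real functional connectivity has the
gradient as a dominant global mode; the generator reproduces that.

Dynamics: latent positions re-jitter network-wise (a common shift,
sd 0.08) at 20 s anchors with probability 0.5. Between anchors the
Cholesky factors of the anchor covariances are linearly interpolated and
applied to per-sample innovations, so each subject is one contiguous,
smoothly nonstationary series and overlapping analysis windows share
samples. Task activation adds `(beta_gain · g*_i + network offset)` times
the HRF-convolved design; white noise (sd 0.5) sits on top.

Group effects, each switchable (`null_effects()` turns all off):

- **DMN contraction** — patient DMN latent positions shrink toward the
  band's own centre by factor 0.5. Centre-shrinkage (rather than shrinkage
  toward the axis midpoint) preserves the network's rank block and hence
  its bin occupancy, so the effect expresses as a gradient-*span*
  contraction without corrupting DMN recruitment through rank mixing.
- **Recruitment deficit (SMC + LIM)** — the within-network boost is damped
  (× 0.25), the networks' coherent window moves are damped by the same
  factor, and — the operative mechanism — matched cross-network ROI pairs
  (one somatomotor with one limbic ROI; an aberrant coupling between the
  epileptogenic limbic focus and its somatomotor discharge terminal)
  intermittently *swap* axis positions, spending ≈ 30 % of anchors swapped
  in persistent Markov episodes (toggle probability 0.1 per anchor).
  Swapping scatters both networks' members out of their own bins (lowering
  recruitment and raising flexibility) while leaving every other network's
  rank occupancy exactly unchanged, so the planted deficit stays selective
  under equal-count binning. A side effect to expect in reports: the
  *gradient-span* family flags expansion in the swapped networks, because
  their time-averaged profiles smear along the axis.

Ground truth stores the latent axis, the true betas, every anchor's latent
positions, and the **model-implied gradient**: the principal gradient of
the noise-free baseline control covariance pushed through the identical
binarize→affinity→embed pipeline. The latent coordinate is defined only up
to monotone reparameterization, and the embedding applies a deterministic
monotone warp to it (rank correlation with the latent axis is ≈ 0.99 while
the Pearson correlation saturates near 0.86); the model-implied gradient is
the right target for recovery tests because the difference from an
estimate is then pure sampling error. Recovery at desk scale (100 ROIs,
10 controls) is |r| ≈ 0.97–0.99.

True betas are tied to the *canonical* axis `g*` in both groups. In
patients the gradient reorganizes while the activation pattern does not,
so the generator naturally reproduces activation–gradient decoupling: the
patient activation pattern tracks the control gradient at least as well as
the patients' own.

Effect sizes and dynamics parameters are calibrated so that recovery by
this pipeline at desk scale is well powered; they are modelling
conveniences, not claims about epilepsy physiology.

### What it does not emulate

No voxel-level structure, spatial smoothness, or geometry; no
autocorrelated noise (innovations are white, so surrogate tests exercise
cross-spectral rather than autospectral preservation); no head motion,
physiological confounds, or scanner drifts (the optional 0.009–0.10 Hz
zero-phase frequency-domain band-pass is off for synthetic data); no
hemispheric structure or lateralized disease effects; no biophysical
(neural-mass/balloon) signal model. Passing the recovery suites therefore
demonstrates that the estimators recover the planted statistical structure
through the full pipeline — not that real TLE data would show these
effects at these magnitudes.

## Numerical choices and degenerate inputs

- Covariance factorization adds a 1e−8 diagonal nugget (coincident latent
  positions after clipping make the exponential kernel singular); genuine
  indefiniteness triggers escalating diagonal loading with a warning.
- Correlation matrices are clipped to [−1, 1]; zero-variance ROIs are a
  hard error naming the rows.
- Binarization ties broken toward the lower column index; equal-count
  binning ties broken by ROI index; both deterministic.
- Disconnected affinity graphs error with advice to lower the sparsity.
- Permutation p-values always carry the +1 correction, hence lie in (0, 1].
- All randomness flows from one master seed through named
  `SeedSequence` streams (per subject, per surrogate replicate, per test),
  so cohorts and summaries are bit-reproducible and per-subject draws do
  not depend on group sizes elsewhere.

## Problem sizes

Default `RunConfig` runs a desk-scale study — 100 ROIs, 15 + 15 subjects,
14 windows, 20 surrogates, 500 permutations (≈ 20 s) — with
`--full-scale` switching to the full 400-ROI, 29 + 30-subject design. The
validation suites use 42–100 ROIs: effect recovery across 20 cohort
replicates at 100 ROIs and 15 + 15 subjects; surrogate-null calibration at
42 ROIs with 19 surrogates and 50 seeds (19 surrogates make the 5 %
empirical test exact); FDR null calibration across 200 replicates at
42 ROIs and 4 + 4 subjects. These sizes were chosen so each suite's
Monte-Carlo error is small relative to the margins it asserts.

## Known limitations

The asymptotic KS p-value on allegiance entries should be read as a
descriptive index (a conventional uncorrected `p_unc`), not a calibrated error rate —
use the empirical surrogate p for inference. Equal-count binning couples
networks through ranks, so strong reorganization in one network can move
other networks' bin statistics; the generator's swap mechanism was designed
around this, but real data offers no such guarantee. The Quade-style rank
ANCOVA assumes covariate effects are monotone (it adjusts ranks linearly);
gross nonlinearity in covariate effects is not captured. Procrustes
alignment to the control template assumes the two groups share a common
2-component subspace; with k = 2 this is mild, but larger k would need a
joint template.
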