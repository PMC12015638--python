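# gradientflow

Dynamic and static functional-connectivity **gradient** analysis for ROI-level
fMRI time series, with a synthetic-cohort generator that plants recoverable
ground truth.

The functional connectivity gradient is a low-dimensional embedding axis of
the ROI-to-ROI connectivity similarity structure; its principal component
runs from unimodal sensory/motor cortex to the transmodal default-mode
network (DMN). `gradientflow` asks whether that gradient is *dynamic* — does
it reconfigure over the course of a task? — and how its static and dynamic
organisation differ between two groups (e.g. healthy controls, HC, versus
temporal lobe epilepsy patients, TLE), linking both to task
activation/deactivation patterns.

It is written for researchers working with parcellated task-fMRI: the inputs
are plain ROI×time matrices (one per subject), a parcellation table mapping
each ROI to one of the seven canonical cortical networks (SMC, VIS, SAN,
DAN, LIM, CCN, DMN) with its voxel count, and a subject table with group
labels and covariates.

## The method

For each subject the series (default: a 300 s block task at TR = 1 s) is cut
into sliding windows of 40 s in steps of 20 s — 14 windows. Per window:

1. Pearson correlation matrix **C** (R×R, default R = 400);
2. row-wise binarization at 10 % density (keep the top ⌈0.1·(R−1)⌉ entries
   per row — the *sparsity 0.9* convention);
3. normalized-angle affinity `a_ij = 1 − arccos(cos ρ_ij)/π` between
   connectivity profiles;
4. diffusion-map embedding (`W = D^−α A D^−α`, α = 0.5; eigenvectors of the
   Markov matrix, scaled by λ/(1−λ)); column 1 is the principal gradient;
5. orthogonal Procrustes alignment to the control group's static gradient,
   then discretization into K = 20 equal-count bins.

From the windowed bin assignments:

- **allegiance** `P_ij` — probability that ROIs *i*, *j* share a bin across
  all subjects and windows of a group;
- **flexibility** `f_i` — fraction of contiguous window transitions in which
  ROI *i* changes bin;
- **recruitment** `r_i` — probability that ROI *i* shares a bin with the
  other ROIs of its own network, averaged over windows.

Gradient dynamics are established by comparing the real allegiance
distribution against allegiance from **phase-randomized surrogates** (one
common random phase vector per subject preserves every amplitude spectrum
and all cross-spectra — the static-null hypothesis) with a two-sample
Kolmogorov–Smirnov test, plus an exchangeability-calibrated empirical
p-value. Activation analysis estimates task>rest betas by OLS against an
HRF-convolved block regressor, computes **loading scores** (beta × reference
gradient, voxel-weighted network means), and tests activation–gradient
coupling with label-permutation and gradient-preference (ROI sign-exchange)
permutation tests. Group comparisons use a Quade-style rank ANCOVA
(covariates: age, sex, education, MoCA) with Benjamini–Hochberg FDR across
the seven networks per measure family.

The `synth` module generates the whole study synthetically: a planted
unimodal→transmodal axis drives the covariance, window-to-window latent
jitter makes the gradient genuinely dynamic, and group effects (DMN gradient
contraction; a somatomotor/limbic recruitment deficit) can be injected and
later recovered by the pipeline. See `docs/methods.md` for the model.

## Worked example

Run the full pipeline on a desk-scale synthetic cohort (100 ROIs, 15
subjects per group, 20 surrogates):

```bash
gradientflow run --seed 1 --out runs/demo
```

or equivalently in Python:

```python
from gradientflow import RunConfig, run_pipeline
summary = run_pipeline(RunConfig(seed=1))
```

Key lines of the summary this prints:

```text
n_windows: 14
static_null: ks_statistic 0.0523, p_value 1.26e-11, p_empirical 0.0476,
             real_iqr 0.0238 > null_iqr 0.0190, more_widespread true
span_ratio TLE/HC, DMN: 0.748
significant_after_fdr: recruitment SMC, recruitment LIM, ...
coupling_test: delta_r 0.0044, p_value 0.657
gradient_preference_test: delta_r -0.0009, p_value 0.954
```

Reading: the control group's allegiance distribution is broader than the
static surrogates' (KS D = 0.052 at p ≪ 0.001; the calibrated surrogate test
also rejects at 0.048) — the gradient is genuinely dynamic, exactly as
planted. The patient group's DMN gradient span is contracted to 0.75 of the
control span, and after FDR correction the recruitment deficit shows up in
SMC and LIM — the two networks it was planted in. The activation–gradient
coupling does not differ between groups (p = 0.66), matching the generator,
which ties true betas to the same reference axis in both groups.

`gradientflow validate-demo --seed 1` reproduces the gradient-validation
checks on the same cohort: the task-based group gradient correlates with the
reference axis at |r| = 0.84 (p = 1.6e-27), and the group-mean betas
correlate with the reference gradient at r = 0.973 (p = 3.3e-64) — the
healthy activation pattern follows the cortical hierarchy.

`gradientflow synth --seed 1 --out cohort/` writes the cohort itself as
TSV files (parcellation, per-subject series, subject table, reference
gradient) plus the ground truth as JSON; `--full-scale` switches to the
full 400-ROI, 29 + 30-subject design.

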