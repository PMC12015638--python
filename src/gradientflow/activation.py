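"""Block-design activation analysis: beta estimation, loading scores, and
permutation tests of activation–gradient coupling.

Betas are task>rest contrast estimates from an ordinary-least-squares fit of
each ROI's series on an intercept, a linear drift, and the (optionally
HRF-convolved) block regressor.  Loading scores weight each ROI's beta by a
reference gradient value — high scores mean the activation/deactivation
pattern conforms to the cortical hierarchy — and are aggregated to networks
by voxel-number-weighted means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation_io import Parcellation, RoiTimeSeries, ValidationError


@dataclass
class BetaVector:
    """Per-ROI task>rest contrast estimates for one subject."""

    subject_id: str
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 1 or not np.isfinite(self.betas).all():
            raise ValidationError(
                f"{self.subject_id}: betas must be a finite 1-D vector"
            )


@dataclass
class LoadingScores:
    """Per-ROI loadings (beta times reference gradient) and their
    voxel-weighted per-network means."""

    per_roi: np.ndarray
    per_network: pd.Series


@dataclass
class PermutationResult:
    """Observed correlation-difference statistic with its permutation p-value."""

    delta_r: float
    p_value: float
    r_first: float
    r_second: float
    n_perm: int


def canonical_hrf(
    sampling_interval_s: float,
    duration_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, sampled at ``dt``.

    Difference of two gamma densities (peak ~6 s, undershoot ~16 s, ratio
    1:6), normalized to unit sum so that convolving a sustained block leaves
    its plateau amplitude unchanged — beta estimates then carry the signal's
    own units.
    """
    dt = float(sampling_interval_s)
    t = np.arange(0.0, duration_s, dt)
    peak = stats.gamma.pdf(t, a=peak_delay_s, scale=1.0)
    under = stats.gamma.pdf(t, a=undershoot_delay_s, scale=1.0)
    h = peak - under / undershoot_ratio
    return h / h.sum()


def convolve_design(
    design: np.ndarray, sampling_interval_s: float = 1.0
) -> np.ndarray:
    """Convolve a binary block design with the canonical HRF (causal,
    truncated to the design length)."""
    design = np.asarray(design, dtype=float)
    h = canonical_hrf(sampling_interval_s)
    return np.convolve(design, h)[: design.size]


def estimate_betas(
    ts: RoiTimeSeries, design: np.ndarray, hrf: bool = True
) -> BetaVector:
    """Per-ROI OLS task>rest betas against [intercept, drift, regressor].

    ``design`` is the binary rest/task vector of length T; with ``hrf=True``
    the regressor is its canonical-HRF convolution.  The returned beta is the
    regressor coefficient.
    """
    design = np.asarray(design, dtype=float)
    if design.size != ts.n_samples:
        raise ValidationError(
            f"design length {design.size} does not match T={ts.n_samples}"
        )
    if np.ptp(design) == 0:
        raise ValidationError("design is constant; task>rest contrast undefined")
    reg = convolve_design(design, ts.sampling_interval_s) if hrf else design
    t = ts.n_samples
    x = np.column_stack(
        [np.ones(t), np.linspace(-0.5, 0.5, t), reg]
    )
    coef, *_ = np.linalg.lstsq(x, ts.data.T, rcond=None)
    return BetaVector(subject_id=ts.subject_id, betas=coef[2])


def loading_scores(
    betas: BetaVector | np.ndarray,
    gradient: np.ndarray,
    parcellation: Parcellation,
) -> LoadingScores:
    """Beta-by-gradient loadings with voxel-weighted network aggregation.

    Per-ROI loading is ``beta_i * g_i`` where ``g`` is the principal axis of
    a reference gradient (a resting-state gradient by default, to keep betas
    and gradient statistically independent).
    """
    b = betas.betas if isinstance(betas, BetaVector) else np.asarray(betas, float)
    g = np.asarray(gradient, dtype=float)
    if b.shape != g.shape or b.size != parcellation.n_roi:
        raise ValidationError(
            f"betas ({b.shape}), gradient ({g.shape}) and parcellation "
            f"({parcellation.n_roi} ROIs) must align"
        )
    per_roi = b * g
    w = parcellation.voxel_weights()
    vals = {}
    for net in parcellation.networks_present:
        idx = parcellation.network_indices(net)
        vals[net] = float(np.sum(per_roi[idx] * w[idx]) / np.sum(w[idx]))
    return LoadingScores(per_roi=per_roi, per_network=pd.Series(vals))


def activation_gradient_correlation(
    betas: BetaVector | np.ndarray, gradient: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation across ROIs between a beta map (or group mean)
    and a gradient's principal axis; two-sided p."""
    b = betas.betas if isinstance(betas, BetaVector) else np.asarray(betas, float)
    r, p = stats.pearsonr(b, np.asarray(gradient, dtype=float))
    return float(r), float(p)


def _stack_betas(betas: list[BetaVector] | np.ndarray) -> np.ndarray:
    if isinstance(betas, np.ndarray):
        return np.atleast_2d(np.asarray(betas, dtype=float))
    return np.vstack([b.betas for b in betas])


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def group_coupling_permutation_test(
    betas_a: list[BetaVector] | np.ndarray,
    betas_b: list[BetaVector] | np.ndarray,
    gradient: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    statistic: str = "mean_betas",
) -> PermutationResult:
    """Two-group test of activation–gradient coupling.

    Statistic: r(mean betas of A, g) − r(mean betas of B, g) (or, with
    ``statistic='mean_r'``, the difference of group-mean per-subject
    correlations).  The null permutes subject group labels; the two-sided
    p-value carries the +1 correction, so it lies in (0, 1].
    """
    if statistic not in ("mean_betas", "mean_r"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    a = _stack_betas(betas_a)
    b = _stack_betas(betas_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("each group needs at least 2 subjects")
    g = np.asarray(gradient, dtype=float)
    pooled = np.vstack([a, b])
    n_a = a.shape[0]

    def stat(idx_a: np.ndarray, idx_b: np.ndarray) -> tuple[float, float, float]:
        if statistic == "mean_betas":
            ra = _corr(pooled[idx_a].mean(axis=0), g)
            rb = _corr(pooled[idx_b].mean(axis=0), g)
        else:
            ra = float(np.mean([_corr(pooled[i], g) for i in idx_a]))
            rb = float(np.mean([_corr(pooled[i], g) for i in idx_b]))
        return ra - rb, ra, rb

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    observed, r_a, r_b = stat(np.arange(n_a), np.arange(n_a, pooled.shape[0]))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        d, _, _ = stat(perm[:n_a], perm[n_a:])
        if abs(d) >= abs(observed) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermutationResult(
        delta_r=observed, p_value=p, r_first=r_a, r_second=r_b, n_perm=n_perm
    )


def gradient_preference_test(
    betas: list[BetaVector] | np.ndarray,
    gradient_first: np.ndarray,
    gradient_second: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Does one activation pattern track gradient 1 more than gradient 2?

    Statistic: r(mean betas, g1) − r(mean betas, g2).  The null swaps
    g1_i and g2_i per ROI at random (a sign-exchange of the paired
    difference), appropriate because under no preference the two gradients
    are exchangeable ROI-wise.
    """
    g1 = np.asarray(gradient_first, dtype=float)
    g2 = np.asarray(gradient_second, dtype=float)
    if g1.shape != g2.shape:
        raise ValidationError("gradients must have the same length")
    mean_b = _stack_betas(betas).mean(axis=0)
    r1 = _corr(mean_b, g1)
    r2 = _corr(mean_b, g2)
    observed = r1 - r2
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hits = 0
    for _ in range(n_perm):
        swap = rng.random(g1.size) < 0.5
        h1 = np.where(swap, g2, g1)
        h2 = np.where(swap, g1, g2)
        d = _corr(mean_b, h1) - _corr(mean_b, h2)
        if abs(d) >= abs(observed) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermutationResult(
        delta_r=observed, p_value=p, r_first=r1, r_second=r2, n_perm=n_perm
    )
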