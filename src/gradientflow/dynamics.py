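"""Dynamic gradient measures over windowed bin assignments.

Allegiance is the probability that two ROIs share a gradient bin across all
subjects and windows of a group; flexibility is the fraction of contiguous
window transitions in which an ROI changes bin; recruitment is the
probability that an ROI shares a bin with the other ROIs of its own
network, averaged over windows.  The reality of gradient dynamics is tested
by comparing the allegiance distribution of real data against allegiance
from stationary (phase-randomized) surrogates with a two-sample
Kolmogorov–Smirnov statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gradients import BinAssignment
from .parcellation_io import Parcellation, ValidationError


@dataclass
class AssignmentStack:
    """Bin assignments for a set of subjects across windows.

    ``bins`` has shape (S, W, R) with integer bins in [0, K).
    """

    bins: np.ndarray
    n_bins: int
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        if self.bins.ndim != 3:
            raise ValidationError("bins must have shape (S, W, R)")
        if self.bins.size and (
            self.bins.min() < 0 or self.bins.max() >= self.n_bins
        ):
            raise ValidationError("bin labels must lie in [0, n_bins)")

    @classmethod
    def from_assignments(
        cls,
        per_subject: list[list[BinAssignment]],
        subject_ids: tuple[str, ...] = (),
    ) -> "AssignmentStack":
        ks = {a.n_bins for row in per_subject for a in row}
        if len(ks) != 1:
            raise ValidationError("all assignments must share n_bins")
        arr = np.stack(
            [np.stack([a.bins for a in row]) for row in per_subject]
        )
        return cls(bins=arr, n_bins=ks.pop(), subject_ids=subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.bins.shape[0]

    @property
    def n_windows(self) -> int:
        return self.bins.shape[1]

    @property
    def n_roi(self) -> int:
        return self.bins.shape[2]


@dataclass
class AllegianceMatrix:
    """Pairwise same-bin probabilities (symmetric, unit diagonal); entries
    are exact fractions over ``n_observations`` (subject, window) pairs."""

    values: np.ndarray
    n_observations: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (
            self.values.ndim != 2
            or self.values.shape[0] != self.values.shape[1]
        ):
            raise ValidationError("allegiance matrix must be square")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


@dataclass
class StaticNullComparison:
    """KS comparison of real vs static-null allegiance distributions.

    ``p_value`` is the asymptotic two-sample KS p treating upper-triangle
    entries as the sample (entries are weakly dependent, so ``statistic`` is
    the primary quantity); ``p_empirical`` is an exchangeability-calibrated
    surrogate-data p: the rank of the real KS distance among leave-one-out
    null-vs-null distances.
    """

    statistic: float
    p_value: float
    p_empirical: float
    real_iqr: float
    null_iqr: float

    @property
    def more_widespread(self) -> bool:
        """Operationalizes "more widespread": larger dispersion in real data."""
        return self.real_iqr > self.null_iqr


def allegiance(stack: AssignmentStack) -> AllegianceMatrix:
    """P_ij = fraction of (subject, window) pairs with bin_i == bin_j."""
    if stack.bins.size == 0:
        raise ValidationError("empty assignment stack")
    flat = stack.bins.reshape(-1, stack.n_roi)
    r = stack.n_roi
    acc = np.zeros((r, r))
    for row in flat:
        acc += row[:, None] == row[None, :]
    return AllegianceMatrix(values=acc / flat.shape[0], n_observations=flat.shape[0])


def flexibility(stack: AssignmentStack) -> np.ndarray:
    """Per-subject, per-ROI fraction of contiguous window transitions with a
    bin change; shape (S, R)."""
    if stack.n_windows < 2:
        raise ValidationError("flexibility needs at least 2 windows")
    changes = stack.bins[:, 1:, :] != stack.bins[:, :-1, :]
    return changes.mean(axis=1)


def recruitment(stack: AssignmentStack, parcellation: Parcellation) -> np.ndarray:
    """Per-subject, per-ROI probability of sharing a bin with same-network
    ROIs, averaged over windows and network peers; shape (S, R).

    ROIs in singleton networks have no peers; their recruitment is undefined
    and returned as NaN (excluded from network means downstream).
    """
    if stack.n_roi != parcellation.n_roi:
        raise ValidationError("stack and parcellation disagree on R")
    s, w, r = stack.bins.shape
    out = np.full((s, r), np.nan)
    for net in parcellation.networks_present:
        idx = parcellation.network_indices(net)
        if idx.size < 2:
            warnings.warn(
                f"network {net} has a single ROI; recruitment undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        sub = stack.bins[:, :, idx]  # (S, W, n)
        same = sub[:, :, :, None] == sub[:, :, None, :]  # (S, W, n, n)
        # exclude self-pairs from the peer average
        peer_mean = (same.sum(axis=3) - 1) / (idx.size - 1)
        out[:, idx] = peer_mean.mean(axis=1)
    return out


def subject_allegiance(stack: AssignmentStack, subject: int) -> AllegianceMatrix:
    """Allegiance restricted to one subject's windows (used by the
    recruitment/allegiance consistency identity)."""
    sub = AssignmentStack(
        bins=stack.bins[[subject]], n_bins=stack.n_bins
    )
    return allegiance(sub)


def network_weighted_mean(
    values: np.ndarray, parcellation: Parcellation
) -> pd.Series | pd.DataFrame:
    """Voxel-number-weighted mean of per-ROI values within each network.

    Accepts a (R,) vector (returns a Series indexed by network) or an
    (S, R) matrix (returns a DataFrame, subjects x networks).  NaN entries
    (undefined recruitment) are excluded from both numerator and weights.
    """
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != parcellation.n_roi:
        raise ValidationError("values length must match parcellation")
    w = parcellation.voxel_weights()
    cols = {}
    for net in parcellation.networks_present:
        idx = parcellation.network_indices(net)
        sub = arr[:, idx]
        ww = np.broadcast_to(w[idx], sub.shape).copy()
        ww[np.isnan(sub)] = 0.0
        denom = ww.sum(axis=1)
        if np.any(denom == 0):
            raise ValidationError(
                f"network {net}: no ROI with a defined value"
            )
        cols[net] = np.nansum(sub * ww, axis=1) / denom
    df = pd.DataFrame(cols)
    return df.iloc[0] if squeeze else df


def compare_to_static_null(
    real: AllegianceMatrix, nulls: list[AllegianceMatrix]
) -> StaticNullComparison:
    """Two-sample KS of real allegiance vs pooled static-null allegiance.

    The sample is the upper-triangle entries.  Alongside the asymptotic KS
    p-value, an empirical p is computed by exchangeability: each null matrix
    is compared against the pool of the remaining nulls, and the real KS
    distance is ranked among those null-vs-null distances (with the +1
    correction).  Under a truly static process real and surrogate matrices
    are exchangeable, so this p is calibrated even though allegiance entries
    are mutually dependent.
    """
    if not nulls:
        raise ValidationError("need at least one null allegiance matrix")
    for m in nulls:
        if m.values.shape != real.values.shape:
            raise ValidationError("null matrix shape mismatch")
    real_vals = real.upper_triangle()
    null_vals = [m.upper_triangle() for m in nulls]
    pooled = np.concatenate(null_vals)
    d, p = stats.ks_2samp(real_vals, pooled)

    if len(nulls) > 1:
        d_nulls = []
        for i in range(len(nulls)):
            rest = np.concatenate(
                [v for j, v in enumerate(null_vals) if j != i]
            )
            d_i, _ = stats.ks_2samp(null_vals[i], rest)
            d_nulls.append(d_i)
        p_emp = (1 + np.sum(np.asarray(d_nulls) >= d - 1e-15)) / (
            1 + len(nulls)
        )
    else:
        p_emp = 1.0

    q1r, q3r = np.percentile(real_vals, [25, 75])
    q1n, q3n = np.percentile(pooled, [25, 75])
    return StaticNullComparison(
        statistic=float(d),
        p_value=float(p),
        p_empirical=float(p_emp),
        real_iqr=float(q3r - q1r),
        null_iqr=float(q3n - q1n),
    )
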