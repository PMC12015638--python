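"""Connectivity gradients: normalized-angle affinity, diffusion-map
embedding, Procrustes alignment, equal-count binning, and per-network
gradient summaries.

The principal gradient is the first non-trivial diffusion-map component of
the normalized-angle affinity between sparsified connectivity profiles; it
runs from unimodal sensory/motor cortex to transmodal default-mode cortex.
Because eigenvector sign and (under near-degeneracy) rotation are arbitrary,
window- and subject-level gradients are aligned to a common reference by
orthogonal Procrustes rotation before binning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix
from .parcellation_io import Parcellation, ValidationError


@dataclass
class GradientSet:
    """Embedding components (R x k; column 0 is the principal gradient) with
    their eigenvalues, sorted non-increasing."""

    components: np.ndarray
    eigenvalues: np.ndarray
    window_index: int | str = "static"
    aligned_to: str | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.components.ndim != 2:
            raise ValidationError("components must be R x k")
        if self.eigenvalues.shape != (self.components.shape[1],):
            raise ValidationError("one eigenvalue per component required")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValidationError("eigenvalues must be non-increasing")
        if not np.isfinite(self.components).all():
            raise ValidationError("components must be finite")

    @property
    def n_roi(self) -> int:
        return self.components.shape[0]

    @property
    def principal(self) -> np.ndarray:
        return self.components[:, 0]


@dataclass
class BinAssignment:
    """Integer bin in [0, K) per ROI along the principal gradient."""

    bins: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=int)
        if self.bins.min(initial=0) < 0 or self.bins.max(initial=0) >= self.n_bins:
            raise ValidationError("bin labels must lie in [0, n_bins)")


def normalized_angle_affinity(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Normalized-angle affinity between connectivity rows.

    a_ij = 1 - arccos(cos_sim(row_i, row_j)) / pi, in [0, 1] with unit
    diagonal.  Rows are the (typically density-thresholded) connectivity
    profiles; a zero row means an ROI retained no edges and is an error.
    """
    vals = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    norms = np.linalg.norm(vals, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValidationError(
            f"ROI rows {bad[:10].tolist()} have no retained edges; lower the "
            f"sparsity (raise the density)"
        )
    unit = vals / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = 0.5 * (aff + aff.T)
    np.fill_diagonal(aff, 1.0)
    return aff


def diffusion_embedding(
    affinity: np.ndarray,
    n_components: int = 2,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric non-negative affinity.

    Anisotropic normalization ``W = D^-alpha A D^-alpha`` (alpha = 0.5
    halves the influence of sampling density), row-normalization to a Markov
    matrix, eigendecomposition via the similar symmetric matrix, and scaling
    of each non-trivial eigenvector by ``lambda / (1 - lambda)`` (the
    automatic-time rule for ``diffusion_time=0``) or ``lambda**t`` otherwise.
    """
    a = np.asarray(affinity, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("affinity must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("affinity must be symmetric")
    if a.min() < -1e-12:
        raise ValidationError("affinity must be non-negative")
    n_comp_graph, _ = connected_components(
        csr_matrix(a > 1e-12), directed=False
    )
    if n_comp_graph > 1:
        raise ValidationError(
            f"affinity graph has {n_comp_graph} components; lower the "
            f"sparsity so the graph is connected"
        )
    r = a.shape[0]
    if not 1 <= n_components < r:
        raise ValidationError(f"need 1 <= n_components < {r}")

    d = a.sum(axis=1)
    d_alpha = d ** (-alpha)
    w = a * np.outer(d_alpha, d_alpha)
    d2 = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d2)
    # symmetric matrix similar to the Markov matrix M = D2^-1 W
    s = w * np.outer(inv_sqrt, inv_sqrt)
    s = 0.5 * (s + s.T)
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # right eigenvectors of M, normalized so the trivial one is constant 1
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]

    lam = evals[1 : n_components + 1]
    if np.any(np.abs(np.diff(evals[: n_components + 1])) < 1e-12):
        warnings.warn(
            "degenerate eigenvalues: components are defined only up to "
            "rotation within the tied subspace",
            RuntimeWarning,
            stacklevel=2,
        )
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    comps = psi[:, 1 : n_components + 1] * scale

    # deterministic sign: the largest-magnitude entry of each column is
    # positive, so reruns and equivalent solvers agree up to this convention
    for j in range(comps.shape[1]):
        i_max = np.argmax(np.abs(comps[:, j]))
        if comps[i_max, j] < 0:
            comps[:, j] = -comps[:, j]
    return GradientSet(components=comps, eigenvalues=lam)


def align_gradients(source: GradientSet, reference: GradientSet) -> GradientSet:
    """Rotate ``source`` components onto ``reference`` by orthogonal
    Procrustes (rotation/reflection only, no scaling)."""
    if source.components.shape != reference.components.shape:
        raise ValidationError(
            f"shape mismatch: {source.components.shape} vs "
            f"{reference.components.shape}"
        )
    rot, _ = orthogonal_procrustes(source.components, reference.components)
    return replace(
        source, components=source.components @ rot, aligned_to="reference"
    )


def bin_gradient(
    g: GradientSet | np.ndarray, n_bins: int = 20, method: str = "count"
) -> BinAssignment:
    """Discretize the principal gradient into ``n_bins`` bins.

    ``method='count'`` (default): equal-count bins — ROIs sorted ascending by
    gradient value (ties broken by ROI index), consecutive runs of
    ceil(R/K) or floor(R/K) ROIs per bin, so bin occupancies differ by at
    most one and allegiance denominators stay comparable across windows.
    ``method='width'``: equal-width intervals spanning [min, max].
    """
    values = g.principal if isinstance(g, GradientSet) else np.asarray(g, float)
    r = values.size
    if not 2 <= n_bins <= r:
        raise ValidationError(f"need 2 <= n_bins <= {r}")
    bins = np.empty(r, dtype=int)
    if method == "count":
        order = np.argsort(values, kind="stable")
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            bins[chunk] = b
    elif method == "width":
        lo, hi = values.min(), values.max()
        if hi == lo:
            bins[:] = 0
        else:
            bins = np.minimum(
                ((values - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1
            )
    else:
        raise ValidationError(f"unknown binning method {method!r}")
    return BinAssignment(bins=bins, n_bins=n_bins)


def gradient_similarity(
    a: GradientSet | np.ndarray, b: GradientSet | np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between two principal gradients
    across ROIs."""
    va = a.principal if isinstance(a, GradientSet) else np.asarray(a, float)
    vb = b.principal if isinstance(b, GradientSet) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValidationError("gradients must share length")
    r, p = stats.pearsonr(va, vb)
    return float(r), float(p)


def network_gradient_distribution(
    g: GradientSet | np.ndarray, parcellation: Parcellation
) -> tuple[dict[str, np.ndarray], "pd.DataFrame"]:
    """Per-network principal-gradient values with median, interquartile
    range, and span (max - min) — the summaries used for gradient
    contraction/expansion comparisons."""
    import pandas as pd

    values = g.principal if isinstance(g, GradientSet) else np.asarray(g, float)
    if values.size != parcellation.n_roi:
        raise ValidationError("gradient length must match parcellation")
    per_net: dict[str, np.ndarray] = {}
    rows = []
    for net in parcellation.networks_present:
        v = values[parcellation.network_indices(net)]
        per_net[net] = v
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            {
                "network": net,
                "median": med,
                "iqr": q3 - q1,
                "span": float(v.max() - v.min()),
            }
        )
    return per_net, pd.DataFrame(rows)
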