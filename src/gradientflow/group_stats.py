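"""Nonparametric group statistics with covariate adjustment and FDR control.

Network-level measures are compared between groups with a Quade-style
nonparametric ANCOVA (ranks residualized on ranked covariates, then a
one-way F test), p-values are Benjamini–Hochberg adjusted across the seven
networks within each measure family, and correlations with cognitive scores
are covariate-adjusted Pearson correlations on residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .parcellation_io import SubjectTable, ValidationError

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex", "education", "moca")


@dataclass
class ComparisonResult:
    """One network-level group comparison within a measure family."""

    measure: str
    network: str
    groups: tuple[str, ...]
    statistic: float
    p_unc: float
    p_fdr: float
    n_per_group: tuple[int, ...]
    covariates: tuple[str, ...]
    test: str


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def quade_ancova(
    y: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Rank-based ANCOVA: F test on covariate-residualized ranks.

    All observations are ranked (y and each covariate separately), the
    ranked response is residualized on an intercept plus the ranked
    covariates by least squares, and a one-way ANOVA F statistic is formed
    on the residuals by group, referred to F(k-1, n-k).  With no covariates
    this reduces to a one-way ANOVA on ranks (a Kruskal–Wallis-style test).
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n = y.size
    if groups.size != n:
        raise ValidationError("y and groups must have equal length")
    labels, counts = np.unique(groups, return_counts=True)
    k = labels.size
    if k < 2 or np.any(counts < 2):
        raise ValidationError("need >= 2 groups with >= 2 subjects each")
    if np.ptp(y) == 0:
        raise ValidationError("constant response; ranks are uninformative")

    ry = stats.rankdata(y)
    design = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValidationError("covariate rows must match subjects")
        rcov = np.column_stack(
            [stats.rankdata(cov[:, j]) for j in range(cov.shape[1])]
        )
        design = np.column_stack([design, rcov])
    resid = _residualize(ry, design)

    grand = resid.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lab in labels:
        g = resid[groups == lab]
        ss_between += g.size * (g.mean() - grand) ** 2
        ss_within += np.sum((g - g.mean()) ** 2)
    df1, df2 = k - 1, n - k
    if ss_within <= 0:
        return float("inf"), 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.

    Exact null distribution when both groups have n <= 12 and there are no
    ties; otherwise the normal approximation with tie correction (and no
    continuity correction, so identical samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and x.size <= 12 and y.size <= 12:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x,
            y,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=False,
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjusted_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on an
    intercept plus covariates; p from t with n - n_cov - 2 df.

    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValidationError("x and y must have equal length")
    if covariates is None or not np.size(covariates):
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
    n_cov = cov.shape[1]
    if n <= n_cov + 2:
        raise ValidationError("need n > n_covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    # a variable fully explained by the covariates leaves a numerically
    # zero residual; its partial correlation is zero by convention
    if (
        np.linalg.norm(rx) < 1e-10 * max(np.linalg.norm(x), 1.0)
        or np.linalg.norm(ry) < 1e-10 * max(np.linalg.norm(y), 1.0)
    ):
        return 0.0, 1.0
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    df = n - n_cov - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def compare_networks(
    values: pd.DataFrame,
    subjects: SubjectTable,
    measure: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[ComparisonResult]:
    """Per-network covariate-adjusted group comparison with BH-FDR across
    networks.

    ``values`` is a subjects x networks DataFrame indexed (or ordered) like
    the subject table.  One Quade ANCOVA per network; the FDR family is the
    set of networks within this measure, and both raw and adjusted p-values
    are reported.
    """
    if values.shape[0] != len(subjects.subject_ids):
        raise ValidationError("values rows must match subject table")
    groups = subjects.groups
    labels, counts = np.unique(groups, return_counts=True)
    cov = subjects.covariate_matrix(covariates) if covariates else None
    nets = list(values.columns)
    stats_p = []
    for net in nets:
        f, p = quade_ancova(values[net].to_numpy(dtype=float), groups, cov)
        stats_p.append((f, p))
    adj = bh_fdr([p for _, p in stats_p])
    return [
        ComparisonResult(
            measure=measure,
            network=net,
            groups=tuple(labels),
            statistic=f,
            p_unc=p,
            p_fdr=float(q),
            n_per_group=tuple(int(c) for c in counts),
            covariates=tuple(covariates),
            test="quade_ancova",
        )
        for net, (f, p), q in zip(nets, stats_p, adj)
    ]


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results to the tabular report layout."""
    return pd.DataFrame(
        [
            {
                "measure": r.measure,
                "network": r.network,
                "statistic": r.statistic,
                "p_unc": r.p_unc,
                "p_FDR": r.p_fdr,
                "n_A": r.n_per_group[0],
                "n_B": r.n_per_group[1] if len(r.n_per_group) > 1 else np.nan,
                "covariates": ",".join(r.covariates),
                "test": r.test,
            }
            for r in results
        ]
    )
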