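"""Synthetic cohort generator with a planted connectivity gradient.

The generator emulates a two-group verbal-fluency-style block fMRI study at
the ROI level: a latent unimodal-to-transmodal axis drives the connectivity
structure, windows reconfigure over time (the source of genuine gradient
dynamics), and group effects can be injected — contraction of the default
mode network's latent positions and reduced within-network dynamic coherence
in selected networks — so every downstream stage has recoverable ground
truth.

Model
-----
ROI *i* carries a latent position ``g*_i`` on [0, 1], ordered along the seven
canonical networks from somatomotor to default-mode.  The baseline covariance
is ``C_ij = exp(-|g_i - g_j| / axis_corr_scale) + w * a_i a_j +
boost * 1[same network]`` with ``a = 2g - 1``: a short-range kernel along the
axis, a rank-one global hierarchy mode (transmodal regions covary and
anticorrelate with unimodal ones, as in the task-positive/default-mode
antagonism), and a same-network block bonus; all three terms are positive
semi-definite.  Latent positions are re-jittered network-wise at regular
anchors with probability ``state_switch_rate``; the per-sample covariance
factor interpolates between consecutive anchor Cholesky factors, so the
series is one contiguous, smoothly nonstationary record and overlapping
analysis windows share samples.  Task activation is added as
``(beta_gain * g*_i + network offset)`` times the HRF-convolved block design,
plus white Gaussian noise.

Patient-group effects: the default-mode band contracts toward its centre
(gradient-span contraction), and in the deficit networks (somatomotor and
limbic by default) matched ROI pairs intermittently swap axis positions —
aberrant coupling between the epileptogenic limbic focus and its
somatomotor discharge terminal — which lowers those networks' recruitment
while leaving every other system's gradient-bin occupancy unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activation import convolve_design
from .parcellation_io import (
    NETWORKS,
    Parcellation,
    RoiTimeSeries,
    SubjectTable,
    ValidationError,
)


@dataclass(frozen=True)
class SynthParams:
    """All knobs of the synthetic cohort; one master seed drives everything.

    Defaults describe the emulated study: 400 ROIs in 7 networks, two groups
    of 29 healthy controls and 30 patients, five 30 s rest + 30 s task
    blocks at 1 s sampling (300 samples), with a default-mode contraction and
    a somatomotor/limbic dynamic-coherence deficit planted in the patient
    group.  Group effect sizes are not claims about pathophysiology; they are
    set so that recovery by the pipeline is well powered at desk scale.
    """

    n_roi: int = 400
    n_networks: int = 7
    voxel_count_range: tuple[int, int] = (50, 500)
    #: (controls, patients) — the emulated cohort is 29 HC vs 30 TLE.
    n_subjects_per_group: tuple[int, int] = (29, 30)
    n_blocks: int = 5
    rest_s: float = 30.0
    task_s: float = 30.0
    sampling_interval_s: float = 1.0
    #: e-folding length of correlation decay along the latent axis.
    axis_corr_scale: float = 0.3
    #: weight of the rank-one global hierarchy mode ``outer(2g-1, 2g-1)``:
    #: transmodal regions covary and anticorrelate with unimodal regions,
    #: making the planted axis a dominant (spectrally separated) mode as in
    #: real functional connectivity.
    axis_mode_weight: float = 2.0
    #: additive covariance bonus for same-network ROI pairs.
    within_network_boost: float = 0.1
    #: per-anchor probability that a network's positions jitter.
    state_switch_rate: float = 0.5
    #: SD of the latent-position jitter (axis units).
    axis_jitter_sd: float = 0.08
    #: spacing of jitter anchors; matches the analysis window step.
    state_switch_interval_s: float = 20.0
    #: patient DMN latent positions are shrunk toward the axis midpoint by
    #: this factor (1 = no effect).
    dmn_contraction_factor: float = 0.5
    recruitment_deficit_networks: tuple[str, ...] = ("SMC", "LIM")
    #: multiplies the within-network boost *and* the coherent share of the
    #: window jitter for deficit networks in patients (1 = no effect).
    coherence_reduction: float = 0.25
    #: slope tying true activation betas to latent position.
    beta_gain: float = 1.0
    beta_network_offset_sd: float = 0.1
    noise_sd: float = 0.5
    #: MoCA shift applied to the patient group (matched cohorts otherwise).
    moca_group_shift: float = -2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi < self.n_networks:
            raise ValidationError(
                f"n_roi ({self.n_roi}) must be >= n_networks "
                f"({self.n_networks})"
            )
        if self.n_networks != len(NETWORKS):
            raise ValidationError(
                f"n_networks must be {len(NETWORKS)} (canonical labels)"
            )
        for name in ("state_switch_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "axis_corr_scale",
            "dmn_contraction_factor",
            "coherence_reduction",
            "sampling_interval_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.dmn_contraction_factor > 1 or self.coherence_reduction > 1:
            raise ValidationError(
                "dmn_contraction_factor and coherence_reduction are factors "
                "in (0, 1]"
            )
        total = self.n_blocks * (self.rest_s + self.task_s)
        n = total / self.sampling_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                "total duration must be a whole number of samples"
            )

    @property
    def n_samples(self) -> int:
        return int(
            round(
                self.n_blocks
                * (self.rest_s + self.task_s)
                / self.sampling_interval_s
            )
        )

    def null_effects(self) -> "SynthParams":
        """Copy with all group effects switched off (groups exchangeable)."""
        return replace(
            self,
            dmn_contraction_factor=1.0,
            coherence_reduction=1.0,
            moca_group_shift=0.0,
        )


@dataclass
class GroundTruth:
    """Planted quantities stored alongside the cohort for recovery tests.

    ``latent_axis`` is the generative coordinate (unique only up to monotone
    reparameterization); ``model_gradient`` is the principal gradient of the
    noise-free baseline control-group connectivity, computed by the same
    embedding pipeline — the model-implied target that gradient estimates
    should reproduce up to sampling error.
    """

    latent_axis: np.ndarray
    model_gradient: np.ndarray
    true_betas: np.ndarray
    #: subject_id -> (n_anchors, R) latent positions used per jitter anchor.
    anchor_positions: dict[str, np.ndarray]
    group_effects: dict[str, object]


@dataclass
class Cohort:
    """A generated cohort: time series, subject table, and ground truth."""

    timeseries: list[RoiTimeSeries]
    subjects: SubjectTable
    ground_truth: GroundTruth
    parcellation: Parcellation
    design: np.ndarray


def make_parcellation(params: SynthParams) -> Parcellation:
    """Seven contiguous near-equal network blocks with heterogeneous sizes.

    Networks are laid out in the canonical unimodal-to-transmodal order so
    ROI order follows the planted axis; voxel counts are drawn uniformly in
    ``voxel_count_range``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0x9A5C])
    )
    sizes = [len(b) for b in np.array_split(np.arange(params.n_roi), len(NETWORKS))]
    labels: list[str] = []
    for net, size in zip(NETWORKS, sizes):
        labels.extend([net] * size)
    lo, hi = params.voxel_count_range
    counts = rng.integers(lo, hi + 1, size=params.n_roi)
    width = len(str(params.n_roi))
    ids = tuple(f"ROI{i:0{width}d}" for i in range(params.n_roi))
    return Parcellation(
        roi_ids=ids, network_labels=tuple(labels), voxel_counts=tuple(int(c) for c in counts)
    )


def make_design(params: SynthParams) -> np.ndarray:
    """Binary rest(0)/task(1) vector: n_blocks repeats of rest then task."""
    rest = int(round(params.rest_s / params.sampling_interval_s))
    task = int(round(params.task_s / params.sampling_interval_s))
    block = np.concatenate([np.zeros(rest, dtype=int), np.ones(task, dtype=int)])
    return np.tile(block, params.n_blocks)


def latent_axis(params: SynthParams, parcellation: Parcellation) -> np.ndarray:
    """Planted gradient: each network occupies a band of [0, 1] in canonical
    order, ROIs evenly spaced inside their band."""
    g = np.empty(parcellation.n_roi)
    n_net = len(NETWORKS)
    for m, net in enumerate(NETWORKS):
        idx = parcellation.network_indices(net)
        lo, hi = m / n_net, (m + 1) / n_net
        pad = (hi - lo) / (2 * len(idx))
        g[idx] = np.linspace(lo + pad, hi - pad, len(idx))
    return g


def _covariance(
    positions: np.ndarray,
    net_codes: np.ndarray,
    boost_by_net: np.ndarray,
    scale: float,
    axis_mode_weight: float = 0.0,
) -> np.ndarray:
    d = np.abs(positions[:, None] - positions[None, :])
    c = np.exp(-d / scale)
    if axis_mode_weight:
        a = 2.0 * positions - 1.0
        c = c + axis_mode_weight * np.outer(a, a)
    same = net_codes[:, None] == net_codes[None, :]
    # same-network implies equal codes, so the row network's boost applies
    c = c + same * boost_by_net[net_codes][:, None]
    # nugget: coincident latent positions (e.g. after clipping at the axis
    # ends) make the exponential kernel singular; a tiny diagonal floor
    # keeps the factorization well posed without visibly changing the model
    c[np.diag_indices_from(c)] += 1e-8
    return c


def _safe_cholesky(c: np.ndarray) -> np.ndarray:
    """Cholesky with minimal escalating diagonal loading on failure."""
    eps = 0.0
    for _ in range(8):
        try:
            return np.linalg.cholesky(c + eps * np.eye(c.shape[0]))
        except np.linalg.LinAlgError:
            eps = 1e-10 if eps == 0.0 else eps * 100
            warnings.warn(
                f"covariance not positive definite; adding diagonal loading "
                f"{eps:g} — consider changing axis_corr_scale or boost",
                RuntimeWarning,
                stacklevel=2,
            )
    raise ValidationError("covariance could not be made positive definite")


def _subject_series(
    params: SynthParams,
    base_positions: np.ndarray,
    net_codes: np.ndarray,
    boost_by_net: np.ndarray,
    decohered: np.ndarray,
    regressor: np.ndarray,
    true_betas: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's (R, T) series and its (n_anchors, R) anchor positions."""
    t_total = params.n_samples
    step = int(round(params.state_switch_interval_s / params.sampling_interval_s))
    n_seg = int(np.ceil(t_total / step))
    n_net = len(NETWORKS)
    r = base_positions.size

    # Decohered networks: ROIs are matched into cross-network pairs (a
    # subject-specific random pairing, e.g. a limbic ROI with a somatomotor
    # ROI — aberrant coupling between the epileptogenic focus and its
    # discharge terminal) that intermittently *swap* axis positions.  A swap
    # scatters both networks' members away from their communities while
    # leaving every other system's rank occupancy exactly unchanged.  With a
    # single decohered network, pairs are drawn across that network's ROIs
    # and a uniform stand-in site on the axis.
    deco_nets = np.flatnonzero(decohered)
    pair_a: np.ndarray
    pair_b: np.ndarray
    offsite = np.zeros(r)
    if deco_nets.size >= 2:
        idx_a = rng.permutation(np.flatnonzero(net_codes == deco_nets[0]))
        idx_b = rng.permutation(np.flatnonzero(net_codes == deco_nets[1]))
        n_pairs = min(idx_a.size, idx_b.size)
        pair_a, pair_b = idx_a[:n_pairs], idx_b[:n_pairs]
    elif deco_nets.size == 1:
        pair_a = rng.permutation(np.flatnonzero(net_codes == deco_nets[0]))
        pair_b = np.array([], dtype=int)
        offsite[pair_a] = rng.uniform(0.0, 1.0, pair_a.size) - base_positions[pair_a]
    else:
        pair_a = pair_b = np.array([], dtype=int)

    # Swap episodes persist across anchors (a two-state Markov chain with a
    # modest toggle rate): transitions, during which a travelling ROI's
    # connectivity profile morphs through intermediate axis positions, are
    # kept rare relative to the time spent at either site.
    # Asymmetric two-state chain: pairs spend ~30% of anchors swapped, so
    # the dynamic deficit is strong while the static (time-averaged)
    # connectivity keeps most of its in-network structure.
    n_pairs = pair_a.size
    swap_frac = 0.3
    p_on = 0.2 * params.state_switch_rate * swap_frac / (1.0 - swap_frac)
    p_off = 0.2 * params.state_switch_rate
    swapped = rng.random(n_pairs) < swap_frac
    anchors = np.empty((n_seg + 1, r))
    anchors[0] = base_positions
    for a in range(1, n_seg + 1):
        flip_p = np.where(swapped, p_off, p_on)
        swapped = swapped ^ (rng.random(n_pairs) < flip_p)
        pos = base_positions.copy()
        for m in range(n_net):
            if rng.random() >= params.state_switch_rate:
                continue
            idx = np.flatnonzero(net_codes == m)
            if decohered[m]:
                shift = params.coherence_reduction * rng.normal(
                    0.0, params.axis_jitter_sd
                )
            else:
                shift = rng.normal(0.0, params.axis_jitter_sd)
            pos[idx] = np.clip(pos[idx] + shift, 0.0, 1.0)
        if pair_b.size:
            a_pos = pos[pair_a].copy()
            pos[pair_a] = np.where(swapped, pos[pair_b], pos[pair_a])
            pos[pair_b] = np.where(swapped, a_pos, pos[pair_b])
        elif pair_a.size:
            pos[pair_a] = np.clip(
                pos[pair_a] + swapped * offsite[pair_a], 0.0, 1.0
            )
        anchors[a] = pos

    chols = [
        _safe_cholesky(
            _covariance(
                anchors[a],
                net_codes,
                boost_by_net,
                params.axis_corr_scale,
                params.axis_mode_weight,
            )
        )
        for a in range(n_seg + 1)
    ]

    z = rng.standard_normal((r, t_total))
    x = np.empty((r, t_total))
    for a in range(n_seg):
        sl = slice(a * step, min((a + 1) * step, t_total))
        n_in = sl.stop - sl.start
        u = (np.arange(n_in) + 0.5) / step
        xa = chols[a] @ z[:, sl]
        xb = chols[a + 1] @ z[:, sl]
        x[:, sl] = xa * (1.0 - u) + xb * u

    x += true_betas[:, None] * regressor[None, :]
    x += rng.normal(0.0, params.noise_sd, size=x.shape)
    return x, anchors


def simulate_cohort(
    params: SynthParams, parcellation: Parcellation | None = None
) -> Cohort:
    """Generate the full two-group cohort under ``params``.

    Deterministic given the seed: all randomness flows from one master
    ``SeedSequence`` split into named streams (parcellation, axis/betas,
    covariates, one per subject), so cohorts are bit-reproducible and
    per-subject draws do not depend on group sizes elsewhere.
    """
    if parcellation is None:
        parcellation = make_parcellation(params)
    g_star = latent_axis(params, parcellation)
    net_codes = np.array(
        [NETWORKS.index(l) for l in parcellation.network_labels]
    )
    design = make_design(params)
    regressor = convolve_design(design, params.sampling_interval_s)

    rng_global = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0xBE7A])
    )
    net_offsets = rng_global.normal(
        0.0, params.beta_network_offset_sd, size=len(NETWORKS)
    )
    true_betas = params.beta_gain * g_star + net_offsets[net_codes]

    n_hc, n_tle = params.n_subjects_per_group
    subjects = [(f"HC{i+1:02d}", "HC") for i in range(n_hc)] + [
        (f"TLE{i+1:02d}", "TLE") for i in range(n_tle)
    ]

    boost_hc = np.full(len(NETWORKS), params.within_network_boost)
    boost_tle = boost_hc.copy()
    decohered_hc = np.zeros(len(NETWORKS), dtype=bool)
    decohered_tle = decohered_hc.copy()
    for net in params.recruitment_deficit_networks:
        m = NETWORKS.index(net)
        boost_tle[m] *= params.coherence_reduction
        decohered_tle[m] = params.coherence_reduction < 1.0

    # Patient DMN latent positions contract toward their own band centre:
    # the network's spread along the hierarchy shrinks while its rank block
    # (and hence its bin occupancy) is preserved, so the contraction shows
    # as a gradient-span effect rather than a recruitment artefact.
    base_tle = g_star.copy()
    dmn_idx = parcellation.network_indices("DMN")
    dmn_centre = g_star[dmn_idx].mean()
    base_tle[dmn_idx] = dmn_centre + params.dmn_contraction_factor * (
        g_star[dmn_idx] - dmn_centre
    )

    series: list[RoiTimeSeries] = []
    anchor_positions: dict[str, np.ndarray] = {}
    for k, (sid, group) in enumerate(subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, 0x5EED, k])
        )
        if group == "HC":
            base, boosts, deco = g_star, boost_hc, decohered_hc
        else:
            base, boosts, deco = base_tle, boost_tle, decohered_tle
        x, anchors = _subject_series(
            params, base, net_codes, boosts, deco, regressor, true_betas, rng
        )
        series.append(
            RoiTimeSeries(
                subject_id=sid,
                data=x,
                sampling_interval_s=params.sampling_interval_s,
            )
        )
        anchor_positions[sid] = anchors

    rng_cov = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0xC0FA])
    )
    n = len(subjects)
    table = pd.DataFrame(
        {
            "subject_id": [s for s, _ in subjects],
            "group": [g for _, g in subjects],
            "age": rng_cov.integers(18, 56, size=n),
            "sex": rng_cov.integers(0, 2, size=n),
            "education": np.clip(
                np.round(rng_cov.normal(12, 3, size=n)), 5, 20
            ).astype(int),
            "moca": np.clip(
                np.round(
                    rng_cov.normal(28.5, 1.5, size=n)
                    + np.where(
                        np.array([g for _, g in subjects]) == "TLE",
                        params.moca_group_shift,
                        0.0,
                    )
                ),
                10,
                30,
            ).astype(int),
        }
    )

    # model-implied gradient: embed the noise-free baseline control-group
    # correlation through the identical analysis pipeline
    c_hc = _covariance(
        g_star,
        net_codes,
        boost_hc,
        params.axis_corr_scale,
        params.axis_mode_weight,
    )
    sd = np.sqrt(np.diag(c_hc))
    corr_hc = c_hc / np.outer(sd, sd)
    from .connectivity import ConnectivityMatrix, binarize_density
    from .gradients import diffusion_embedding, normalized_angle_affinity

    model_grad = diffusion_embedding(
        normalized_angle_affinity(
            binarize_density(ConnectivityMatrix(values=corr_hc))
        ),
        n_components=2,
    ).principal

    gt = GroundTruth(
        latent_axis=g_star,
        model_gradient=model_grad,
        true_betas=true_betas,
        anchor_positions=anchor_positions,
        group_effects={
            "dmn_contraction_factor": params.dmn_contraction_factor,
            "recruitment_deficit_networks": list(
                params.recruitment_deficit_networks
            ),
            "coherence_reduction": params.coherence_reduction,
            "tle_base_positions": base_tle,
        },
    )
    return Cohort(
        timeseries=series,
        subjects=SubjectTable(table),
        ground_truth=gt,
        parcellation=parcellation,
        design=design,
    )
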