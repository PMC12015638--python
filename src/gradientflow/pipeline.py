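"""End-to-end orchestration: cohort (synthetic or loaded) -> windowed
connectivity -> gradients -> dynamics -> activation -> group statistics.

Every run is deterministic given the master seed, emits per-stage TSVs plus
a JSON summary, and records a manifest (parameters, seed, versions, stage
timings) sufficient to reproduce it bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import (
    BetaVector,
    activation_gradient_correlation,
    estimate_betas,
    gradient_preference_test,
    group_coupling_permutation_test,
    loading_scores,
)
from .connectivity import (
    ConnectivityMatrix,
    WindowScheme,
    binarize_density,
    correlation_matrix,
    group_average,
    phase_randomized_surrogate,
    plan_windows,
)
from .dynamics import (
    AllegianceMatrix,
    AssignmentStack,
    allegiance,
    compare_to_static_null,
    flexibility,
    network_weighted_mean,
    recruitment,
)
from .gradients import (
    GradientSet,
    align_gradients,
    bin_gradient,
    diffusion_embedding,
    gradient_similarity,
    network_gradient_distribution,
    normalized_angle_affinity,
)
from .group_stats import (
    DEFAULT_COVARIATES,
    compare_networks,
    results_frame,
)
from .parcellation_io import (
    Parcellation,
    RoiTimeSeries,
    SubjectTable,
    ValidationError,
    read_parcellation,
    read_subject_table,
    read_timeseries,
    read_vector,
    write_parcellation,
    write_subject_table,
    write_timeseries,
    write_vector,
)
from .synth import Cohort, GroundTruth, SynthParams, make_design, simulate_cohort

logger = logging.getLogger("gradientflow")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage and offending subject."""


def desk_scale_synth(seed: int = 0) -> SynthParams:
    """Reduced-scale defaults for interactive runs and CI: 100 ROIs and
    15 subjects per group instead of the emulated study's 400 and 29/30."""
    return SynthParams(n_roi=100, n_subjects_per_group=(15, 15), seed=seed)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run, serialized verbatim into
    the run manifest."""

    synth: SynthParams = field(default_factory=desk_scale_synth)
    input_dir: str | None = None  # real-data mode; overrides synth
    window_length_s: float = 40.0
    step_s: float = 20.0
    density: float = 0.10
    kernel: str = "normalized_angle"
    n_components: int = 2
    n_bins: int = 20
    bin_method: str = "count"
    align_windows: bool = True
    n_surrogates: int = 20
    null_model: str = "phase"  # or "replicate-static"
    n_perm: int = 500
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.kernel != "normalized_angle":
            raise ValidationError(f"unsupported kernel {self.kernel!r}")
        if self.null_model not in ("phase", "replicate-static"):
            raise ValidationError(f"unsupported null_model {self.null_model!r}")
        if not 0 < self.density <= 1:
            raise ValidationError("density must be in (0, 1]")
        # keep the synthetic generator on the run's master seed
        if self.input_dir is None and self.synth.seed != self.seed:
            self.synth = replace(self.synth, seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        synth_d = d.pop("synth", {})
        synth = SynthParams(**synth_d) if synth_d else desk_scale_synth()
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(synth=synth, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# Reusable building blocks
# ---------------------------------------------------------------------------


def embed_connectivity(
    m: ConnectivityMatrix,
    density: float = 0.10,
    n_components: int = 2,
    reference: GradientSet | None = None,
) -> GradientSet:
    """Weighted matrix -> density binarization -> normalized-angle affinity
    -> diffusion-map embedding, optionally Procrustes-aligned to a
    reference."""
    b = binarize_density(m, density)
    aff = normalized_angle_affinity(b)
    g = diffusion_embedding(aff, n_components=n_components)
    g.window_index = m.window_index
    if reference is not None:
        g = align_gradients(g, reference)
    return g


def subject_window_gradients(
    ts: RoiTimeSeries,
    windows: list[tuple[int, int]],
    density: float = 0.10,
    n_components: int = 2,
    reference: GradientSet | None = None,
) -> list[GradientSet]:
    """Per-window gradients for one subject."""
    out = []
    for w, rng in enumerate(windows):
        m = correlation_matrix(ts, rng, window_index=w)
        out.append(
            embed_connectivity(
                m, density=density, n_components=n_components, reference=reference
            )
        )
    return out


def cohort_assignments(
    ts_list: list[RoiTimeSeries],
    windows: list[tuple[int, int]],
    cfg: RunConfig,
    reference: GradientSet | None,
) -> AssignmentStack:
    """Windowed, aligned, binned gradients for a list of subjects."""
    per_subject = []
    for ts in ts_list:
        grads = subject_window_gradients(
            ts,
            windows,
            density=cfg.density,
            n_components=cfg.n_components,
            reference=reference if cfg.align_windows else None,
        )
        per_subject.append(
            [bin_gradient(g, cfg.n_bins, cfg.bin_method) for g in grads]
        )
    return AssignmentStack.from_assignments(
        per_subject, subject_ids=tuple(t.subject_id for t in ts_list)
    )


def static_null_allegiances(
    ts_list: list[RoiTimeSeries],
    windows: list[tuple[int, int]],
    cfg: RunConfig,
    reference: GradientSet | None,
) -> list[AllegianceMatrix]:
    """One group-pooled allegiance matrix per surrogate replicate.

    ``null_model='phase'``: each subject is phase-randomized per replicate
    and pushed through the identical windowed-gradient pipeline.
    ``null_model='replicate-static'``: each subject's static bin assignment
    is replicated across all windows (the degenerate static hypothesis).
    """
    nulls = []
    if cfg.null_model == "replicate-static":
        rows = []
        for ts in ts_list:
            g = embed_connectivity(
                correlation_matrix(ts),
                density=cfg.density,
                n_components=cfg.n_components,
                reference=reference,
            )
            b = bin_gradient(g, cfg.n_bins, cfg.bin_method)
            rows.append([b for _ in windows])
        stack = AssignmentStack.from_assignments(rows)
        return [allegiance(stack)]
    for r in range(cfg.n_surrogates):
        rows = []
        for k, ts in enumerate(ts_list):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 0x51AB, r, k])
            )
            surr = phase_randomized_surrogate(ts, rng)
            grads = subject_window_gradients(
                surr,
                windows,
                density=cfg.density,
                n_components=cfg.n_components,
                reference=reference if cfg.align_windows else None,
            )
            rows.append(
                [bin_gradient(g, cfg.n_bins, cfg.bin_method) for g in grads]
            )
        nulls.append(allegiance(AssignmentStack.from_assignments(rows)))
    return nulls


def _load_cohort(cfg: RunConfig) -> Cohort:
    """Real-data mode: read parcellation, subject table, per-subject series
    and (optionally) a reference gradient from ``input_dir``."""
    root = Path(cfg.input_dir)
    parc = read_parcellation(root / "parcellation.tsv")
    subjects = read_subject_table(root / "subjects.tsv")
    dt = cfg.synth.sampling_interval_s
    ts = [
        read_timeseries(
            root / f"{sid}.tsv", parc, subject_id=sid, sampling_interval_s=dt
        )
        for sid in subjects.subject_ids
    ]
    ref_path = root / "reference_gradient.tsv"
    ref = read_vector(ref_path, parc) if ref_path.exists() else None
    design = make_design(cfg.synth)
    axis = ref if ref is not None else np.full(parc.n_roi, np.nan)
    gt = GroundTruth(
        latent_axis=axis,
        model_gradient=np.full(parc.n_roi, np.nan),
        true_betas=np.full(parc.n_roi, np.nan),
        anchor_positions={},
        group_effects={},
    )
    return Cohort(
        timeseries=ts,
        subjects=subjects,
        ground_truth=gt,
        parcellation=parc,
        design=design,
    )


def _stage(name: str, timings: dict[str, float]):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, timings[name])

    return _Timer()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run the full analysis and return the summary dictionary.

    Stages: cohort, windowing, group gradients, windowed gradients and bin
    assignments, dynamic measures with group comparisons, static-null KS
    comparison, activation analysis with coupling tests, and reporting.
    With ``cfg.out_dir`` set, per-stage TSVs, ``summary.json`` and
    ``manifest.json`` are written there.
    """
    timings: dict[str, float] = {}
    summary: dict[str, Any] = {"config_seed": cfg.seed}

    with _stage("cohort", timings):
        cohort = (
            _load_cohort(cfg) if cfg.input_dir else simulate_cohort(cfg.synth)
        )
        parc = cohort.parcellation
        dt = cohort.timeseries[0].sampling_interval_s
        groups = sorted(set(cohort.subjects.groups))
        by_group = {
            g: [
                ts
                for ts in cohort.timeseries
                if ts.subject_id in set(cohort.subjects.subjects_in(g))
            ]
            for g in groups
        }

    with _stage("windowing", timings):
        scheme = WindowScheme(
            total_s=cohort.timeseries[0].total_s,
            window_length_s=cfg.window_length_s,
            step_s=cfg.step_s,
            sampling_interval_s=dt,
        )
        windows = plan_windows(scheme)
        summary["n_windows"] = len(windows)

    with _stage("group_gradients", timings):
        # group-level static gradients; the control group's is the common
        # alignment template for every window- and subject-level gradient
        ref_group = "HC" if "HC" in by_group else groups[0]
        static_by_subject = {
            ts.subject_id: correlation_matrix(ts) for ts in cohort.timeseries
        }
        group_grads: dict[str, GradientSet] = {}
        ref_gradient: GradientSet | None = None
        for g in [ref_group] + [g for g in groups if g != ref_group]:
            avg = group_average(
                [static_by_subject[ts.subject_id] for ts in by_group[g]]
            )
            grad = embed_connectivity(
                avg,
                density=cfg.density,
                n_components=cfg.n_components,
                reference=ref_gradient,
            )
            if ref_gradient is None:
                ref_gradient = grad
            group_grads[g] = grad

        span_summaries = {}
        for g in groups:
            _, summ = network_gradient_distribution(group_grads[g], parc)
            span_summaries[g] = summ.set_index("network")
        summary["group_gradient_span"] = {
            g: span_summaries[g]["span"].to_dict() for g in groups
        }
        if len(groups) == 2:
            a, b = ref_group, [g for g in groups if g != ref_group][0]
            ratios = (
                span_summaries[b]["span"] / span_summaries[a]["span"]
            ).to_dict()
            summary["span_ratio"] = {f"{b}/{a}": ratios}

    with _stage("windowed_gradients", timings):
        stacks = {
            g: cohort_assignments(by_group[g], windows, cfg, ref_gradient)
            for g in groups
        }

    with _stage("dynamics", timings):
        dyn_frames = {}
        comparisons = []
        order = list(cohort.subjects.subject_ids)
        for family, fn in (
            ("flexibility", lambda st: flexibility(st)),
            ("recruitment", lambda st: recruitment(st, parc)),
        ):
            rows = []
            for g in groups:
                per_roi = fn(stacks[g])
                df = network_weighted_mean(per_roi, parc)
                df.index = list(stacks[g].subject_ids)
                rows.append(df)
            values = pd.concat(rows).loc[order]
            dyn_frames[family] = values
            comparisons += compare_networks(
                values, cohort.subjects, family, cfg.covariates
            )

        # per-subject static-gradient network span enters the same group
        # machinery as the dynamic families
        span_rows = {}
        for ts in cohort.timeseries:
            g_sub = embed_connectivity(
                static_by_subject[ts.subject_id],
                density=cfg.density,
                n_components=cfg.n_components,
                reference=ref_gradient,
            )
            _, summ = network_gradient_distribution(g_sub, parc)
            span_rows[ts.subject_id] = summ.set_index("network")["span"]
        span_values = pd.DataFrame(span_rows).T.loc[order]
        dyn_frames["gradient_span"] = span_values
        comparisons += compare_networks(
            span_values, cohort.subjects, "gradient_span", cfg.covariates
        )

    with _stage("static_null", timings):
        real_alleg = allegiance(stacks[ref_group])
        nulls = static_null_allegiances(
            by_group[ref_group], windows, cfg, ref_gradient
        )
        ks = compare_to_static_null(real_alleg, nulls)
        summary["static_null"] = {
            "ks_statistic": ks.statistic,
            "p_value": ks.p_value,
            "p_empirical": ks.p_empirical,
            "real_iqr": ks.real_iqr,
            "null_iqr": ks.null_iqr,
            "more_widespread": ks.more_widespread,
            "n_surrogates": len(nulls),
        }

    with _stage("activation", timings):
        betas = {
            ts.subject_id: estimate_betas(ts, cohort.design)
            for ts in cohort.timeseries
        }
        # reference gradient for loading scores: an independent resting-state
        # axis (the planted axis in synthetic mode) when available, else the
        # control group's static task gradient
        axis = cohort.ground_truth.latent_axis
        ref_vec = (
            axis
            if np.isfinite(axis).all()
            else group_grads[ref_group].principal
        )
        load_rows = {}
        for sid, b in betas.items():
            ls = loading_scores(b, ref_vec, parc)
            load_rows[sid] = ls.per_network
        load_values = pd.DataFrame(load_rows).T.loc[order]
        dyn_frames["loading"] = load_values
        comparisons += compare_networks(
            load_values, cohort.subjects, "loading", cfg.covariates
        )

        if len(groups) == 2:
            other = [g for g in groups if g != ref_group][0]
            betas_ref = [betas[t.subject_id] for t in by_group[ref_group]]
            betas_other = [betas[t.subject_id] for t in by_group[other]]
            coup = group_coupling_permutation_test(
                betas_ref,
                betas_other,
                ref_vec,
                n_perm=cfg.n_perm,
                seed=np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, 0xC0DE])
                ),
            )
            pref = gradient_preference_test(
                betas_other,
                group_grads[ref_group].principal,
                group_grads[other].principal,
                n_perm=cfg.n_perm,
                seed=np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, 0xFACE])
                ),
            )
            summary["coupling_test"] = {
                "delta_r": coup.delta_r,
                "p_value": coup.p_value,
                f"r_{ref_group}": coup.r_first,
                f"r_{other}": coup.r_second,
            }
            summary["gradient_preference_test"] = {
                "delta_r": pref.delta_r,
                "p_value": pref.p_value,
                f"r_vs_{ref_group}_gradient": pref.r_first,
                f"r_vs_{other}_gradient": pref.r_second,
            }

    with _stage("report", timings):
        comp_df = results_frame(comparisons)
        summary["network_comparisons"] = comp_df.to_dict(orient="records")
        summary["significant_after_fdr"] = comp_df.loc[
            comp_df["p_FDR"] < 0.05, ["measure", "network"]
        ].to_dict(orient="records")
        summary = _jsonable(summary)

        if cfg.out_dir:
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_parcellation(parc, out / "parcellation.tsv")
            write_subject_table(cohort.subjects, out / "subjects.tsv")
            comp_df.to_csv(out / "network_comparisons.tsv", sep="\t", index=False)
            for family, df in dyn_frames.items():
                df.rename_axis("subject_id").to_csv(
                    out / f"{family}_by_network.tsv", sep="\t"
                )
            beta_df = pd.DataFrame(
                {sid: b.betas for sid, b in betas.items()},
                index=list(parc.roi_ids),
            )
            beta_df.rename_axis("roi_id").to_csv(
                out / "betas.tsv", sep="\t"
            )
            write_vector(
                ref_gradient.principal, parc, out / "static_gradient_ref_group.tsv"
            )
            with open(out / "summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            manifest = {
                "config": _jsonable(cfg.to_dict()),
                "window_plan": windows,
                "package_version": __version__,
                "numpy_version": np.__version__,
                "timings_s": timings,
            }
            with open(out / "manifest.json", "w", encoding="utf-8") as fh:
                json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)

    return summary


def validate_demo(cfg: RunConfig) -> dict[str, Any]:
    """Synthetic-mode validation of the gradient machinery.

    Reports three correlations with two-sided p-values: the control-group
    task gradient against the reference axis, the mean control beta map
    against the reference axis, and the mean control beta map against the
    task gradient — plus recovery of the planted axis.
    """
    if cfg.input_dir:
        raise ValidationError("validate_demo runs in synthetic mode only")
    cohort = simulate_cohort(cfg.synth)
    parc = cohort.parcellation
    hc_ids = set(cohort.subjects.subjects_in("HC"))
    hc_ts = [t for t in cohort.timeseries if t.subject_id in hc_ids]
    avg = group_average([correlation_matrix(t) for t in hc_ts])
    grad = embed_connectivity(avg, density=cfg.density, n_components=cfg.n_components)
    axis = cohort.ground_truth.latent_axis

    r_grad, p_grad = gradient_similarity(grad.principal, axis)
    mean_betas = np.mean(
        [estimate_betas(t, cohort.design).betas for t in hc_ts], axis=0
    )
    r_beta_ref, p_beta_ref = activation_gradient_correlation(mean_betas, axis)
    r_beta_task, p_beta_task = activation_gradient_correlation(
        mean_betas, grad.principal
    )
    report = {
        "task_gradient_vs_reference": {"r": r_grad, "p": p_grad},
        "betas_vs_reference_gradient": {"r": r_beta_ref, "p": p_beta_ref},
        "betas_vs_task_gradient": {"r": r_beta_task, "p": p_beta_task},
        "axis_recovery_abs_r": abs(r_grad),
        "n_hc": len(hc_ts),
        "n_roi": parc.n_roi,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = ["gradient validation report", "=" * 26]
        for key, val in report.items():
            lines.append(f"{key}: {val}")
        (out / "validation_report.txt").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
    return _jsonable(report)
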