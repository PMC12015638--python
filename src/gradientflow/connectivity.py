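"""Static and sliding-window functional connectivity.

Pearson correlation matrices per subject (full series or 40 s windows in
20 s steps — 14 windows for a 300 s task at 1 s sampling), row-wise density
binarization (top 10% of connections per row, the "sparsity = 0.9"
convention of gradient toolboxes), group averaging, and phase-randomized
stationary surrogates for the static null model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .parcellation_io import RoiTimeSeries, ValidationError


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window layout in seconds; defaults give 14 windows of 40 s in
    steps of 20 s over a 300 s series."""

    total_s: float
    window_length_s: float = 40.0
    step_s: float = 20.0
    sampling_interval_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("total_s", "window_length_s", "step_s", "sampling_interval_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.window_length_s > self.total_s:
            raise ValidationError(
                f"window ({self.window_length_s} s) longer than series "
                f"({self.total_s} s)"
            )
        for name in ("total_s", "window_length_s", "step_s"):
            n = getattr(self, name) / self.sampling_interval_s
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(
                    f"{name} must be divisible by the sampling interval"
                )

    @property
    def window_samples(self) -> int:
        return int(round(self.window_length_s / self.sampling_interval_s))

    @property
    def step_samples(self) -> int:
        return int(round(self.step_s / self.sampling_interval_s))

    @property
    def total_samples(self) -> int:
        return int(round(self.total_s / self.sampling_interval_s))


@dataclass
class ConnectivityMatrix:
    """An R x R connectivity matrix, weighted (Pearson) or binarized.

    ``window_index`` is an integer for sliding windows or the string
    ``"static"`` for full-series matrices.
    """

    values: np.ndarray
    kind: str = "weighted"
    window_index: int | str = "static"
    subject_or_group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"matrix must be square, got {self.values.shape}")
        if self.kind not in ("weighted", "binarized"):
            raise ValidationError(f"unknown kind {self.kind!r}")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


def plan_windows(scheme: WindowScheme) -> list[tuple[int, int]]:
    """Half-open [start, end) sample ranges for the sliding windows.

    Count = floor((total - window) / step) + 1; the first window starts at
    sample 0 and the last ends at or before the series end.
    """
    win = scheme.window_samples
    step = scheme.step_samples
    total = scheme.total_samples
    count = (total - win) // step + 1
    return [(i * step, i * step + win) for i in range(count)]


def correlation_matrix(
    ts: RoiTimeSeries,
    window: tuple[int, int] | None = None,
    window_index: int | str | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation of ROI rows over a sample range (or full series).

    ``window`` is a half-open [start, end) sample range; ``window_index`` is
    an optional tag recorded on the result (defaults to the start sample, or
    ``"static"`` for the full series).
    """
    if window is None:
        seg = ts.data
        widx: int | str = "static" if window_index is None else window_index
    else:
        start, end = window
        if end > ts.n_samples or start < 0 or end - start < 3:
            raise ValidationError(
                f"invalid window [{start}, {end}) for T={ts.n_samples}"
            )
        seg = ts.data[:, start:end]
        widx = start if window_index is None else window_index
    sd = seg.std(axis=1)
    if np.any(sd == 0):
        bad_ids = [str(i) for i in np.flatnonzero(sd == 0)]
        raise ValidationError(
            f"{ts.subject_id}: zero-variance ROI rows {bad_ids[:10]} in "
            f"window {window}"
        )
    c = np.corrcoef(seg)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(
        values=c, kind="weighted", window_index=widx, subject_or_group=ts.subject_id
    )


def binarize_density(
    m: ConnectivityMatrix, density: float = 0.10
) -> ConnectivityMatrix:
    """Row-wise density thresholding: per row keep the top
    ``ceil(density * (R-1))`` off-diagonal entries as 1, the rest 0.

    Ties are broken toward the lower column index.  The result need not be
    symmetric; the normalized-angle affinity downstream handles that.
    """
    if not 0.0 < density <= 1.0:
        raise ValidationError(f"density must be in (0, 1], got {density}")
    if m.kind != "weighted":
        raise ValidationError("binarize_density expects a weighted matrix")
    r = m.n_roi
    k = math.ceil(density * (r - 1))
    vals = m.values.copy()
    np.fill_diagonal(vals, -np.inf)
    # stable argsort of -values: equal values keep ascending column order
    order = np.argsort(-vals, axis=1, kind="stable")
    out = np.zeros((r, r))
    rows = np.repeat(np.arange(r), k)
    cols = order[:, :k].ravel()
    out[rows, cols] = 1.0
    return replace(m, values=out, kind="binarized")


def group_average(ms: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Entrywise mean of same-shaped weighted matrices (individual-level
    matrices averaged to a group-level matrix)."""
    if not ms:
        raise ValidationError("group_average of an empty list")
    first = ms[0]
    for m in ms[1:]:
        if m.values.shape != first.values.shape:
            raise ValidationError("matrices must share shape")
        if m.kind != first.kind:
            raise ValidationError("matrices must share kind")
        if m.window_index != first.window_index:
            raise ValidationError("matrices must share window_index")
    mean = np.mean([m.values for m in ms], axis=0)
    return ConnectivityMatrix(
        values=mean,
        kind=first.kind,
        window_index=first.window_index,
        subject_or_group="group",
    )


def phase_randomized_surrogate(
    ts: RoiTimeSeries, seed: int | np.random.Generator = 0
) -> RoiTimeSeries:
    """Multivariate phase-randomized surrogate of one subject's series.

    One common random phase vector is added to every ROI's Fourier phases
    (conjugate-symmetric, DC and Nyquist untouched).  This preserves each
    series' amplitude spectrum and all pairwise cross-spectra — hence the
    static covariance — while destroying any genuine nonstationary
    reconfiguration, which is exactly the "static" null hypothesis.
    """
    if ts.n_samples < 4:
        raise ValidationError("need T >= 4 samples for phase randomization")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t = ts.n_samples
    spec = np.fft.rfft(ts.data, axis=1)
    n_freq = spec.shape[1]
    phases = np.zeros(n_freq)
    if t % 2 == 0:
        phases[1 : n_freq - 1] = rng.uniform(0.0, 2.0 * np.pi, n_freq - 2)
    else:
        phases[1:] = rng.uniform(0.0, 2.0 * np.pi, n_freq - 1)
    rotated = spec * np.exp(1j * phases)[None, :]
    data = np.fft.irfft(rotated, n=t, axis=1)
    return RoiTimeSeries(
        subject_id=f"{ts.subject_id}#surrogate",
        data=data,
        sampling_interval_s=ts.sampling_interval_s,
    )


def bandpass(
    ts: RoiTimeSeries, low_hz: float = 0.009, high_hz: float = 0.10
) -> RoiTimeSeries:
    """Zero-phase frequency-domain band-pass (hard mask on the rFFT).

    Intended for real acquisitions; the synthetic pipeline leaves it off by
    default because the generator injects no scanner drifts.
    """
    if not 0 <= low_hz < high_hz:
        raise ValidationError("need 0 <= low_hz < high_hz")
    t = ts.n_samples
    freqs = np.fft.rfftfreq(t, d=ts.sampling_interval_s)
    spec = np.fft.rfft(ts.data, axis=1)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    mask[0] = True  # keep the mean; correlation de-means anyway
    data = np.fft.irfft(spec * mask[None, :], n=t, axis=1)
    return RoiTimeSeries(
        subject_id=ts.subject_id,
        data=data,
        sampling_interval_s=ts.sampling_interval_s,
    )
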