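"""Data model and delimited-text I/O for parcellations, ROI time series, and cohorts.

All tabular files are tab-delimited UTF-8 with a header row.  Plain numeric
matrices (time series) may omit the header, in which case an orientation flag
decides whether ROIs are in rows (default) or columns.  Sampling interval is
never inferred from files; it is carried explicitly because plain matrices
have no time metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The seven canonical cortical systems, ordered from unimodal (sensory/motor)
#: to transmodal (default-mode) along the principal connectivity gradient:
#: somatomotor, visual, salience, dorsal attention, (para)limbic, cognitive
#: control, and default mode network.
NETWORKS: tuple[str, ...] = ("SMC", "VIS", "SAN", "DAN", "LIM", "CCN", "DMN")


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates the data model."""


@dataclass(frozen=True)
class Parcellation:
    """A fixed ordering of ROIs with network labels and voxel counts.

    Parameters
    ----------
    roi_ids
        Ordered ROI identifiers (length R).  Row order of every matrix in the
        pipeline follows this order.
    network_labels
        One of the seven canonical network labels per ROI.
    voxel_counts
        Strictly positive voxel count per ROI, used for voxel-number-weighted
        network means (ROIs differ in size).
    """

    roi_ids: tuple[str, ...]
    network_labels: tuple[str, ...]
    voxel_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        r = len(self.roi_ids)
        if len(self.network_labels) != r or len(self.voxel_counts) != r:
            raise ValidationError(
                f"parcellation fields must have equal length; got "
                f"{r} roi_ids, {len(self.network_labels)} labels, "
                f"{len(self.voxel_counts)} voxel counts"
            )
        if len(set(self.roi_ids)) != r:
            raise ValidationError("roi_ids must be unique")
        for i, lab in enumerate(self.network_labels):
            if lab not in NETWORKS:
                raise ValidationError(
                    f"row {i} (roi_id={self.roi_ids[i]!r}): unknown network "
                    f"label {lab!r}; allowed: {', '.join(NETWORKS)}"
                )
        for i, v in enumerate(self.voxel_counts):
            if int(v) <= 0:
                raise ValidationError(
                    f"row {i} (roi_id={self.roi_ids[i]!r}): voxel_count must "
                    f"be positive, got {v}"
                )

    @property
    def n_roi(self) -> int:
        return len(self.roi_ids)

    @property
    def networks_present(self) -> tuple[str, ...]:
        present = set(self.network_labels)
        return tuple(n for n in NETWORKS if n in present)

    def network_indices(self, network: str) -> np.ndarray:
        """Integer ROI indices belonging to ``network`` (parcellation order)."""
        labels = np.asarray(self.network_labels)
        return np.flatnonzero(labels == network)

    def voxel_weights(self) -> np.ndarray:
        return np.asarray(self.voxel_counts, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": list(self.roi_ids),
                "network": list(self.network_labels),
                "voxel_count": list(self.voxel_counts),
            }
        )


@dataclass
class RoiTimeSeries:
    """One subject's ROI-by-time matrix in acquisition order.

    ``data`` has shape (R, T); row order matches the parcellation.  The
    sampling interval is in seconds (1.0 for the emulated acquisition).
    """

    subject_id: str
    data: np.ndarray
    sampling_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"{self.subject_id}: time-series data must be 2-D, got "
                f"shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"{self.subject_id}: non-finite value at ROI row {bad[0]}, "
                f"sample {bad[1]}"
            )
        if self.sampling_interval_s <= 0:
            raise ValidationError("sampling_interval_s must be positive")

    @property
    def n_roi(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def total_s(self) -> float:
        return self.n_samples * self.sampling_interval_s


@dataclass
class SubjectTable:
    """Cohort metadata: one row per subject with group label and covariates.

    Required columns: ``subject_id`` (unique) and ``group``.  Any further
    numeric columns are treated as covariates (age, sex coded 0/1, education
    years, MoCA).  Group labels are free strings; the default cohort uses
    ``HC`` and ``TLE`` and remains extensible to left/right patient subgroups.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("subject_id", "group"):
            if col not in self.data.columns:
                raise ValidationError(f"subject table missing column {col!r}")
        ids = self.data["subject_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"])

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Dense (n_subjects, n_covariates) design block; errors on NaN."""
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"missing covariate columns: {missing}")
        mat = self.data[list(names)].to_numpy(dtype=float)
        if np.isnan(mat).any():
            raise ValidationError(
                "covariates must be complete for adjusted comparisons"
            )
        return mat

    def subjects_in(self, group: str) -> list[str]:
        return list(self.data.loc[self.data["group"] == group, "subject_id"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation table (columns roi_id, network, voxel_count).

    File row order is preserved and becomes the canonical ROI order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str})
    for col in ("roi_id", "network", "voxel_count"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return Parcellation(
        roi_ids=tuple(df["roi_id"].astype(str)),
        network_labels=tuple(df["network"].astype(str)),
        voxel_counts=tuple(int(v) for v in df["voxel_count"]),
    )


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    parcellation.to_frame().to_csv(path, sep="\t", index=False)


def read_timeseries(
    path: str | Path,
    parcellation: Parcellation,
    subject_id: str | None = None,
    orientation: str = "rois-in-rows",
    sampling_interval_s: float = 1.0,
) -> RoiTimeSeries:
    """Read one subject's ROI x time matrix and align it to the parcellation.

    Two layouts are accepted: a plain numeric matrix (no header) whose rows
    (or columns, with ``orientation='rois-in-columns'``) follow parcellation
    order, or a headed table whose first column is ``roi_id`` — in that case
    rows are reordered to parcellation order regardless of file row order.
    """
    if orientation not in ("rois-in-rows", "rois-in-columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    has_ids = first.split("\t")[0].strip() == "roi_id"
    if has_ids:
        df = pd.read_csv(path, sep="\t", dtype={"roi_id": str})
        df = df.set_index("roi_id")
        missing = [r for r in parcellation.roi_ids if r not in df.index]
        if missing:
            raise ValidationError(
                f"{path}: missing ROIs {missing[:5]} (and possibly more)"
            )
        mat = df.loc[list(parcellation.roi_ids)].to_numpy()
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        nonnum = df.apply(pd.to_numeric, errors="coerce")
        if nonnum.isna().any().any():
            r, c = np.argwhere(nonnum.isna().to_numpy())[0]
            raise ValidationError(
                f"{path}: non-numeric cell at row {r}, column {c}: "
                f"{df.iloc[r, c]!r}"
            )
        mat = nonnum.to_numpy(dtype=float)
        if orientation == "rois-in-columns":
            mat = mat.T
    if mat.shape[0] != parcellation.n_roi:
        raise ValidationError(
            f"{path}: matrix shape {mat.shape} does not match parcellation "
            f"with {parcellation.n_roi} ROIs"
        )
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeSeries(
        subject_id=sid, data=mat, sampling_interval_s=sampling_interval_s
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a plain ROI-in-rows numeric matrix (no header)."""
    pd.DataFrame(ts.data).to_csv(path, sep="\t", index=False, header=False)


def read_vector(path: str | Path, parcellation: Parcellation) -> np.ndarray:
    """Read a per-ROI vector (beta map or reference gradient).

    Expects columns ``roi_id`` and ``value``; rows are aligned to the
    parcellation order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str}).set_index("roi_id")
    if "value" not in df.columns:
        raise ValidationError(f"{path}: missing column 'value'")
    missing = [r for r in parcellation.roi_ids if r not in df.index]
    if missing:
        raise ValidationError(f"{path}: missing ROIs {missing[:5]}")
    return df.loc[list(parcellation.roi_ids), "value"].to_numpy(dtype=float)


def write_vector(
    values: np.ndarray, parcellation: Parcellation, path: str | Path
) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != (parcellation.n_roi,):
        raise ValidationError(
            f"vector length {values.shape} does not match parcellation "
            f"({parcellation.n_roi} ROIs)"
        )
    pd.DataFrame(
        {"roi_id": list(parcellation.roi_ids), "value": values}
    ).to_csv(path, sep="\t", index=False)


def read_subject_table(path: str | Path) -> SubjectTable:
    return SubjectTable(pd.read_csv(path, sep="\t", dtype={"subject_id": str}))


def write_subject_table(table: SubjectTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
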