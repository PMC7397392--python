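"""Readers and writers for the formats the pipeline consumes.

Physiological traces are plain delimited text with a header and two
numeric columns (time in seconds, conductance in microsiemens); event
schedules are tab-separated (onset, condition); volumes are NIfTI-1.
Units are never rescaled on the way in or out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError

CONDITIONS = ("word", "pseudoword")


@dataclass
class ScrTrace:
    """One subject's electrodermal time series.

    Parameters
    ----------
    samples : ndarray
        Conductance values in microsiemens, in temporal order.
    rate : float
        Sampling frequency in Hz, strictly positive.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.rate


@dataclass
class EventSchedule:
    """Ordered stimulus onsets with condition labels."""

    onsets: np.ndarray
    conditions: np.ndarray

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.onsets.size != self.conditions.size:
            raise ValueError("onsets and conditions differ in length")
        if np.any(np.diff(self.onsets) <= 0):
            raise FormatError("onsets must be strictly increasing")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition label(s): {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def count(self, condition: str) -> int:
        return int(np.sum(self.conditions == condition))

    @property
    def counts(self) -> dict:
        return {c: self.count(c) for c in CONDITIONS}


@dataclass
class VolumeMap:
    """A 3-D scalar field with a voxel-to-world affine and optional mask.

    World coordinates follow the RAS mm convention of the affine; voxel
    indices are 0-based.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")

    def voxel_to_world(self, idx) -> np.ndarray:
        """Map a 0-based voxel index to world (RAS) mm coordinates."""
        return nib.affines.apply_affine(self.affine, np.asarray(idx, dtype=float))


@dataclass
class SubjectTable:
    """Cohort manifest: one row per subject.

    Columns: subject_id, group in {healthy, patient}, gose (1-8, patients
    only), and optional physio/events/volume file paths.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("subject_id", "group")

    def __post_init__(self):
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"subject table missing column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise FormatError(f"duplicate subject_id(s): {dup}")
        bad = set(df["group"]) - {"healthy", "patient"}
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}")
        if "gose" in df.columns:
            pat = df["group"] == "patient"
            if df.loc[pat, "gose"].isna().any():
                raise FormatError("patients must carry a GOS-E score")
            if df.loc[~pat, "gose"].notna().any():
                raise FormatError("healthy subjects must not carry a GOS-E score")
        elif (df["group"] == "patient").any():
            raise FormatError("subject table with patients requires a gose column")

    def __len__(self) -> int:
        return len(self.table)


def read_physio(path, rate_override: float | None = None) -> ScrTrace:
    """Read a two-column (time s, conductance uS) delimited text file.

    The sampling rate is inferred from the median inter-sample interval
    unless ``rate_override`` is given. The time column must be strictly
    increasing.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty physio file: {path}") from exc
    except Exception as exc:  # delimiter sniffing fails on 1-column files
        raise FormatError(f"physio file needs 2 columns (time, conductance): {path}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"physio file needs 2 columns (time, conductance): {path}")
    if len(df) == 0:
        raise FormatError(f"physio file has no data rows: {path}")
    try:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        y = df.iloc[:, 1].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric physio columns in {path}") from exc
    if np.isnan(t).any() or np.isnan(y).any():
        raise FormatError(f"physio file needs 2 numeric columns (time, conductance): {path}")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"non-monotone time column in {path}")
    if rate_override is not None:
        rate = float(rate_override)
    elif t.size > 1:
        rate = 1.0 / float(np.median(np.diff(t)))
    else:
        raise FormatError("cannot infer rate from a single sample; pass rate_override")
    return ScrTrace(samples=y, rate=rate, start_time=float(t[0]))


def write_physio(trace: ScrTrace, path) -> None:
    """Write a trace as CSV with columns time_s, conductance_us."""
    pd.DataFrame(
        {"time_s": trace.times, "conductance_us": trace.samples}
    ).to_csv(path, index=False, float_format="%.10g")


def read_events(path) -> EventSchedule:
    """Read a tab-separated (onset, condition) schedule; rows are sorted
    by onset and condition labels validated against {word, pseudoword}."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "condition"):
        if col not in df.columns:
            raise FormatError(f"events file missing column {col!r}: {path}")
    df = df.sort_values("onset", kind="stable")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) == 0):
        raise FormatError(f"duplicate onsets in {path}")
    return EventSchedule(onsets=onsets, conditions=df["condition"].to_numpy(dtype=object))


def write_events(schedule: EventSchedule, path) -> None:
    pd.DataFrame({"onset": schedule.onsets, "condition": schedule.conditions}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_subject_table(path) -> SubjectTable:
    df = pd.read_csv(path, sep="\t")
    return SubjectTable(df)


def read_volume4d(path, tr_override: float | None = None):
    """Load a 4-D NIfTI.

    Returns ``(data, affine, tr)`` with TR in seconds taken from the
    header time step. Explicit ``tr_override`` takes precedence over the
    header (headers of synthetic or legacy files are unreliable).
    """
    img = nib.load(os.fspath(path))
    if img.ndim != 4:
        raise FormatError(f"expected a 4-D volume, got {img.ndim}-D: {path}")
    data = np.asarray(img.get_fdata(), dtype=float)
    if tr_override is not None:
        tr = float(tr_override)
    else:
        tr = float(img.header.get_zooms()[3])
        if not tr > 0:
            raise FormatError(
                f"TR missing/zero in header of {path}; pass an explicit TR override"
            )
    return data, np.asarray(img.affine, dtype=float), tr


def read_volume3d(path) -> VolumeMap:
    img = nib.load(os.fspath(path))
    if img.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {img.ndim}-D: {path}")
    return VolumeMap(data=np.asarray(img.get_fdata(), dtype=float), affine=img.affine)


def write_volume3d(vmap: VolumeMap, path) -> None:
    """Write a VolumeMap as NIfTI-1; data and affine round-trip bitwise
    (float64 on disk)."""
    img = nib.Nifti1Image(vmap.data.astype(np.float64), vmap.affine)
    nib.save(img, os.fspath(path))


def write_volume4d(data, affine, tr: float, path) -> None:
    data = np.asarray(data)
    img = nib.Nifti1Image(data.astype(np.float32), np.asarray(affine, dtype=float))
    zooms = list(img.header.get_zooms())
    zooms[3] = tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, os.fspath(path))
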