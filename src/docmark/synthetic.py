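"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the study design end to end so every pipeline
stage is testable without patient data:

* **Event schedules** — 30 emotionally salient words and 30 pseudo-words
  in seeded random order at a fixed 12-s onset-to-onset interval.
* **Electrodermal traces** — a tonic level with a slow random-walk
  drift, plus one phasic response per stimulus: a peak-normalised
  bi-exponential kernel (0.75 s rise, 4 s decay) delayed by ~2 s, whose
  amplitude is drawn per trial around a condition mean, floored at 0,
  plus white measurement noise. Healthy and outcome-positive subjects
  respond more strongly to words than pseudo-words; outcome-negative
  subjects show no condition difference.
* **GOS-E labels** — sampled uniformly within each outcome band
  (positive: 3-8, negative: 1-2) so the threshold classifier is
  exercised across its range.
* **Resting 4-D volumes** — AR(1) temporal noise inside an ellipsoidal
  brain mask, plus, inside a spherical blob, a low-frequency sinusoid
  whose amplitude is ``blob_amp_base + coupling * delta`` (floored at
  0), coupling each subject's SCR delta index to local low-frequency
  power as the analysis expects to recover.

Every artifact is fully determined by its parameter set and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import (
    EventSchedule,
    ScrTrace,
    SubjectTable,
    VolumeMap,
    write_events,
    write_physio,
    write_volume3d,
    write_volume4d,
)

POST_EVENT_PAD = 12.0  # s of trace kept after the last onset


@dataclass
class ScrGenParams:
    """Electrodermal trace generator settings.

    Amplitudes are in microsiemens; ``amp_sd`` is a fractional
    trial-to-trial spread (sd = amp_sd * condition mean, floored at 0);
    ``tonic_drift_sd`` is the random-walk increment scale in uS per
    sqrt(second). Defaults give subject delta indices around 0.3-0.5
    with between-subject spread ~0.25, matching the magnitude of
    published healthy-control values.
    """

    rate: float = 50.0
    latency_mean: float = 2.0
    tau1: float = 0.75
    tau2: float = 4.0
    amp_word: float = 0.30
    amp_pseudo: float = 0.20
    amp_sd: float = 0.8
    tonic_level: float = 2.0
    tonic_drift_sd: float = 0.02
    noise_sd: float = 0.05

    def __post_init__(self):
        if not (self.tau1 > 0 and self.tau2 > self.tau1):
            raise ValueError("need 0 < tau1 < tau2")
        if self.amp_word < 0 or self.amp_pseudo < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.rate <= 2.0 / self.tau1:
            raise ValueError("rate too low to resolve the kernel rise")


@dataclass
class BoldGenParams:
    """Resting 4-D volume generator settings."""

    shape: tuple = (16, 16, 16)
    n_vols: int = 200
    tr: float = 3.0
    ar_coef: float = 0.3
    noise_sd: float = 0.5
    blob_center: tuple = (8, 8, 8)
    blob_radius: float = 3.0
    blob_freq: float = 0.03
    blob_amp_base: float = 1.0
    coupling: float = 4.0

    def __post_init__(self):
        if not 0 < self.blob_freq < 1.0 / (2.0 * self.tr):
            raise ValueError("blob_freq must lie below Nyquist")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        lo = np.array(self.blob_center) - self.blob_radius
        hi = np.array(self.blob_center) + self.blob_radius
        if (lo < 0).any() or (hi >= np.array(self.shape)).any():
            raise ValueError("blob extends outside the volume")


@dataclass
class CohortSpec:
    """Study-scale cohort: healthy controls plus two patient outcome
    groups. Outcome-positive patients share the healthy response
    profile; outcome-negative patients show no word/pseudo-word
    difference."""

    n_healthy: int = 35
    n_positive: int = 10
    n_negative: int = 5
    healthy_scr: ScrGenParams = field(default_factory=ScrGenParams)
    positive_scr: ScrGenParams = field(default_factory=ScrGenParams)
    negative_scr: ScrGenParams = field(
        default_factory=lambda: ScrGenParams(amp_word=0.25, amp_pseudo=0.25)
    )
    bold: BoldGenParams = field(default_factory=BoldGenParams)
    # patients lose the baseline low-frequency blob amplitude and keep a
    # weaker delta-proportional residual, giving both a group deficit
    # (controls > patients) and a within-patient delta coupling
    patient_bold: BoldGenParams = field(
        default_factory=lambda: BoldGenParams(blob_amp_base=0.0, coupling=2.0)
    )
    seed: int = 0

    def __post_init__(self):
        if min(self.n_healthy, self.n_positive, self.n_negative) < 1:
            raise ValueError("every group needs at least 1 subject")


def generate_schedule(n_word: int = 30, n_pseudo: int = 30, isi: float = 12.0,
                      lead_in: float = 30.0, seed: int = 0) -> EventSchedule:
    """Fixed-interval schedule: onsets at lead_in + k*isi with a seeded
    uniform shuffle of the word/pseudo-word multiset."""
    if n_word < 1 or n_pseudo < 1:
        raise ValueError("need at least one event per condition")
    rng = np.random.default_rng(seed)
    labels = np.array(["word"] * n_word + ["pseudoword"] * n_pseudo, dtype=object)
    rng.shuffle(labels)
    onsets = lead_in + isi * np.arange(n_word + n_pseudo)
    return EventSchedule(onsets=onsets, conditions=labels)


def _phasic_kernel(t: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    """Bi-exponential kernel, peak-normalised to 1, zero for t < 0."""
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau2) - np.exp(-np.maximum(t, 0) / tau1), 0.0)
    t_peak = tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)
    peak = math.exp(-t_peak / tau2) - math.exp(-t_peak / tau1)
    return k / peak


def generate_scr_trace(schedule: EventSchedule, params: ScrGenParams,
                       seed: int = 0) -> ScrTrace:
    """Simulate one subject's electrodermal recording for a schedule."""
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(seed)
    rate = params.rate
    duration = float(schedule.onsets[-1]) + POST_EVENT_PAD
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate

    drift = np.cumsum(rng.normal(0.0, params.tonic_drift_sd / math.sqrt(rate), n))
    trace = params.tonic_level + drift

    for onset, cond in zip(schedule.onsets, schedule.conditions):
        mean_amp = params.amp_word if cond == "word" else params.amp_pseudo
        amp = max(0.0, mean_amp * (1.0 + params.amp_sd * rng.standard_normal()))
        if amp == 0.0:
            continue
        start = onset + params.latency_mean
        i0 = int(np.searchsorted(t, start))
        # kernel support truncated at 8 decay constants
        i1 = min(n, i0 + int(8 * params.tau2 * rate))
        trace[i0:i1] += amp * _phasic_kernel(t[i0:i1] - start, params.tau1, params.tau2)

    trace += rng.normal(0.0, params.noise_sd, n)
    return ScrTrace(samples=trace, rate=rate, start_time=0.0)


def _subject_seeds(master_seed: int, n: int) -> list:
    """Deterministic per-subject integer seeds below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def simulate_cohort(spec: CohortSpec) -> list:
    """In-memory cohort: list of dicts with subject_id, group, gose,
    schedule and trace. Deterministic given ``spec.seed``."""
    groups = (
        [("healthy", spec.healthy_scr, None)] * spec.n_healthy
        + [("patient", spec.positive_scr, "positive")] * spec.n_positive
        + [("patient", spec.negative_scr, "negative")] * spec.n_negative
    )
    n = len(groups)
    seeds = _subject_seeds(spec.seed, 3 * n)
    gose_rng = np.random.default_rng(np.random.SeedSequence(spec.seed).generate_state(3 * n + 1)[-1] % (2**31))
    subjects = []
    for i, (group, params, outcome) in enumerate(groups):
        schedule = generate_schedule(seed=seeds[3 * i])
        trace = generate_scr_trace(schedule, params, seed=seeds[3 * i + 1])
        if outcome == "positive":
            gose = int(gose_rng.integers(3, 9))
        elif outcome == "negative":
            gose = int(gose_rng.integers(1, 3))
        else:
            gose = None
        subjects.append(
            {
                "subject_id": f"sub-{i + 1:03d}",
                "group": group,
                "gose": gose,
                "schedule": schedule,
                "trace": trace,
                "bold_seed": seeds[3 * i + 2],
            }
        )
    return subjects


def generate_cohort(spec: CohortSpec, out_dir) -> SubjectTable:
    """Write a cohort to disk: per-subject physio CSV and events TSV
    plus a tab-separated manifest. Returns the manifest as a
    SubjectTable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in simulate_cohort(spec):
        sid = sub["subject_id"]
        physio = out / f"{sid}_physio.csv"
        events = out / f"{sid}_events.tsv"
        write_physio(sub["trace"], physio)
        write_events(sub["schedule"], events)
        rows.append(
            {
                "subject_id": sid,
                "group": sub["group"],
                "gose": np.nan if sub["gose"] is None else float(sub["gose"]),
                "physio_path": str(physio),
                "events_path": str(events),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return SubjectTable(df)


def ellipsoid_mask(shape, fraction: float = 0.9) -> np.ndarray:
    """Centered ellipsoidal brain mask with semi-axes fraction/2 of
    each dimension."""
    c = (np.array(shape) - 1) / 2.0
    r = np.array(shape) * fraction / 2.0
    grid = np.indices(shape)
    d2 = sum(((grid[k] - c[k]) / r[k]) ** 2 for k in range(3))
    return d2 <= 1.0


def _blob_mask(params: BoldGenParams) -> np.ndarray:
    grid = np.indices(params.shape)
    d2 = sum((grid[k] - params.blob_center[k]) ** 2 for k in range(3))
    return d2 <= params.blob_radius**2


def simulate_bold(delta: float, params: BoldGenParams, seed: int = 0,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """One subject's 4-D lattice: AR(1) noise in-mask plus a blob
    sinusoid at ``blob_freq`` with amplitude blob_amp_base +
    coupling*delta (floored at 0) and a seeded random phase."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = ellipsoid_mask(params.shape)
    blob = _blob_mask(params)
    if not mask[blob].all():
        raise ValueError("blob lies outside the brain mask")
    n_vox = int(mask.sum())
    phi = params.ar_coef
    innov_sd = params.noise_sd * math.sqrt(max(1e-12, 1.0 - phi * phi))
    white = rng.normal(0.0, innov_sd, (n_vox, params.n_vols))
    noise = lfilter([1.0], [1.0, -phi], white, axis=1)

    data = np.zeros(params.shape + (params.n_vols,))
    data[mask] = noise
    amp = max(0.0, params.blob_amp_base + params.coupling * delta)
    if amp > 0:
        tt = params.tr * np.arange(params.n_vols)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        data[blob & mask] += amp * np.sin(2.0 * math.pi * params.blob_freq * tt + phase)
    return data


def default_affine(voxel_mm: float = 3.0) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return aff


def generate_bold_dataset(deltas, params: BoldGenParams, out_dir,
                          seed: int = 0) -> dict:
    """Write per-subject 4-D NIfTIs plus the shared brain mask.

    Returns a dict with the volume paths, mask path, and the blob mask
    (ground truth for recovery checks).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = ellipsoid_mask(params.shape)
    affine = default_affine()
    seeds = _subject_seeds(seed, len(list(deltas)))
    paths = []
    for i, delta in enumerate(deltas):
        data = simulate_bold(delta, params, seed=seeds[i], mask=mask)
        p = out / f"sub-{i + 1:03d}_bold.nii.gz"
        write_volume4d(data, affine, params.tr, p)
        paths.append(str(p))
    mask_path = out / "brain_mask.nii.gz"
    write_volume3d(VolumeMap(data=mask.astype(float), affine=affine), mask_path)
    return {
        "volumes": paths,
        "mask": str(mask_path),
        "blob": _blob_mask(params) & mask,
        "affine": affine,
    }
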