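"""Event-related electrodermal scoring.

Each trial is scored peak-to-base: the maximum conductance in the 8 s
after stimulus onset minus the mean conductance of the 3 s baseline
before onset. Trial scores are z-normalised within subject, pooled
across both stimulus conditions, and summarised as the SCR delta index
(mean z of word trials minus mean z of pseudo-word trials) — the
subject-level prognostic marker.

Window conventions: the post-stimulus interval is open at the onset and
closed at onset + post_window; the baseline is closed at onset -
pre_window and open at the onset, so the onset sample never belongs to
both windows. Negative peak-to-base values are kept (z-scoring assumes
signed scores). The z-score uses the population (n-denominator)
standard deviation: trials form a fixed finite set, not a sample from a
superpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSubjectError, TrialWindowError
from .io import EventSchedule, ScrTrace, SubjectTable, read_events, read_physio

DEFAULT_PRE_WINDOW = 3.0
DEFAULT_POST_WINDOW = 8.0


@dataclass
class TrialScore:
    onset: float
    condition: str
    raw: float
    z: float | None = None


@dataclass
class SubjectScr:
    """Per-trial scores and condition summaries for one subject."""

    subject_id: str
    trials: list = field(default_factory=list)

    @property
    def raw(self) -> np.ndarray:
        return np.array([t.raw for t in self.trials], dtype=float)

    @property
    def z(self) -> np.ndarray:
        if any(t.z is None for t in self.trials):
            raise ValueError("z-scores not set; call znormalize first")
        return np.array([t.z for t in self.trials], dtype=float)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials], dtype=object)

    def mean_z(self, condition: str) -> float:
        sel = self.conditions == condition
        if not sel.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return float(self.z[sel].mean())

    @property
    def delta(self) -> float:
        return delta_index(self)


def score_trial(
    trace: ScrTrace,
    onset: float,
    pre_window: float = DEFAULT_PRE_WINDOW,
    post_window: float = DEFAULT_POST_WINDOW,
) -> float:
    """Raw peak-to-base score (microsiemens) for one stimulus onset.

    max over samples with time in (onset, onset + post_window] minus the
    mean over samples with time in [onset - pre_window, onset). May be
    negative.
    """
    t = trace.times
    if onset - pre_window < t[0] - 1e-9 or onset + post_window > t[-1] + 1e-9:
        raise TrialWindowError([onset])
    base = (t >= onset - pre_window - 1e-12) & (t < onset)
    post = (t > onset) & (t <= onset + post_window + 1e-12)
    if not base.any() or not post.any():
        raise TrialWindowError([onset], f"no samples in a window at onset {onset:g} s")
    return float(trace.samples[post].max() - trace.samples[base].mean())


def score_subject(
    trace: ScrTrace,
    schedule: EventSchedule,
    subject_id: str = "",
    pre_window: float = DEFAULT_PRE_WINDOW,
    post_window: float = DEFAULT_POST_WINDOW,
) -> SubjectScr:
    """Score every event in the schedule; order is preserved.

    All out-of-bounds onsets are collected and reported together.
    """
    bad = []
    trials = []
    for onset, cond in zip(schedule.onsets, schedule.conditions):
        try:
            raw = score_trial(trace, onset, pre_window, post_window)
        except TrialWindowError:
            bad.append(onset)
            continue
        trials.append(TrialScore(onset=float(onset), condition=str(cond), raw=raw))
    if bad:
        raise TrialWindowError(bad)
    return SubjectScr(subject_id=subject_id, trials=trials)


def znormalize(subject: SubjectScr) -> SubjectScr:
    """Set z-scores in place: (raw - mean) / population SD, pooled across
    both conditions. Raises DegenerateSubjectError on zero variance."""
    raw = subject.raw
    if raw.size < 2:
        raise ValueError("z-normalisation needs at least 2 trials")
    sd = float(raw.std(ddof=0))
    if sd == 0.0:
        raise DegenerateSubjectError(
            f"subject {subject.subject_id!r}: all trial scores identical"
        )
    mu = float(raw.mean())
    for t in subject.trials:
        t.z = (t.raw - mu) / sd
    return subject


def delta_index(subject: SubjectScr) -> float:
    """SCR delta index: mean z of word trials minus mean z of
    pseudo-word trials."""
    return subject.mean_z("word") - subject.mean_z("pseudoword")


def cohort_deltas(
    table: SubjectTable,
    pre_window: float = DEFAULT_PRE_WINDOW,
    post_window: float = DEFAULT_POST_WINDOW,
) -> tuple[pd.DataFrame, list]:
    """Score every subject in a cohort manifest.

    Returns a frame with columns (subject_id, group, gose, delta) for
    non-degenerate subjects, plus a list of subject ids flagged as
    degenerate (zero trial variance). Missing files raise with the
    offending path named.
    """
    rows = []
    degenerate = []
    for rec in table.table.itertuples(index=False):
        try:
            trace = read_physio(rec.physio_path)
            schedule = read_events(rec.events_path)
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"subject {rec.subject_id!r}: missing file {exc.filename}"
            ) from exc
        subj = score_subject(trace, schedule, subject_id=rec.subject_id,
                             pre_window=pre_window, post_window=post_window)
        try:
            znormalize(subj)
        except DegenerateSubjectError:
            degenerate.append(rec.subject_id)
            continue
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "gose": getattr(rec, "gose", np.nan),
                "delta": delta_index(subj),
            }
        )
    return pd.DataFrame(rows), degenerate
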