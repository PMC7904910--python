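"""Data model, file I/O and score computation for smartphone SDMT trials.

The smartphone test lets subjects answer for a configurable duration
(ultimately 75 s instead of the written test's 90 s), so raw correct-answer
counts are not comparable across durations.  All scores are therefore
rescaled to the conventional 90-second scale::

    score_90s = n_correct / duration_s * 90

Scores are carried unrounded through the pipeline; rounding to one decimal
happens only at serialization/report time, matching the reporting
convention of clinical SDMT scores.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COHORTS = ("HV", "PPMS", "SPMS", "RRMS", "MS")

#: canonical long-format trial table columns
TRIAL_COLUMNS = [
    "subject_id", "cohort", "sitting", "trial",
    "n_correct", "duration_s", "event_times",
]

#: wide per-subject covariate table columns
PROFILE_COLUMNS = [
    "subject_id", "cohort", "age", "gender", "written_sdmt", "app_sdmt",
    "pasat3", "bpfr", "t2ll", "dh_taps",
    "neurex_total", "neurex_cognitive", "neurex_dh_cerebellar",
    "neurex_upper_motor", "neurex_vision", "neurex_eye_movements",
    "neurex_brainstem", "edss", "combiwise",
]


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema; carries a
    row-by-row report in ``errors`` (list of (row_index, message))."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"row {i}: {m}" for i, m in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"invalid trial table: {lines}{more}")


@dataclass(frozen=True)
class TrialRecord:
    """One timed SDMT trial.

    Parameters
    ----------
    subject_id : opaque subject identifier.
    cohort : one of HV / PPMS / SPMS / RRMS (or pooled MS).
    sitting : 1-based test-sitting index.
    trial : trial number within the sitting (1 or 2).
    n_correct : number of correct symbol-digit matches.
    duration_s : total testing time in seconds (> 0).
    event_times : optional ordered times (s) of each correct answer,
        needed for duration-truncation analyses.
    """

    subject_id: str
    cohort: str
    sitting: int
    trial: int
    n_correct: int
    duration_s: float
    event_times: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.n_correct < 0:
            raise ValueError("n_correct must be >= 0")
        if self.event_times is not None:
            et = np.asarray(self.event_times, dtype=float)
            if et.size and (np.any(np.diff(et) < 0) or et[-1] > self.duration_s):
                raise ValueError(
                    "event_times must be non-decreasing and <= duration_s")

    @property
    def score_90s(self) -> float:
        return rescale_score(self.n_correct, self.duration_s)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject clinical and MRI covariates.

    ``bpfr`` is the brain parenchymal fraction (parenchymal volume over
    intracranial volume, a fraction in (0, 1)); ``t2ll`` the T2 lesion
    load expressed on the same volume-normalized scale; ``dh_taps`` the
    dominant-hand tap count from the companion smartphone tapping test.
    NeurEx subscores quantify the neurological-exam subsystems that
    plausibly contribute to a touch-based, visually guided test.
    """

    subject_id: str
    cohort: str
    age: float
    written_sdmt: float | None = None
    app_sdmt: float | None = None
    pasat3: float | None = None
    bpfr: float | None = None
    t2ll: float | None = None
    dh_taps: float | None = None
    neurex_total: float | None = None
    neurex_cognitive: float | None = None
    neurex_dh_cerebellar: float | None = None
    neurex_upper_motor: float | None = None
    neurex_vision: float | None = None
    neurex_eye_movements: float | None = None
    neurex_brainstem: float | None = None
    edss: float | None = None
    combiwise: float | None = None
    gender: str | None = None

    def __post_init__(self):
        if self.bpfr is not None and not (0 < self.bpfr < 1):
            raise ValueError(f"bpfr must lie in (0, 1), got {self.bpfr}")
        if self.edss is not None and not (0 <= self.edss <= 10):
            raise ValueError(f"edss must lie in [0, 10], got {self.edss}")


@dataclass(frozen=True)
class SittingScore:
    """Rescaled score selected for one sitting (trial 1, trial 2 or the
    mean of both trials)."""

    subject_id: str
    sitting: int
    score_90s: float
    source: str  # {"trial1", "trial2", "mean_of_trials"}


def rescale_score(n_correct, duration_s):
    """Rescale a correct-answer count to the 90-second SDMT scale.

    Accepts scalars or arrays; returns ``n_correct / duration_s * 90``
    unrounded.  Raises ``ValueError`` for non-positive durations.
    """
    n_correct = np.asarray(n_correct, dtype=float)
    duration_s = np.asarray(duration_s, dtype=float)
    if np.any(duration_s <= 0):
        raise ValueError("duration_s must be > 0")
    out = n_correct / duration_s * 90.0
    return float(out) if out.ndim == 0 else out


def truncate_trial(record: TrialRecord, cutoff_s: float) -> TrialRecord:
    """Re-derive a trial as if it had been stopped at ``cutoff_s`` seconds.

    Requires per-answer event times; the truncated count is the number of
    events at or before the cutoff.
    """
    if record.event_times is None:
        raise ValueError(
            "truncate_trial requires event_times; trial has none")
    if not (0 < cutoff_s <= record.duration_s):
        raise ValueError(
            f"cutoff_s must lie in (0, {record.duration_s}], got {cutoff_s}")
    et = np.asarray(record.event_times, dtype=float)
    kept = tuple(float(t) for t in et[et <= cutoff_s])
    return replace(record, n_correct=len(kept), duration_s=float(cutoff_s),
                   event_times=kept)


def apply_bias_correction(scores, bias_points: float):
    """Shift scores by a constant bias (e.g. +7.8 points to app scores to
    compensate for the systematic written-test advantage).  Order
    preserving by construction."""
    scores = np.asarray(scores, dtype=float)
    out = scores + float(bias_points)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV I/O — canonical long trials table and wide profiles table

def _encode_events(ev) -> str:
    if ev is None or (isinstance(ev, float) and np.isnan(ev)):
        return ""
    return ";".join(format(float(t), "g") for t in ev)


def _decode_events(s):
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return None
    return tuple(float(t) for t in str(s).split(";"))


def write_trials(table: pd.DataFrame, path) -> None:
    """Write the canonical long-format trials CSV (UTF-8, header,
    semicolon-joined event times)."""
    df = table.copy()
    if "event_times" not in df.columns:
        df["event_times"] = None
    df["event_times"] = df["event_times"].map(_encode_events)
    df = df[TRIAL_COLUMNS]
    out = df.copy()
    out["duration_s"] = out["duration_s"].map(lambda v: format(float(v), "g"))
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate the canonical trials CSV.

    Returns a DataFrame with parsed ``event_times`` tuples (or None).
    Schema violations are collected row-by-row and raised together as a
    :class:`TrialValidationError`.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns
               and c != "event_times"]
    if missing:
        raise TrialValidationError(
            [(-1, f"missing mandatory column(s): {', '.join(missing)}")])
    if "event_times" not in df.columns:
        df["event_times"] = None
    errors: list[tuple[int, str]] = []
    for col in ("sitting", "trial", "n_correct", "duration_s"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        errors.extend((int(i), f"non-numeric {col}: {df.loc[i, col]!r}")
                      for i in bad)
        df[col] = coerced
    for i in df.index[df["duration_s"] <= 0].difference(
            df.index[df["duration_s"].isna()]):
        errors.append((int(i), f"duration_s must be > 0, got "
                               f"{df.loc[i, 'duration_s']}"))
    for i in df.index[df["n_correct"] < 0]:
        errors.append((int(i), "n_correct must be >= 0"))
    dup = df.duplicated(subset=["subject_id", "sitting", "trial"], keep=False)
    for i in df.index[dup]:
        errors.append((int(i), "duplicate (subject_id, sitting, trial)"))
    if errors:
        raise TrialValidationError(sorted(set(errors)))
    df["event_times"] = df["event_times"].map(_decode_events)
    df["sitting"] = df["sitting"].astype(int)
    df["trial"] = df["trial"].astype(int)
    df["n_correct"] = df["n_correct"].astype(int)
    df["duration_s"] = df["duration_s"].astype(float)
    return df[TRIAL_COLUMNS]


def write_profiles(table: pd.DataFrame, path) -> None:
    cols = [c for c in PROFILE_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise TrialValidationError([(-1, "missing column subject_id")])
    return df


# ---------------------------------------------------------------------------
# Sitting-level score selection

def sitting_scores(trials: pd.DataFrame, policy: str = "trial1") -> pd.DataFrame:
    """Collapse per-trial records into one rescaled score per sitting.

    policy
        ``"trial1"`` (default) takes trial 1; ``"trial2"`` takes trial 2;
        ``"mean"`` averages the rescaled scores of all trials in the
        sitting.  Cross-sectional analyses conventionally use the first
        sitting's trial 1.
    """
    if policy not in ("trial1", "trial2", "mean"):
        raise ValueError(f"unknown sitting policy {policy!r}")
    df = trials.copy()
    df["score_90s"] = rescale_score(df["n_correct"].to_numpy(),
                                    df["duration_s"].to_numpy())
    if policy in ("trial1", "trial2"):
        want = 1 if policy == "trial1" else 2
        out = df[df["trial"] == want]
        source = policy
    else:
        out = (df.groupby(["subject_id", "cohort", "sitting"], as_index=False)
                 ["score_90s"].mean())
        source = "mean_of_trials"
    out = out[["subject_id", "cohort", "sitting", "score_90s"]].copy()
    out["source"] = source
    return out.reset_index(drop=True)


def first_sitting_scores(trials: pd.DataFrame,
                         policy: str = "trial1") -> pd.DataFrame:
    """Scores from each subject's first observed sitting (the
    cross-sectional slice of a longitudinal table)."""
    scores = sitting_scores(trials, policy=policy)
    first = scores.groupby("subject_id")["sitting"].transform("min")
    return scores[scores["sitting"] == first].reset_index(drop=True)


def round_scores(df: pd.DataFrame, columns: Iterable[str],
                 decimals: int = 1) -> pd.DataFrame:
    """Report-time rounding (1 decimal by convention)."""
    out = df.copy()
    for c in columns:
        out[c] = out[c].round(decimals)
    return out
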