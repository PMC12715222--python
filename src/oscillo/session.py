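"""Map behavioral protocol structure onto signal time.

A fear-extinction retrieval session is a 180 s baseline followed by 40
tones of 30 s separated by 5 s inter-trial intervals (ITIs).  This module
segments continuous traces by labeled intervals, assigns trials to the
early / intermediate / late extinction stages (trials 1-13, 14-26, 27-39;
trial 40 excluded), and aggregates per-segment measures per condition.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SignalTrace, ValidationError

SESSION_KINDS = (
    "conditioning",
    "context_extinction",
    "tone_extinction",
    "retrieval",
    "open_field",
)

_LABEL_RE = re.compile(
    r"^(baseline|tone_\d+|iti_\d+|shock_\d+|center|periphery)$"
)


@dataclass(frozen=True)
class Interval:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValidationError(
                f"interval {self.label}: start must be < end "
                f"({self.start_s} >= {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class EventSchedule:
    """Ordered, non-overlapping labeled time intervals."""

    intervals: tuple[Interval, ...]
    session_kind: str = "retrieval"

    def __post_init__(self) -> None:
        if self.session_kind not in SESSION_KINDS:
            raise ValidationError(f"unknown session_kind {self.session_kind!r}")
        ivs = tuple(
            iv if isinstance(iv, Interval) else Interval(*iv) for iv in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        for iv in ivs:
            if not _LABEL_RE.match(iv.label):
                raise ValidationError(f"label {iv.label!r} outside controlled vocabulary")
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-12:
                raise ValidationError(f"intervals {a.label} and {b.label} overlap")

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_duration_s(self) -> float:
        return sum(iv.duration_s for iv in self.intervals)

    @property
    def end_s(self) -> float:
        return self.intervals[-1].end_s if self.intervals else 0.0

    def select(self, pattern: str) -> tuple[Interval, ...]:
        """Intervals whose label matches a glob pattern (e.g. ``tone_*``)."""
        return tuple(iv for iv in self.intervals if fnmatch.fnmatch(iv.label, pattern))

    def labels(self) -> tuple[str, ...]:
        return tuple(iv.label for iv in self.intervals)

    # -- CSV dialect: header ``label,start_s,end_s``, exact round-trip --
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(iv.label, repr(iv.start_s), repr(iv.end_s)) for iv in self.intervals],
            columns=["label", "start_s", "end_s"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, session_kind: str = "retrieval") -> "EventSchedule":
        df = pd.read_csv(path)
        required = {"label", "start_s", "end_s"}
        if not required.issubset(df.columns):
            raise ValidationError(f"schedule CSV must have columns {sorted(required)}")
        ivs = tuple(
            Interval(str(r.label), float(r.start_s), float(r.end_s))
            for r in df.itertuples(index=False)
        )
        return cls(ivs, session_kind=session_kind)


@dataclass(frozen=True)
class StageAssignment:
    trial_index: int
    stage: str  # early | intermediate | late | excluded


STAGES = ("early", "intermediate", "late")


def stage_of_trial(k: int, n_trials: int = 40) -> str:
    """Extinction stage of 1-based trial ``k``.

    For the canonical 40-trial protocol: trials 1-13 are ``early``, 14-26
    ``intermediate``, 27-39 ``late`` and trial 40 is ``excluded``.  Other
    trial counts fall back to thirds with the remainder trials excluded
    from the end.
    """
    if not 1 <= k <= n_trials:
        raise ValidationError(f"trial index {k} outside 1..{n_trials}")
    if n_trials == 40:
        per_stage = 13
    else:
        per_stage = n_trials // 3
        if per_stage == 0:
            return "excluded"
    if k > 3 * per_stage:
        return "excluded"
    return STAGES[(k - 1) // per_stage]


def segment(
    trace: SignalTrace, schedule: EventSchedule, selector: str = "*"
) -> list[SignalTrace]:
    """Cut a trace into per-interval sub-traces.

    Interval boundaries are half-open ``[start, end)``: the start is mapped
    to the nearest sample and the length is ``floor(duration * rate)``
    samples, so adjacent tone/ITI segments never share a sample.
    """
    fs = trace.sampling_rate_hz
    out: list[SignalTrace] = []
    for iv in schedule.select(selector):
        i0 = int(round((iv.start_s - trace.t0) * fs))
        n = int(np.floor(iv.duration_s * fs + 1e-9))
        if i0 < 0 or i0 + n > trace.n_samples:
            raise ValidationError(
                f"interval {iv.label} [{iv.start_s}, {iv.end_s}) s outside trace span"
            )
        sub = SignalTrace(
            trace.samples[i0 : i0 + n],
            fs,
            t0=iv.start_s,
            provenance=trace.provenance + (f"segment({iv.label})",),
        )
        out.append(sub)
    return out


def trial_index_of(label: str) -> int | None:
    """1-based trial index encoded in a ``tone_k`` / ``iti_k`` label."""
    m = re.match(r"^(?:tone|iti|shock)_(\d+)$", label)
    return int(m.group(1)) if m else None


def aggregate_condition(
    values: pd.DataFrame,
    grouping: str = "whole_session",
    n_trials: int = 40,
) -> pd.DataFrame:
    """Aggregate per-segment measures into per-condition summaries.

    Parameters
    ----------
    values
        Tidy frame with columns ``label``, ``value`` and optionally
        ``condition`` (defaults to the label stripped of its trial index).
    grouping
        ``whole_session`` pools all trials per condition; ``by_stage``
        additionally splits by extinction stage, dropping excluded trials.

    Returns
    -------
    One row per (condition, stage-or-'all') with mean, standard deviation
    and n.
    """
    if grouping not in ("whole_session", "by_stage"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    df = values.copy()
    if "condition" not in df.columns:
        df["condition"] = df["label"].str.replace(r"_\d+$", "", regex=True)
    if grouping == "by_stage":
        trial = df["label"].map(lambda s: trial_index_of(s))
        df["stage"] = [
            stage_of_trial(k, n_trials) if k is not None else "all" for k in trial
        ]
        df = df[df["stage"] != "excluded"]
    else:
        df["stage"] = "all"
    out = (
        df.groupby(["condition", "stage"], sort=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out
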