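"""Event schedules and event-aligned quantification of %dF/F traces.

Traces are time-locked to behavioural events (food presentation, eating
onset, food removal), baseline-normalised per trial, and summarised as
window means aggregated per animal first and per group second — the order
used when figure panels report "n = N mice per group".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from arcpipe.errors import AlignmentError, ConfigurationError, DegenerateInputError
from arcpipe.photometry import DffTrace

#: Event labels understood by the aligner.
EVENT_LABELS = ("presentation", "eating_onset", "removal", "stim_on", "stim_off")

#: Behavioural paradigms the generator can emulate.
PARADIGMS = (
    "inedible_tube",
    "chow",
    "peanut_butter",
    "caged_chow",
    "removal_2min",
    "removal_10min",
)

#: Paradigms in which the food is accessible, so an eating onset can occur.
ACCESSIBLE_PARADIGMS = ("chow", "peanut_butter", "removal_2min", "removal_10min")


@dataclass(frozen=True)
class EventSchedule:
    """Timestamped labelled events for one recording session.

    ``events`` is a sequence of ``(time_s, label)`` pairs with strictly
    increasing times; ``paradigm`` names the behavioural design.
    """

    events: tuple[tuple[float, str], ...]
    paradigm: str

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ConfigurationError(f"unknown paradigm {self.paradigm!r}; known: {PARADIGMS}")
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigurationError("event times must be strictly increasing")
        for _, label in self.events:
            if label not in EVENT_LABELS:
                raise ConfigurationError(f"unknown event label {label!r}")

    def times(self, label: str) -> np.ndarray:
        """All event times (s) carrying ``label``, in order."""
        return np.array([t for t, lab in self.events if lab == label], dtype=float)

    def first(self, label: str) -> float | None:
        t = self.times(label)
        return float(t[0]) if t.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["time_s", "label"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, paradigm: str) -> "EventSchedule":
        pairs = tuple((float(r.time_s), str(r.label)) for r in df.itertuples())
        return cls(events=pairs, paradigm=paradigm)


@dataclass
class AlignedTrials:
    """Trial x time matrix of %dF/F time-locked to one event class.

    ``relative_time`` spans ``[-pre_s, +post_s]`` with t = 0 at the event
    sample; each row has been baseline-normalised according to
    ``baseline_mode`` over ``baseline_window``. Trials without full window
    coverage are excluded and counted in ``n_excluded``.
    """

    relative_time: np.ndarray
    matrix: np.ndarray
    baseline_window: tuple[float, float]
    baseline_mode: str
    event_label: str
    event_times: np.ndarray
    n_excluded: int = 0

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    def mean_trace(self) -> np.ndarray:
        """Across-trial average trace (the PSTH)."""
        return self.matrix.mean(axis=0)


@dataclass
class WindowStat:
    """Per-unit window means with their group aggregate.

    Units are trials (single-animal use) or animals (group use); per-unit
    means are always computed before aggregation.
    """

    window: tuple[float, float]
    per_unit: np.ndarray
    mean: float
    sem: float
    n: int

    def to_dict(self) -> dict:
        return {
            "t0": self.window[0],
            "t1": self.window[1],
            "mean": self.mean,
            "sem": self.sem,
            "n": self.n,
        }


@dataclass
class EpochComparison:
    """Paired cue-epoch vs consumption-epoch means for one animal."""

    pre_eating_mean: float
    eating_mean: float
    pre_window: tuple[float, float]
    eating_window: tuple[float, float]
    n_trimmed_samples: int = 0


def _window_mask(relative_time: np.ndarray, t0: float, t1: float) -> np.ndarray:
    # left-closed, right-open: t0 <= t < t1
    return (relative_time >= t0) & (relative_time < t1)


def align_trials(
    trace: DffTrace,
    events: EventSchedule | Sequence[tuple[float, str]],
    label: str,
    pre_s: float,
    post_s: float,
    baseline_window: tuple[float, float] = (-60.0, 0.0),
    baseline_mode: str = "subtract_mean",
) -> AlignedTrials:
    """Extract per-event trace segments on a common relative timebase.

    Events are aligned to the nearest sample (no interpolation). Segments
    that do not fully cover ``[-pre_s, +post_s]`` are excluded and counted.
    ``baseline_mode`` is ``subtract_mean`` (default), ``zscore`` or ``none``.
    """
    if baseline_mode not in ("subtract_mean", "zscore", "none"):
        raise ConfigurationError(f"unknown baseline_mode {baseline_mode!r}")
    if isinstance(events, EventSchedule):
        ev_times = events.times(label)
    else:
        ev_times = np.array([t for t, lab in events if lab == label], dtype=float)

    time = trace.time
    fs = trace.sampling_rate
    n = len(time)
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    rel_time = np.arange(-n_pre, n_post + 1) / fs

    rows, used_times, n_excluded = [], [], 0
    for t_ev in ev_times:
        i0 = int(round((t_ev - time[0]) * fs))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi >= n:
            n_excluded += 1
            continue
        if not rows:
            # anchor the relative grid on the recording's own timebase so
            # window boundaries stay exact at representable times
            rel_time = time[lo : hi + 1] - time[i0]
        rows.append(trace.dff[lo : hi + 1])
        used_times.append(t_ev)

    if not rows:
        raise AlignmentError(
            f"no usable {label!r} events: {len(ev_times)} found, "
            f"{n_excluded} excluded for incomplete [-{pre_s}, +{post_s}] s coverage"
        )

    matrix = np.asarray(rows, dtype=float)
    if baseline_mode != "none":
        mask = _window_mask(rel_time, *baseline_window)
        if not mask.any():
            raise ConfigurationError("baseline window contains no samples")
        base_mean = matrix[:, mask].mean(axis=1, keepdims=True)
        matrix = matrix - base_mean
        if baseline_mode == "zscore":
            base_sd = matrix[:, mask].std(axis=1, ddof=1, keepdims=True)
            if np.any(base_sd == 0):
                raise DegenerateInputError("zero baseline s.d.; cannot z-score")
            matrix = matrix / base_sd

    return AlignedTrials(
        relative_time=rel_time,
        matrix=matrix,
        baseline_window=baseline_window,
        baseline_mode=baseline_mode,
        event_label=label,
        event_times=np.asarray(used_times),
        n_excluded=n_excluded,
    )


def window_mean(
    aligned: AlignedTrials, windows: Sequence[tuple[float, float]]
) -> list[WindowStat]:
    """Per-trial means over each left-closed window, with mean +/- s.e.m."""
    out = []
    for t0, t1 in windows:
        mask = _window_mask(aligned.relative_time, t0, t1)
        if not mask.any():
            raise ConfigurationError(f"window ({t0}, {t1}) s contains no samples")
        per_unit = aligned.matrix[:, mask].mean(axis=1)
        n = per_unit.size
        sem = float(per_unit.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        out.append(WindowStat((t0, t1), per_unit, float(per_unit.mean()), sem, n))
    return out


def group_window_stats(
    aligned_by_animal: Mapping[str, AlignedTrials],
    windows: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Aggregate window means per animal first, then across animals.

    Each animal contributes the mean of its own trial means, so unbalanced
    trial counts do not bias the group mean. Returns a tidy frame with one
    row per (animal, window) plus group rows (animal = "__group__").
    """
    records = []
    group_vals: dict[tuple[float, float], list[float]] = {w: [] for w in windows}
    for animal, aligned in aligned_by_animal.items():
        for stat in window_mean(aligned, windows):
            records.append(
                {"animal": animal, "t0": stat.window[0], "t1": stat.window[1],
                 "mean_dff": stat.mean, "n_trials": stat.n}
            )
            group_vals[stat.window].append(stat.mean)
    for (t0, t1), vals in group_vals.items():
        arr = np.asarray(vals)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
        records.append(
            {"animal": "__group__", "t0": t0, "t1": t1,
             "mean_dff": float(arr.mean()), "n_trials": arr.size, "sem": sem}
        )
    return pd.DataFrame(records)


def epoch_compare(
    trace: DffTrace,
    presentation: float,
    eating_onset: float,
    epoch_len_s: float = 60.0,
) -> EpochComparison:
    """Mean %dF/F in the cue epoch vs the consumption epoch.

    Cue epoch is ``[presentation, eating_onset)``; consumption epoch is
    ``[eating_onset, eating_onset + epoch_len_s)``, trimmed (with a counted
    warning) if it overruns the recording.
    """
    if eating_onset <= presentation:
        raise ConfigurationError("eating_onset must be strictly after presentation")
    time = trace.time
    pre_mask = (time >= presentation) & (time < eating_onset)
    eat_end = eating_onset + epoch_len_s
    eat_mask = (time >= eating_onset) & (time < eat_end)
    if not pre_mask.any() or not eat_mask.any():
        raise AlignmentError("an epoch contains no samples within the recording")
    n_trimmed = 0
    if eat_end > time[-1] + 0.5 / trace.sampling_rate:
        n_trimmed = int(round((eat_end - time[-1]) * trace.sampling_rate))
    return EpochComparison(
        pre_eating_mean=float(trace.dff[pre_mask].mean()),
        eating_mean=float(trace.dff[eat_mask].mean()),
        pre_window=(presentation, eating_onset),
        eating_window=(eating_onset, min(eat_end, float(time[-1]))),
        n_trimmed_samples=n_trimmed,
    )
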