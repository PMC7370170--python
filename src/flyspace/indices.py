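"""Scalar behavioral assay indices.

Implements the standard group-assay scores for fly behavior batteries:

* **aggregation (sociability) index** — sample variance of per-compartment
  fly counts divided by their mean; 0 for a perfectly even spread, maximal
  when every fly sits in one compartment (16 for 16 flies in 8
  compartments, where the variance extremes are 0 and 32);
* **performance index (PI)** for a two-vial odorant-avoidance choice —
  (flies in the air vial − flies in the odorant vial) / total flies loaded,
  in [−1, 1], higher meaning stronger avoidance;
* **climbing percent** for startle-induced negative geotaxis — percent of
  flies reaching the top vial;
* **total aggression duration** — summed duration of scored aggressive
  events across both flies in an arena (per displayed behavior, not a
  wall-clock union);
* **activity summary** — total and per-minute mean beam crossings over a
  30-minute monitor record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentCounts",
    "ChoiceTrial",
    "ClimbingTrial",
    "EventLog",
    "ActivityRecord",
    "AGGRESSION_BEHAVIORS",
    "aggregation_index",
    "aggregation_index_range",
    "performance_index",
    "climbing_percent",
    "total_event_duration",
    "activity_summary",
    "read_event_log",
]

#: Ethogram of aggressive behaviors scored in paired-fly arenas.
AGGRESSION_BEHAVIORS = frozenset(
    {
        "wing threat",
        "lunging",
        "high-level fencing",
        "charging",
        "holding",
        "boxing",
        "tussling",
    }
)

#: Minutes in a standard activity-monitor test period.
ACTIVITY_MINUTES = 30


@dataclass
class CompartmentCounts:
    """Per-compartment fly counts from one sociability chamber."""

    counts: np.ndarray
    chamber_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or len(c) < 2:
            raise ValueError("need counts for >= 2 compartments")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if np.any(c != np.floor(c)) or np.any(c < 0):
                raise ValueError("counts must be non-negative integers")
            c = c.astype(int)
        self.counts = c.astype(int)

    @property
    def n_flies(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ChoiceTrial:
    """Two-vial choice outcome; non-choosers stay in the total."""

    n_air: int
    n_dso: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_air, self.n_dso) < 0:
            raise ValueError("vial counts must be >= 0")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if self.n_air + self.n_dso > self.n_total:
            raise ValueError("n_air + n_dso exceeds the number of flies loaded")


@dataclass(frozen=True)
class ClimbingTrial:
    """Startle-induced climbing outcome."""

    n_top: int
    n_total: int = 40

    def __post_init__(self) -> None:
        if not 0 <= self.n_top <= self.n_total:
            raise ValueError("need 0 <= n_top <= n_total")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")


@dataclass
class EventLog:
    """Scored behavioral events for one paired-fly arena.

    ``events`` rows are (behavior label, start s, stop s, fly id).
    """

    events: list[tuple[str, float, float, str]] = field(default_factory=list)
    arena_id: str = ""
    observation_length: float = 1200.0

    def __post_init__(self) -> None:
        for label, start, stop, _fly in self.events:
            if stop <= start:
                raise ValueError(f"event '{label}' has stop <= start ({start}-{stop})")
            if start < 0 or stop > self.observation_length:
                raise ValueError(
                    f"event '{label}' ({start}-{stop} s) outside the "
                    f"{self.observation_length} s observation window"
                )


@dataclass
class ActivityRecord:
    """Per-minute beam-crossing counts for one fly over 30 minutes."""

    counts: np.ndarray
    fly_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if len(c) != ACTIVITY_MINUTES:
            raise ValueError(
                f"expected {ACTIVITY_MINUTES} per-minute counts, got {len(c)}"
            )
        if np.any(c < 0) or np.any(c != np.floor(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(int)


# ---------------------------------------------------------------------------
# Index formulas
# ---------------------------------------------------------------------------

def aggregation_index(cc: CompartmentCounts) -> float:
    """Sociability aggregation index: sample variance / mean of counts.

    The variance uses the n−1 (sample) denominator, so 16 flies packed
    into one of 8 compartments give variance 32 and index 16, while a
    perfectly even spread gives 0.
    """
    counts = cc.counts
    mean = counts.mean()
    if mean == 0:
        raise ValueError("no flies loaded: all compartment counts are zero")
    return float(np.var(counts, ddof=1) / mean)


def aggregation_index_range(n_flies: int, n_compartments: int) -> tuple[float, float]:
    """(min, max) attainable aggregation index for a chamber layout.

    The minimum is attained by the most even integer split, the maximum by
    the all-in-one-compartment allocation.
    """
    if n_flies < 1 or n_compartments < 2:
        raise ValueError("need n_flies >= 1 and n_compartments >= 2")
    q, r = divmod(n_flies, n_compartments)
    even = np.array([q + 1] * r + [q] * (n_compartments - r))
    packed = np.array([n_flies] + [0] * (n_compartments - 1))
    mean = n_flies / n_compartments
    return (
        float(np.var(even, ddof=1) / mean),
        float(np.var(packed, ddof=1) / mean),
    )


def performance_index(t: ChoiceTrial) -> float:
    """Avoidance PI: (n_air − n_dso) / n_total, in [−1, 1]."""
    return (t.n_air - t.n_dso) / t.n_total


def climbing_percent(t: ClimbingTrial) -> float:
    """Percent of flies reaching the top vial."""
    return 100.0 * t.n_top / t.n_total


def total_event_duration(
    log: EventLog,
    labels: Iterable[str] = AGGRESSION_BEHAVIORS,
) -> float:
    """Total duration (s) of events whose label is in ``labels``.

    Events are summed individually across both flies: simultaneous
    behaviors by the two flies both count, because the measure is the
    duration of displayed behavior, not occupied wall-clock time.
    """
    labels = set(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    present = {label for label, *_ in log.events}
    unknown = labels - AGGRESSION_BEHAVIORS - present
    if unknown:
        warnings.warn(
            f"labels {sorted(unknown)} are neither in the aggression "
            f"ethogram {sorted(AGGRESSION_BEHAVIORS)} nor in the log",
            UserWarning,
            stacklevel=2,
        )
    return float(
        sum(stop - start for label, start, stop, _fly in log.events if label in labels)
    )


def activity_summary(rec: ActivityRecord) -> tuple[int, float]:
    """(total crossings, per-minute mean) for one fly's activity record."""
    total = int(rec.counts.sum())
    return total, total / len(rec.counts)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_BORIS_COLUMN_ALIASES = {
    "behavior": "behavior",
    "behaviour": "behavior",
    "subject": "subject",
    "start": "start",
    "start (s)": "start",
    "stop": "stop",
    "stop (s)": "stop",
}


def read_event_log(
    source: str | pd.DataFrame,
    arena_id: str = "",
    observation_length: float = 1200.0,
) -> EventLog:
    """Read a scored-event table in a minimal BORIS-style export dialect.

    Accepts a CSV path or DataFrame with (case-insensitive) columns
    ``behavior``, ``subject``, ``start``, ``stop`` (``Start (s)`` /
    ``Stop (s)`` variants allowed).
    """
    df = pd.read_csv(source) if isinstance(source, str) else source
    renames = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _BORIS_COLUMN_ALIASES:
            renames[col] = _BORIS_COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    missing = {"behavior", "subject", "start", "stop"} - set(df.columns)
    if missing:
        raise ValueError(f"event log is missing columns: {sorted(missing)}")
    events = [
        (str(r.behavior), float(r.start), float(r.stop), str(r.subject))
        for r in df.itertuples()
    ]
    return EventLog(events=events, arena_id=arena_id, observation_length=observation_length)
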