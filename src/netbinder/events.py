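"""Final-docking trajectory analytics: distance series and event start times.

Given a frame-ordered pose ensemble with frame times, this module extracts
per-frame distance series — either between two selected atoms (hydrogen
bond/salt bridge proxies) or between a pose's center of mass and a fixed
reference pose (the d_D trace) — and detects when each structural change
settles.

The event-start rule is sustained stability: the final value is the mean
over a terminal window (100 ns by default), and the event starts at the
earliest time after which the signal never again leaves ±tolerance (1.0 Å
by default) of that final value.  A transient excursion into the band does
not count; the last sustained entry wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pooling import compute_dD
from .structures import PoseEnsemble, Selector, Structure, atom_pair_distance

__all__ = [
    "DistanceSeries",
    "EventRecord",
    "EventSpec",
    "distance_series",
    "detect_event_start",
    "event_table",
]

DEFAULT_TOLERANCE = 1.0        # Å
DEFAULT_TERMINAL_WINDOW = 100.0  # ns


@dataclass
class DistanceSeries:
    """A labelled per-frame distance trace.

    ``time_unit`` is "ns" when frame times were supplied and "frame" when
    unit-spaced indices were substituted.
    """

    label: str
    times: np.ndarray
    values: np.ndarray
    time_unit: str = "ns"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({f"time_{self.time_unit}": self.times,
                             "distance_A": self.values})

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EventRecord:
    """A detected structural-change event."""

    label: str
    start_time: float       # same unit as the series
    value_at_start: float   # Å
    final_value: float      # Å, mean over the terminal window
    reference_value: float | None = None  # Å, from an experimental structure


@dataclass(frozen=True)
class EventSpec:
    """Configuration of one monitored distance: label, two atom selectors and
    a stability tolerance (Å)."""

    label: str
    sel_a: str | Selector
    sel_b: str | Selector
    tolerance: float = DEFAULT_TOLERANCE


def _series_times(ensemble: PoseEnsemble) -> tuple[np.ndarray, str]:
    if ensemble.frame_times is not None:
        return ensemble.frame_times, "ns"
    return np.arange(len(ensemble), dtype=float), "frame"


def distance_series(ensemble: PoseEnsemble,
                    sel_a: str | Selector | None = None,
                    sel_b: str | Selector | None = None,
                    mode: str = "atom-pair",
                    reference: Structure | None = None,
                    label: str = "") -> DistanceSeries:
    """Per-frame distance trace over an ensemble.

    ``mode="atom-pair"`` measures the distance between the two selected atoms
    in every frame; ``mode="com-to-reference"`` measures d_D of each frame
    against a fixed ``reference`` pose.
    """
    times, unit = _series_times(ensemble)
    if mode == "atom-pair":
        if sel_a is None or sel_b is None:
            raise ValueError("atom-pair mode needs both selectors")
        values = [atom_pair_distance(p, sel_a, sel_b) for p in ensemble]
        label = label or f"{sel_a}-{sel_b}"
    elif mode == "com-to-reference":
        if reference is None:
            raise ValueError("com-to-reference mode needs a reference pose")
        values = [compute_dD(p, reference) for p in ensemble]
        label = label or "d_D"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceSeries(label=label, times=times,
                          values=np.asarray(values), time_unit=unit)


def detect_event_start(series: DistanceSeries,
                       tolerance: float = DEFAULT_TOLERANCE,
                       terminal_window: float = DEFAULT_TERMINAL_WINDOW
                       ) -> EventRecord:
    """Earliest time after which the trace stays within ±tolerance of its
    terminal-window mean for the rest of the series."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if series.span < terminal_window:
        raise ValueError(
            f"series spans {series.span:g} {series.time_unit}, shorter than the "
            f"terminal window ({terminal_window:g})"
        )
    t, v = series.times, series.values
    terminal = v[t >= t[-1] - terminal_window]
    final_value = float(terminal.mean())
    outside = np.abs(v - final_value) > tolerance
    out_idx = np.nonzero(outside)[0]
    start_idx = 0 if len(out_idx) == 0 else int(out_idx[-1]) + 1
    if start_idx >= len(t):
        # even the final frame is outside the band around the terminal mean
        start_idx = len(t) - 1
    return EventRecord(
        label=series.label,
        start_time=float(t[start_idx]),
        value_at_start=float(v[start_idx]),
        final_value=final_value,
    )


def event_table(ensemble: PoseEnsemble,
                event_specs: Sequence[EventSpec],
                reference_structure: Structure | None = None,
                terminal_window: float = DEFAULT_TERMINAL_WINDOW
                ) -> list[EventRecord]:
    """One detected event per spec.

    With ``reference_structure`` given, each record carries the same selector
    distance measured in that structure (e.g. the crystallographic value).
    """
    records = []
    for spec in event_specs:
        series = distance_series(ensemble, spec.sel_a, spec.sel_b,
                                 mode="atom-pair", label=spec.label)
        rec = detect_event_start(series, tolerance=spec.tolerance,
                                 terminal_window=terminal_window)
        ref = None
        if reference_structure is not None:
            ref = atom_pair_distance(reference_structure, spec.sel_a, spec.sel_b)
        records.append(EventRecord(
            label=rec.label, start_time=rec.start_time,
            value_at_start=rec.value_at_start, final_value=rec.final_value,
            reference_value=ref,
        ))
    return records


def events_to_dataframe(records: Sequence[EventRecord],
                        time_unit: str = "ns") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            f"start_time_{time_unit}": [r.start_time for r in records],
            "value_at_start_A": [r.value_at_start for r in records],
            "final_value_A": [r.final_value for r in records],
            "experimental_A": [r.reference_value for r in records],
        }
    )
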