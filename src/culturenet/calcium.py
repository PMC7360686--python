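"""Calcium transient detection and the three network-activity statistics.

Raw fluorescence is converted to dF/F against a running-percentile
baseline (8th percentile over a 60-s window by default), which absorbs
slow drift while leaving transients intact.  Events are runs of frames
where dF/F exceeds the cell's median by ``threshold_sd`` robust noise
standard deviations; the noise SD is estimated from the median absolute
deviation of the first-differenced trace, which calcium transients
(smooth on the frame timescale) barely contaminate even at high duty
cycles.  Because an exponentially decaying transient spends seconds in
the band around any threshold, noise splits single transients into
fragments; runs separated by gaps up to ``max_gap_s`` are therefore
merged into one event, and an event must additionally reach
``peak_threshold_sd`` noise SDs at its peak, which keeps the
false-positive rate on noise-only cells well below 5%.  Summaries
report the three statistics used to describe spontaneous calcium
activity in cultured networks: the percentage of functionally active
cells, the event frequency in events/min (averaged over active cells),
and the mean event duration in seconds.  At a 2-Hz imaging rate
duration resolution is capped at one frame (0.5 s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

from .io import CalciumTraceSet

__all__ = [
    "CalciumEvent",
    "CalciumSummary",
    "compute_dff",
    "detect_events",
    "summarize_calcium",
    "CalciumEventModel",
    "CalciumEventResults",
]

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class CalciumEvent:
    """One detected calcium transient (threshold-crossing width)."""

    cell_id: str
    onset_s: float
    offset_s: float
    peak_dff: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class CalciumSummary:
    """The three group statistics of spontaneous calcium activity."""

    pct_active_cells: float
    mean_rate_per_min: Optional[float]
    mean_duration_s: Optional[float]
    n_cells: int
    n_events: int
    duration_s: float

    def to_dict(self) -> dict:
        return {
            "pct_active_cells": self.pct_active_cells,
            "mean_rate_per_min": self.mean_rate_per_min,
            "mean_duration_s": self.mean_duration_s,
            "n_cells": self.n_cells,
            "n_events": self.n_events,
            "duration_s": self.duration_s,
        }


def compute_dff(
    traces: CalciumTraceSet,
    baseline_window_s: float = 60.0,
    baseline_percentile: float = 8.0,
) -> np.ndarray:
    """Baseline-normalized dF/F per cell.

    F0 is a running percentile of the raw trace (default 8th percentile
    over a 60-s window, edge frames use nearest-window values); the
    baseline is floored at a small positive constant so division is
    always defined.  Raises if a cell's fluorescence is non-positive
    everywhere.
    """
    window = int(round(baseline_window_s * traces.frame_rate_hz))
    if window < 2:
        raise ValueError("baseline window must span at least 2 frames")
    window = min(window, traces.n_frames)
    f = traces.traces
    if np.any(np.all(f <= 0, axis=1)):
        bad = [traces.cell_ids[i] for i in
               np.nonzero(np.all(f <= 0, axis=1))[0]]
        raise ValueError(f"non-positive fluorescence everywhere: cells {bad}")
    f0 = percentile_filter(f, percentile=baseline_percentile,
                           size=(1, window), mode="nearest")
    f0 = np.maximum(f0, 1e-9)
    return (f - f0) / f0


def _estimate_noise_sd(dff_row: np.ndarray) -> float:
    """Noise SD from the MAD of the first-differenced trace.

    Differencing removes the slowly varying transient component, so the
    estimate stays calibrated even when transients occupy a large
    fraction of the recording (plain MAD of the trace inflates badly in
    that regime).  For iid Gaussian noise the difference has sqrt(2)
    times the SD of the noise itself.
    """
    d = np.diff(dff_row)
    mad = np.median(np.abs(d - np.median(d)))
    return _MAD_TO_SD * mad / np.sqrt(2.0)


def detect_events(
    dff: np.ndarray,
    cell_ids: List[str],
    frame_rate_hz: float,
    threshold_sd: float = 2.5,
    min_duration_s: float = 1.0,
    max_gap_s: float = 1.0,
    peak_threshold_sd: float = 4.0,
) -> List[CalciumEvent]:
    """Threshold-crossing event detection on dF/F traces.

    Per cell, the noise SD is estimated robustly (scaled median absolute
    deviation of the first-differenced trace) and an event is a run of
    frames with ``dff > median + threshold_sd * sd``; runs separated by
    sub-threshold gaps of at most ``max_gap_s`` are merged into one
    event (``max_gap_s = 0`` keeps every run distinct).  An event must
    span at least ``min_duration_s`` from onset to offset and reach
    ``median + peak_threshold_sd * sd`` at its peak.  Onset is the first
    supra-threshold frame time, offset the frame after the last one, so
    duration is a whole number of frames.
    """
    dff = np.atleast_2d(dff)
    dt = 1.0 / frame_rate_hz
    min_frames = max(1, int(round(min_duration_s * frame_rate_hz)))
    gap_frames = int(round(max_gap_s * frame_rate_hz))
    events: List[CalciumEvent] = []
    for row, cid in zip(dff, cell_ids):
        sd = _estimate_noise_sd(row)
        med = np.median(row)
        level = med + threshold_sd * sd
        peak_level = med + peak_threshold_sd * sd
        above = row > level
        if not above.any():
            continue
        # boundaries of maximal supra-threshold runs
        padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
        starts = np.nonzero(padded == 1)[0]
        ends = np.nonzero(padded == -1)[0]  # exclusive
        merged = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= gap_frames:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < min_frames:
                continue
            peak = float(row[s:e].max())
            if peak < peak_level:
                continue
            events.append(CalciumEvent(
                cell_id=str(cid),
                onset_s=s * dt,
                offset_s=e * dt,
                peak_dff=peak,
            ))
    return events


def summarize_calcium(
    events: List[CalciumEvent],
    n_cells: int,
    duration_s: float,
    rate_scope: str = "active",
) -> CalciumSummary:
    """Aggregate events into the three activity statistics.

    ``pct_active_cells`` is the percentage of cells with at least one
    event.  ``mean_rate_per_min`` averages events/min over active cells
    (``rate_scope="active"``, the default) or over all cells
    (``rate_scope="all"``).  ``mean_duration_s`` averages over all
    events.  With no events the rate and duration are reported absent
    (None).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_scope not in ("active", "all"):
        raise ValueError("rate_scope must be 'active' or 'all'")
    per_cell: dict = {}
    for ev in events:
        per_cell[ev.cell_id] = per_cell.get(ev.cell_id, 0) + 1
    n_active = len(per_cell)
    minutes = duration_s / 60.0
    if events:
        if rate_scope == "active":
            rate = float(np.mean([c / minutes for c in per_cell.values()]))
        else:
            rate = len(events) / minutes / n_cells
        dur = float(np.mean([ev.duration_s for ev in events]))
    else:
        rate = None
        dur = None
    return CalciumSummary(
        pct_active_cells=100.0 * n_active / n_cells if n_cells else 0.0,
        mean_rate_per_min=rate,
        mean_duration_s=dur,
        n_cells=n_cells,
        n_events=len(events),
        duration_s=duration_s,
    )


def events_to_frame(events: List[CalciumEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(ev.cell_id, ev.onset_s, ev.offset_s, ev.duration_s, ev.peak_dff)
         for ev in events],
        columns=["cell_id", "onset_s", "offset_s", "duration_s", "peak_dff"])


class CalciumEventModel:
    """Event detection and summary statistics for one trace set.

    Parameters mirror the detector: running-percentile baseline
    (window/percentile), MAD-based threshold multiplier, and the minimum
    event duration.
    """

    def __init__(self, traces: CalciumTraceSet,
                 baseline_window_s: float = 60.0,
                 baseline_percentile: float = 8.0,
                 threshold_sd: float = 2.5,
                 min_duration_s: float = 1.0,
                 max_gap_s: float = 1.0,
                 peak_threshold_sd: float = 4.0,
                 rate_scope: str = "active"):
        self.traces = traces
        self.baseline_window_s = baseline_window_s
        self.baseline_percentile = baseline_percentile
        self.threshold_sd = threshold_sd
        self.min_duration_s = min_duration_s
        self.max_gap_s = max_gap_s
        self.peak_threshold_sd = peak_threshold_sd
        self.rate_scope = rate_scope

    def fit(self) -> "CalciumEventResults":
        dff = compute_dff(self.traces, self.baseline_window_s,
                          self.baseline_percentile)
        events = detect_events(dff, self.traces.cell_ids,
                               self.traces.frame_rate_hz,
                               self.threshold_sd, self.min_duration_s,
                               self.max_gap_s, self.peak_threshold_sd)
        summary = summarize_calcium(events, self.traces.n_cells,
                                    self.traces.duration_s, self.rate_scope)
        return CalciumEventResults(self, dff, events, summary)


class CalciumEventResults:
    """Detected events, the dF/F traces they came from, and summaries."""

    def __init__(self, model: CalciumEventModel, dff: np.ndarray,
                 events: List[CalciumEvent], summary: CalciumSummary):
        self.model = model
        self.dff = dff
        self.events = events
        self.calcium_summary = summary

    def to_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)

    def summary(self) -> str:
        s = self.calcium_summary
        rate = "%.2f" % s.mean_rate_per_min if s.mean_rate_per_min is not None else "n/a"
        dur = "%.2f" % s.mean_duration_s if s.mean_duration_s is not None else "n/a"
        lines = [
            "Calcium event analysis",
            "=" * 46,
            f"cells                        {s.n_cells:10d}",
            f"recording duration           {s.duration_s:10.1f} s",
            f"events detected              {s.n_events:10d}",
            f"active cells                 {s.pct_active_cells:9.1f} %",
            f"events / min (active cells)  {rate:>10}",
            f"mean event duration          {dur:>8} s",
        ]
        return "\n".join(lines)
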