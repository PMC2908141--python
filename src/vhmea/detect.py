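"""Threshold-based spike extraction and active-electrode classification.

The detector follows the standard-deviation-multiple rule: for each
preprocessed trace the standard deviation delta is computed and events are
extracted wherever the voltage leaves +/- 4.5*delta, timestamped at the
excursion extremum.  Electrodes with at least 50 detected spikes per 50-s
segment (1 Hz) count as active; firing frequency is reported per 25-s
window on active electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import RecordingSegment, SNIPPET_WINDOW


class DegenerateSignalError(ValueError):
    pass


class InvalidWindowError(ValueError):
    pass


class InvalidInputError(ValueError):
    pass


class InconsistentTableError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdEstimate:
    delta_uv: float        # trace standard deviation
    multiplier: float      # 4.5 by default
    threshold_uv: float    # multiplier * delta
    polarity: str = "both"


@dataclass(frozen=True)
class ActivityCriterion:
    """>= ``min_spikes`` spikes per ``window_s`` (default 50 per 50 s = 1 Hz)."""

    min_spikes: int = 50
    window_s: float = 50.0

    @property
    def rate_hz(self) -> float:
        return self.min_spikes / self.window_s


@dataclass
class ElectrodeEvents:
    electrode: int
    times_s: np.ndarray
    amplitudes_uv: np.ndarray  # signed extremum voltage
    polarities: np.ndarray     # +1 / -1

    @property
    def count(self) -> int:
        return len(self.times_s)


@dataclass
class SpikeEventTable:
    """Detected events for every electrode of one segment."""

    events: dict[int, ElectrodeEvents]
    duration: float
    fs: float

    def counts(self) -> dict[int, int]:
        return {e: ev.count for e, ev in self.events.items()}

    def total(self) -> int:
        return int(sum(ev.count for ev in self.events.values()))

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for e in sorted(self.events):
            ev = self.events[e]
            for t, a, p in zip(ev.times_s, ev.amplitudes_uv, ev.polarities):
                rows.append((e, float(t), float(a), int(p)))
        return pd.DataFrame(rows, columns=["electrode", "t_s", "amp_uv", "polarity"])


@dataclass
class WaveformMatrix:
    """Peak-aligned spike snippets per electrode, rows matching the event table."""

    snippets: dict[int, np.ndarray]  # electrode -> (n_spikes, window)
    window: int


def estimate_threshold(trace: np.ndarray, multiplier: float = 4.5) -> ThresholdEstimate:
    """delta = sample SD of the preprocessed trace; threshold = multiplier*delta."""
    x = np.asarray(trace, dtype=np.float64)
    if x.size < 2:
        raise DegenerateSignalError("trace too short to estimate a threshold")
    delta = float(np.std(x))
    if delta == 0.0:
        raise DegenerateSignalError("zero-variance trace has no noise scale")
    return ThresholdEstimate(delta_uv=delta, multiplier=multiplier,
                             threshold_uv=multiplier * delta)


def _excursion_extrema(x: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices and signed values of the extremum of each supra-threshold excursion."""
    above = np.abs(x) > threshold
    if not above.any():
        return np.empty(0, dtype=np.intp), np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, len(x))
    idx = np.empty(len(starts), dtype=np.intp)
    for k, (s, e) in enumerate(zip(starts, ends)):
        idx[k] = s + np.argmax(np.abs(x[s:e]))
    return idx, x[idx]


def detect_spikes(
    trace: np.ndarray,
    thr: ThresholdEstimate,
    fs: float,
    dead_time_ms: float = 1.0,
    window: int = SNIPPET_WINDOW,
) -> tuple[ElectrodeEvents, np.ndarray]:
    """Extract one event per +/-threshold excursion, with peak-aligned snippets.

    Events closer than ``dead_time_ms`` are merged keeping the larger
    extremum.  Events whose snippet window would run off the trace are
    dropped (keeps the waveform matrix aligned with the event table).
    """
    x = np.asarray(trace, dtype=np.float64)
    if window > x.size:
        raise InvalidWindowError("snippet window exceeds trace length")
    idx, vals = _excursion_extrema(x, thr.threshold_uv)

    dead = int(round(dead_time_ms / 1000.0 * fs))
    keep_idx: list[int] = []
    keep_val: list[float] = []
    for i, v in zip(idx, vals):
        if keep_idx and i - keep_idx[-1] < dead:
            if abs(v) > abs(keep_val[-1]):
                keep_idx[-1] = int(i)
                keep_val[-1] = float(v)
        else:
            keep_idx.append(int(i))
            keep_val.append(float(v))

    half = window // 2
    n = x.size
    final_idx = [i for i in keep_idx if i - half >= 0 and i - half + window <= n]
    final_val = [v for i, v in zip(keep_idx, keep_val)
                 if i - half >= 0 and i - half + window <= n]
    snips = np.empty((len(final_idx), window))
    for k, i in enumerate(final_idx):
        snips[k] = x[i - half : i - half + window]
    events = ElectrodeEvents(
        electrode=-1,
        times_s=np.asarray(final_idx, dtype=np.float64) / fs,
        amplitudes_uv=np.asarray(final_val),
        polarities=np.sign(np.asarray(final_val)).astype(np.int8),
    )
    return events, snips


def classify_active(count_50s: int, criterion: ActivityCriterion | None = None) -> bool:
    criterion = criterion or ActivityCriterion()
    if count_50s < 0:
        raise InvalidInputError("spike count cannot be negative")
    return count_50s >= criterion.min_spikes


def frequency_series(
    table: SpikeEventTable,
    window_s: float = 25.0,
    electrodes: list[int] | None = None,
) -> dict[int, np.ndarray]:
    """Per-electrode firing frequency in consecutive windows (counts / window).

    For a 50-s segment with the default 25-s window each electrode yields
    two observations.
    """
    n_win = int(round(table.duration / window_s))
    if n_win < 1:
        raise InvalidInputError("window longer than segment")
    out: dict[int, np.ndarray] = {}
    edges = np.arange(n_win + 1) * window_s
    which = electrodes if electrodes is not None else sorted(table.events)
    for e in which:
        ev = table.events[e]
        if ev.count and (ev.times_s.min() < 0 or ev.times_s.max() >= table.duration):
            raise InconsistentTableError(f"electrode {e} has events outside the segment")
        counts, _ = np.histogram(ev.times_s, bins=edges)
        out[e] = counts / window_s
    return out


def detect_segment(
    segment: RecordingSegment,
    multiplier: float = 4.5,
    dead_time_ms: float = 1.0,
    window: int = SNIPPET_WINDOW,
    criterion: ActivityCriterion | None = None,
) -> tuple[SpikeEventTable, WaveformMatrix, np.ndarray, dict[int, ThresholdEstimate]]:
    """Run thresholding over every electrode of a preprocessed segment.

    Returns the event table, waveform matrix, a boolean active-electrode
    vector and the per-electrode threshold estimates.  Zero-variance
    (silent) electrodes yield zero events rather than an error.
    """
    criterion = criterion or ActivityCriterion()
    events: dict[int, ElectrodeEvents] = {}
    snippets: dict[int, np.ndarray] = {}
    thresholds: dict[int, ThresholdEstimate] = {}
    n_elec = segment.samples.shape[0]
    active = np.zeros(n_elec, dtype=bool)
    for e in range(n_elec):
        trace = segment.samples[e]
        try:
            thr = estimate_threshold(trace, multiplier)
        except DegenerateSignalError:
            events[e] = ElectrodeEvents(e, np.empty(0), np.empty(0),
                                        np.empty(0, dtype=np.int8))
            snippets[e] = np.empty((0, window))
            continue
        ev, snips = detect_spikes(trace, thr, segment.fs, dead_time_ms, window)
        ev.electrode = e
        events[e] = ev
        snippets[e] = snips
        thresholds[e] = thr
        active[e] = classify_active(ev.count, criterion)
    table = SpikeEventTable(events=events, duration=segment.duration, fs=segment.fs)
    return table, WaveformMatrix(snippets=snippets, window=window), active, thresholds
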