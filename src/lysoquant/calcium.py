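"""Ratiometric Ca2+ trace analysis: F340/F380 ratios, baseline, spike detection.

Dual-excitation Fura-2 imaging reports intracellular free Ca2+ as the
fluorescence ratio F340/F380 sampled every 5 s.  A spike is a transient
elevation of the ratio above the running baseline whose amplitude exceeds
0.05 ratio units; spikes are counted per cell over a 40 min window and the
population is summarised as the percentage of cells with each spike count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass
class CalciumTrace:
    """One cell's dual-excitation fluorescence time series (uniform sampling)."""

    cell_id: str
    time_s: np.ndarray
    f340: np.ndarray
    f380: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if not (len(self.time_s) == len(self.f340) == len(self.f380)):
            raise ValueError("time/F340/F380 must have equal lengths")
        if len(self.time_s) >= 2:
            dt = np.diff(self.time_s)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time_s must be uniformly increasing")

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if len(self.time_s) >= 2 else float("nan")


@dataclass
class Spike:
    peak_time_s: float
    amplitude: float


@dataclass
class SpikeSet:
    cell_id: str
    spikes: list[Spike]
    baseline: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.spikes)


@dataclass
class SpikeHistogram:
    """Spike-count -> percentage of cells; bin 0 is cells with no spikes."""

    bins: dict[int, float]
    n_cells: int


def compute_ratio(f340: np.ndarray, f380: np.ndarray, f380_floor: float = 0.0) -> np.ndarray:
    """Elementwise F340/F380; points with F380 <= floor become NaN (missing)."""
    f340 = np.asarray(f340, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f340.shape != f380.shape:
        raise ValueError("F340 and F380 must have equal lengths")
    valid = f380 > f380_floor
    if not valid.any():
        raise ValueError("all points fall below the F380 floor")
    out = np.full(f340.shape, np.nan)
    out[valid] = f340[valid] / f380[valid]
    return out


def _interpolate_missing(x: np.ndarray) -> np.ndarray:
    """Bridge NaNs linearly (edge NaNs take the nearest valid value)."""
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def estimate_baseline(ratio: np.ndarray, dt_s: float, window_s: float = 180.0) -> np.ndarray:
    """Running median of the ratio over a centred window (edges truncated).

    Missing points are bridged by linear interpolation before the median and
    are never counted as peaks downstream.  The window must span at least
    three samples so a single-sample transient cannot move the median.
    """
    ratio = np.asarray(ratio, dtype=float)
    if len(ratio) < 3:
        raise ValueError("trace shorter than 3 samples")
    if window_s < 3 * dt_s:
        raise ValueError("window_s must be at least 3 sampling intervals")
    filled = _interpolate_missing(ratio)
    half = int(round(window_s / dt_s)) // 2
    return np.array([np.median(filled[max(0, i - half): i + half + 1])
                     for i in range(len(filled))])


def detect_spikes(trace: CalciumTrace, threshold: float = 0.05, window_s: float = 2400.0,
                  refractory_s: float = 10.0, baseline_window_s: float = 180.0,
                  f380_floor: float = 0.0) -> SpikeSet:
    """Count ratio transients exceeding ``threshold`` above baseline.

    A spike is a local maximum of (ratio - baseline) strictly exceeding the
    threshold within the analysis window (the first ``window_s`` seconds,
    40 min by default); maxima closer than ``refractory_s`` are merged,
    keeping the larger.  Amplitude is (ratio - baseline) at the peak.
    """
    ratio = compute_ratio(trace.f340, trace.f380, f380_floor)
    dt = trace.dt_s
    baseline = estimate_baseline(ratio, dt, baseline_window_s)
    in_window = trace.time_s < window_s
    excess = ratio - baseline  # NaN where ratio missing

    candidates: list[tuple[float, float]] = []  # (time, amplitude)
    n = len(excess)
    for i in np.nonzero(in_window)[0]:
        e = excess[i]
        if not np.isfinite(e) or e <= threshold:
            continue
        left = excess[i - 1] if i > 0 and np.isfinite(excess[i - 1]) else -np.inf
        right = excess[i + 1] if i < n - 1 and np.isfinite(excess[i + 1]) else -np.inf
        if e >= left and e >= right:
            candidates.append((float(trace.time_s[i]), float(e)))

    merged: list[tuple[float, float]] = []
    for t, a in candidates:
        if merged and t - merged[-1][0] < refractory_s:
            if a > merged[-1][1]:
                merged[-1] = (t, a)
        else:
            merged.append((t, a))

    spikes = [Spike(peak_time_s=t, amplitude=a) for t, a in merged]
    return SpikeSet(cell_id=trace.cell_id, spikes=spikes, baseline=baseline,
                    params={"threshold": threshold, "window_s": window_s,
                            "refractory_s": refractory_s,
                            "baseline_window_s": baseline_window_s})


def spike_histogram(spike_sets: Sequence[SpikeSet]) -> SpikeHistogram:
    """Percentage of cells with each spike count; percentages sum to 100."""
    if not spike_sets:
        raise ValueError("no cells")
    counts = [s.count for s in spike_sets]
    n = len(counts)
    bins: dict[int, float] = {}
    for k in range(0, max(counts) + 1):
        c = counts.count(k)
        if c or k == 0:
            bins[k] = 100.0 * c / n
    return SpikeHistogram(bins=bins, n_cells=n)
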