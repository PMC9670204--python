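"""Synthetic ratiometric Ca2+ traces with planted spikes.

Each cell's ratio trace is a constant baseline plus exponentially decaying
spikes at (thinned) Poisson times plus Gaussian noise.  The F380 channel is
constant, and F340 = ratio x F380, so the computed F340/F380 ratio equals
the planted trace by construction.

Two choices keep the planted truth exactly recoverable on noiseless traces:
spike onsets are snapped to the sampling grid (events are only observable at
samples anyway), and the decaying pulse is truncated where it falls below
1e-3 of its amplitude, so a long-enough running-median window sees a clean
majority of baseline samples.  A minimum inter-spike interval (default 20 s,
above the detector's 10 s refractory) emulates the refractoriness of
store-release Ca2+ transients and keeps planted events distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..calcium import CalciumTrace
from .images import substream

PULSE_RELATIVE_FLOOR = 1e-3


@dataclass(frozen=True)
class TraceSimParams:
    """Defaults follow 5 s sampling over 40 min.

    ``amplitude_dist`` is ``("fixed", a)`` or ``("lognormal", mu, sigma)``
    in ratio units.  ``spike_times_s`` (one sequence per cell) overrides the
    Poisson process for deterministic planting.
    """

    duration_s: float = 2400.0
    dt_s: float = 5.0
    baseline_ratio: float = 1.0
    spike_rate_per_min: float = 0.5
    amplitude_dist: tuple = ("fixed", 0.1)
    decay_tau_s: float = 10.0
    noise_sd: float = 0.01
    n_cells: int = 50
    seed: int = 0
    min_interval_s: float = 20.0
    f380_level: float = 1.0
    spike_times_s: Optional[tuple[tuple[float, ...], ...]] = None

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        n = self.duration_s / self.dt_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s must be an integer multiple of dt_s")
        if self.amplitude_dist[0] not in ("fixed", "lognormal"):
            raise ValueError(f"unknown amplitude_dist {self.amplitude_dist!r}")
        if self.amplitude_dist[0] == "fixed" and self.amplitude_dist[1] <= 0:
            raise ValueError("amplitudes must be > 0")


@dataclass
class TraceTruth:
    cell_id: str
    spike_times_s: np.ndarray
    amplitudes: np.ndarray


def _draw_amplitudes(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    if dist[0] == "fixed":
        return np.full(n, float(dist[1]))
    _, mu, sigma = dist
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def generate_traces(params: TraceSimParams) -> tuple[list[CalciumTrace], list[TraceTruth]]:
    """Generate per-cell traces and the planted spike truth.

    ratio(t) = baseline + sum_i a_i * exp(-(t - t_i)/tau) * 1[t >= t_i]
    (pulse truncated below 1e-3 relative level) + Gaussian noise.
    """
    n_samples = int(round(params.duration_s / params.dt_s))
    time_s = np.arange(n_samples) * params.dt_s
    support_s = params.decay_tau_s * math.log(1.0 / PULSE_RELATIVE_FLOOR) if params.decay_tau_s > 0 else 0.0

    traces: list[CalciumTrace] = []
    truths: list[TraceTruth] = []
    for i in range(params.n_cells):
        rng = substream(params.seed, 10, i)
        if params.spike_times_s is not None:
            times = np.sort(np.asarray(params.spike_times_s[i], dtype=float))
        else:
            rate_per_s = params.spike_rate_per_min / 60.0
            n_events = rng.poisson(rate_per_s * params.duration_s)
            raw = np.sort(rng.uniform(0.0, params.duration_s, size=n_events))
            # snap to the sampling grid, then thin to the minimum interval
            snapped = np.round(raw / params.dt_s) * params.dt_s
            snapped = snapped[snapped < params.duration_s]
            times_list: list[float] = []
            for t in snapped:
                if not times_list or t - times_list[-1] >= params.min_interval_s:
                    times_list.append(float(t))
            times = np.asarray(times_list)
        amps = _draw_amplitudes(params.amplitude_dist, len(times), rng)

        ratio = np.full(n_samples, params.baseline_ratio)
        for t0, a in zip(times, amps):
            i0 = int(round(t0 / params.dt_s))
            i1 = min(n_samples, i0 + int(math.floor(support_s / params.dt_s)) + 1) if support_s > 0 else i0 + 1
            i1 = min(i1, n_samples)
            if i0 >= n_samples:
                continue
            if params.decay_tau_s > 0:
                ratio[i0:i1] += a * np.exp(-(time_s[i0:i1] - t0) / params.decay_tau_s)
            else:
                ratio[i0] += a
        if params.noise_sd > 0:
            ratio = ratio + rng.normal(0.0, params.noise_sd, size=n_samples)

        cell_id = f"cell{i:04d}"
        f380 = np.full(n_samples, params.f380_level)
        traces.append(CalciumTrace(cell_id=cell_id, time_s=time_s,
                                   f340=ratio * f380, f380=f380))
        truths.append(TraceTruth(cell_id=cell_id, spike_times_s=times, amplitudes=amps))
    return traces, truths
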