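"""Stimulus process and stimulus-tuned Poisson LGN drive.

The model's input space is circular with period 1000 "input units".  A
single global stimulus value s(t) is presented to all LGN synapses at once;
it is redrawn uniformly on [0, 1000) after holding for an exponentially
distributed duration (mean 20 ms).  LGN synapse ``a`` fires as an
inhomogeneous Poisson process with the periodically wrapped Gaussian tuning

    r_a(s) = R0 + R1 [G(s - a) + G(s - a + 1000) + G(s - a - 1000)],
    G(d) = exp(-d^2 / (2 sigma^2)),

with baseline R0 = 5 Hz, amplitude R1 = 20 Hz and width sigma = 80 units.
A separate untuned Poisson background (0.5 Hz per cell) drives every
cortical cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LgnRateParams",
    "StimulusTrace",
    "lgn_rate",
    "sample_stimulus_trace",
    "sweep_stimulus_trace",
    "generate_poisson_spikes",
    "sample_lgn_events",
    "sample_background_events",
]

INPUT_PERIOD = 1000.0


@dataclass(frozen=True)
class LgnRateParams:
    """Tuning parameters of the LGN rate function."""

    R0: float = 5.0  # Hz, untuned baseline
    R1: float = 20.0  # Hz, tuned amplitude
    sigma_tuning: float = 80.0  # input units
    period: float = INPUT_PERIOD  # input units

    def __post_init__(self):
        if self.R0 < 0 or self.R1 < 0:
            raise ValueError("rates must be non-negative")
        if self.sigma_tuning <= 0:
            raise ValueError("sigma_tuning must be positive")


@dataclass
class StimulusTrace:
    """Piecewise-constant stimulus: label ``labels[k]`` is shown on
    [onsets[k], onsets[k] + durations[k]); segments tile [0, total_time]."""

    onsets: np.ndarray  # s
    labels: np.ndarray  # input units, in [0, period)
    durations: np.ndarray  # s

    @property
    def total_time(self) -> float:
        return float(self.onsets[-1] + self.durations[-1])

    def __len__(self) -> int:
        return len(self.onsets)


def lgn_rate(
    a: np.ndarray | float,
    s: np.ndarray | float,
    params: LgnRateParams = LgnRateParams(),
) -> np.ndarray | float:
    """Firing rate (Hz) of LGN synapse ``a`` under stimulus ``s``.

    Vectorized over both arguments (broadcast).  Periodic in (s - a) with
    the input-space period; >= R0 everywhere.
    """
    d = np.asarray(s, dtype=float) - np.asarray(a, dtype=float)
    two_sig2 = 2.0 * params.sigma_tuning**2
    p = params.period
    tuned = (
        np.exp(-(d**2) / two_sig2)
        + np.exp(-((d + p) ** 2) / two_sig2)
        + np.exp(-((d - p) ** 2) / two_sig2)
    )
    out = params.R0 + params.R1 * tuned
    return float(out) if np.isscalar(s) and np.isscalar(a) else out


def sample_stimulus_trace(
    total_time: float,
    mean_duration: float = 0.020,
    rng_seed: int | np.random.Generator = 0,
    period: float = INPUT_PERIOD,
) -> StimulusTrace:
    """Draw a random stimulus sequence tiling [0, total_time].

    Labels are i.i.d. uniform on [0, period); holding times are i.i.d.
    exponential with mean ``mean_duration``; the final segment is truncated
    at ``total_time``.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    rng = np.random.default_rng(rng_seed)
    onsets, labels, durations = [], [], []
    t = 0.0
    # draw in blocks to avoid a per-segment python loop
    est = max(16, int(total_time / mean_duration * 1.2))
    while t < total_time:
        durs = rng.exponential(mean_duration, size=est)
        labs = rng.uniform(0.0, period, size=est)
        ends = t + np.cumsum(durs)
        keep = int(np.searchsorted(ends, total_time, side="left")) + 1
        keep = min(keep, est)
        onsets.append(t + np.concatenate([[0.0], np.cumsum(durs[: keep - 1])]))
        labels.append(labs[:keep])
        durations.append(durs[:keep])
        t = float(ends[keep - 1])
        est = max(16, int((total_time - t) / mean_duration * 1.2) + 16)
    onsets = np.concatenate(onsets)
    labels = np.concatenate(labels)
    durations = np.concatenate(durations)
    durations[-1] = total_time - onsets[-1]  # truncate the last segment
    return StimulusTrace(onsets=onsets, labels=labels, durations=durations)


def sweep_stimulus_trace(
    step: float = 20.0,
    dwell: float = 2.0,
    period: float = INPUT_PERIOD,
) -> StimulusTrace:
    """Deterministic measurement sweep: labels 0, step, 2*step, ... each
    held for ``dwell`` seconds (used for tuning-curve measurement)."""
    labels = np.arange(0.0, period, step)
    onsets = np.arange(len(labels)) * dwell
    durations = np.full(len(labels), dwell)
    return StimulusTrace(onsets=onsets, labels=labels, durations=durations)


def generate_poisson_spikes(
    rate_fn,
    total_time: float,
    rng_seed: int | np.random.Generator = 0,
    dt: float = 1e-4,
) -> np.ndarray:
    """Spike times of an inhomogeneous Poisson process on [0, total_time).

    ``rate_fn`` maps time (s) -> rate (Hz) and must be piecewise constant on
    a scale coarse relative to ``dt``.  Implemented as a per-step Bernoulli
    thinning with probability rate*dt (requires rate*dt << 1), matching the
    clock-driven integrator's event grid.
    """
    rng = np.random.default_rng(rng_seed)
    n_steps = int(round(total_time / dt))
    t = (np.arange(n_steps) + 0.5) * dt
    rates = np.asarray([rate_fn(tt) for tt in t]) if callable(rate_fn) else rate_fn
    fired = rng.random(n_steps) < rates * dt
    return t[fired]


# ---------------------------------------------------------------------------
# pre-sampled event streams for the fast simulator

def sample_lgn_events(
    trace: StimulusTrace,
    n_lgn: int,
    dt: float,
    rng: np.random.Generator,
    params: LgnRateParams = LgnRateParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Sample all LGN spikes for a stimulus trace on the integration grid.

    For each stimulus segment, per-synapse counts are drawn Poisson
    (rate * duration) and placed on uniformly random steps within the
    segment, which realizes the same piecewise-constant inhomogeneous
    Poisson process as per-step thinning but in O(events).

    Returns (event_steps, event_labels), sorted by step.
    """
    labels = np.arange(n_lgn, dtype=float)
    all_steps, all_labels = [], []
    seg_start_steps = np.round(trace.onsets / dt).astype(np.int64)
    seg_end_steps = np.round((trace.onsets + trace.durations) / dt).astype(np.int64)
    for k in range(len(trace)):
        lo, hi = seg_start_steps[k], seg_end_steps[k]
        if hi <= lo:
            continue
        rates = lgn_rate(labels, trace.labels[k], params)
        counts = rng.poisson(rates * (hi - lo) * dt)
        total = int(counts.sum())
        if total == 0:
            continue
        labs = np.repeat(np.arange(n_lgn), counts)
        steps = rng.integers(lo, hi, size=total)
        all_steps.append(steps)
        all_labels.append(labs)
    if not all_steps:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    steps = np.concatenate(all_steps)
    labs = np.concatenate(all_labels)
    order = np.argsort(steps, kind="stable")
    return steps[order].astype(np.int64), labs[order].astype(np.int64)


def sample_background_events(
    n_cells: int,
    total_time: float,
    dt: float,
    rng: np.random.Generator,
    rate: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Untuned background Poisson spikes (rate Hz per cell) on the step grid.

    Returns (event_steps, event_cells), sorted by step.
    """
    n_steps = int(round(total_time / dt))
    counts = rng.poisson(rate * total_time, size=n_cells)
    total = int(counts.sum())
    cells = np.repeat(np.arange(n_cells), counts)
    steps = rng.integers(0, max(n_steps, 1), size=total)
    order = np.argsort(steps, kind="stable")
    return steps[order].astype(np.int64), cells[order].astype(np.int64)
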