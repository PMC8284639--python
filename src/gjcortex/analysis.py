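"""Analysis suite: orientation-preference statistics, map disorder,
synchrony events and connectivity statistics.

Every function here is a pure function of saved run outputs (spike trains,
weight snapshots, tuning tables, the wiring), so re-running the analysis on
the same container reproduces the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gjcortex.network import NetworkGraph, wrapped_grid_distance
from gjcortex.records import WeightTrajectory

__all__ = [
    "op_difference",
    "group_op_distributions",
    "learning_slope",
    "kld_to_uniform",
    "local_disorder",
    "nse_count",
    "connectivity_stats",
    "gj_degree_stats",
    "gj_groups",
    "sample_non_gj_pairs",
]

INPUT_PERIOD = 1000.0


def op_difference(op_a, op_b, period: float = INPUT_PERIOD):
    """Circular distance between two OPs: min(|d|, period - |d|) in [0, period/2].

    Vectorized; NaN inputs propagate (undefined OPs are excluded upstream).
    """
    d = np.abs(np.asarray(op_a, dtype=float) - np.asarray(op_b, dtype=float))
    out = np.minimum(d, period - d)
    return float(out) if out.ndim == 0 else out


def sample_non_gj_pairs(
    graph: NetworkGraph, n_pairs: int, rng: np.random.Generator
) -> np.ndarray:
    """Random excitatory pairs with no GJ edge, size-matched to the GJ set."""
    exc = graph.excitatory_ids
    gj_keys = {
        (min(a, b), max(a, b)) for a, b in graph.gj_edges
    }
    pairs = []
    while len(pairs) < n_pairs:
        a, b = rng.choice(exc, size=2, replace=False)
        key = (min(a, b), max(a, b))
        if key not in gj_keys:
            pairs.append(key)
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


@dataclass
class OpDistributions:
    """Paired OP-difference samples and histograms (bin width 50 units)."""

    gj_diffs: np.ndarray
    control_diffs: np.ndarray
    bin_edges: np.ndarray
    gj_hist: np.ndarray
    control_hist: np.ndarray
    n_excluded: int  # pairs dropped because an OP was undefined


def group_op_distributions(
    op: np.ndarray,
    graph: NetworkGraph,
    rng_seed: int | np.random.Generator = 0,
    bin_width: float = 50.0,
    period: float = INPUT_PERIOD,
) -> OpDistributions:
    """OP-difference distributions for GJ-coupled pairs vs a size-matched
    random sample of non-GJ excitatory pairs."""
    rng = np.random.default_rng(rng_seed)
    edges = graph.gj_edges
    diffs, dropped = _pair_diffs(op, edges, period)
    ctrl_pairs = sample_non_gj_pairs(graph, max(len(edges), 1), rng)
    ctrl, dropped_c = _pair_diffs(op, ctrl_pairs, period)
    bin_edges = np.arange(0.0, period / 2 + bin_width, bin_width)
    gj_hist, _ = np.histogram(diffs, bins=bin_edges)
    control_hist, _ = np.histogram(ctrl, bins=bin_edges)
    return OpDistributions(
        gj_diffs=diffs,
        control_diffs=ctrl,
        bin_edges=bin_edges,
        gj_hist=gj_hist,
        control_hist=control_hist,
        n_excluded=dropped + dropped_c,
    )


def _pair_diffs(op, pairs, period):
    if len(pairs) == 0:
        return np.empty(0), 0
    a = op[pairs[:, 0]]
    b = op[pairs[:, 1]]
    ok = np.isfinite(a) & np.isfinite(b)
    return op_difference(a[ok], b[ok], period), int((~ok).sum())


@dataclass
class LearningSlope:
    """Mean weight time-course of the synapses that eventually potentiated.

    ``time_to_half_max`` is the first crossing of 0.5 g_max.  When initial
    weights already sit above half-maximum that statistic degenerates, so
    ``time_to_half_rise`` — the first crossing of the midpoint between the
    curve's starting value and g_max — carries the learning-speed
    comparison in that regime.
    """

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_synapses: int
    time_to_half_max: float  # s; NaN when the curve never crosses
    time_to_half_rise: float  # s; NaN when the curve never crosses


def learning_slope(
    trajectory: WeightTrajectory,
    cells: np.ndarray,
    g_max: float,
    potentiation_criterion: float = 0.7,
) -> LearningSlope:
    """Average LGN weight time-course over the feedforward synapses onto
    ``cells`` whose *final* weight reached at least
    ``potentiation_criterion * g_max``.

    Returns the mean curve, its sd band and the time at which the mean
    curve first reaches half of ``g_max`` (linear interpolation between
    snapshots).  Raises ValueError when no synapse meets the criterion.
    """
    w = np.asarray(trajectory.w_lgn[:, cells, :], dtype=float)  # (T, m, n_lgn)
    final = w[-1]
    sel = final >= potentiation_criterion * g_max
    if not np.any(sel):
        raise ValueError("no synapse met the potentiation criterion")
    series = w[:, sel]  # (T, n_selected)
    mean = series.mean(axis=1)
    sd = series.std(axis=1)
    t = np.asarray(trajectory.times, dtype=float)

    def crossing(level):
        above = mean >= level
        if not above.any():
            return np.nan
        k = int(np.argmax(above))
        if k == 0:
            return t[0]
        f = (level - mean[k - 1]) / (mean[k] - mean[k - 1])
        return t[k - 1] + f * (t[k] - t[k - 1])

    return LearningSlope(
        times=t,
        mean=mean,
        sd=sd,
        n_synapses=int(sel.sum()),
        time_to_half_max=float(crossing(0.5 * g_max)),
        time_to_half_rise=float(crossing(mean[0] + 0.5 * (g_max - mean[0]))),
    )


def kld_to_uniform(
    op: np.ndarray, n_bins: int = 25, period: float = INPUT_PERIOD
) -> float:
    """Kullback-Leibler divergence (nats) of the OP histogram from uniform.

    OPs are binned into ``n_bins`` equal circular bins; KLD(P || U) =
    sum p_i ln(p_i n_bins) with the 0 ln 0 = 0 convention.  Undefined OPs
    are ignored.
    """
    vals = np.asarray(op, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no defined OPs")
    hist, _ = np.histogram(vals, bins=n_bins, range=(0.0, period))
    p = hist / hist.sum()
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] * n_bins)))


def local_disorder(
    op: np.ndarray,
    graph: NetworkGraph,
    radius: float,
    period: float = INPUT_PERIOD,
) -> tuple[float, int]:
    """Mean circular OP difference between each selective excitatory cell
    and the selective excitatory cells within wrapped grid distance
    ``radius`` (excluding itself), averaged over cells.

    Returns (mean difference in input units, number of cells excluded for
    lacking a defined OP or any in-radius neighbour).  Larger values mean
    more disorder; an i.i.d.-uniform map gives ~period/4.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dist = wrapped_grid_distance(graph.positions, graph.grid_side)
    exc = graph.is_excitatory
    valid = exc & np.isfinite(op)
    per_cell = []
    excluded = 0
    for i in np.flatnonzero(exc):
        if not valid[i]:
            excluded += 1
            continue
        nbrs = np.flatnonzero(valid & (dist[i] <= radius))
        nbrs = nbrs[nbrs != i]
        if len(nbrs) == 0:
            excluded += 1
            continue
        per_cell.append(op_difference(op[i], op[nbrs], period).mean())
    if not per_cell:
        raise ValueError("no cell has an in-radius selective neighbour")
    return float(np.mean(per_cell)), excluded


def gj_groups(graph: NetworkGraph, min_size: int = 2) -> list[np.ndarray]:
    """Connected components of the GJ graph with at least ``min_size`` cells."""
    parent = {int(c): int(c) for c in np.unique(graph.gj_edges)}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in graph.gj_edges:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    comps: dict[int, list[int]] = {}
    for c in parent:
        comps.setdefault(find(c), []).append(c)
    return [
        np.asarray(sorted(v), dtype=np.int64)
        for v in comps.values()
        if len(v) >= min_size
    ]


def nse_count(
    spike_times: list[np.ndarray],
    window_total: float,
    threshold: float = 0.6,
    tail: float = 0.020,
    dt: float = 1e-3,
) -> float:
    """Network-synchronous-event rate of one GJ group (events per second).

    The group activity a(t) is formed by attaching an exponential tail of
    ``tail`` seconds to each spike of each cell, summing, and dividing by
    the number of cells; an NSE is a strictly upward crossing of
    ``threshold`` (a(t - dt) < thr <= a(t)).  Empty trains give 0.
    """
    m = len(spike_times)
    if m < 2:
        raise ValueError("a GJ group needs at least 2 cells")
    if window_total <= 0:
        raise ValueError("window_total must be positive")
    n_steps = int(round(window_total / dt)) + 1
    a = np.zeros(n_steps)
    decay = np.exp(-dt / tail)
    all_spikes = np.concatenate([s for s in spike_times]) if any(
        len(s) for s in spike_times
    ) else np.empty(0)
    if len(all_spikes) == 0:
        return 0.0
    # accumulate spike impulses on the grid, then run the exponential filter
    idx = np.clip(np.round(all_spikes / dt).astype(int), 0, n_steps - 1)
    impulses = np.bincount(idx, minlength=n_steps).astype(float)
    acc = 0.0
    for k in range(n_steps):
        acc = acc * decay + impulses[k]
        a[k] = acc
    a /= m
    up = (a[1:] >= threshold) & (a[:-1] < threshold)
    return float(up.sum() / window_total)


@dataclass
class ConnectivityStats:
    """Fractions of pair classes among GJ vs matched non-GJ pairs."""

    gj: dict[str, float]
    non_gj: dict[str, float]
    n_gj_pairs: int
    strong_threshold: float


def connectivity_stats(
    w_ee: np.ndarray,
    graph: NetworkGraph,
    strong_threshold: float = 0.5,
    g_ee_max: float = 0.025,
    rng_seed: int | np.random.Generator = 0,
) -> ConnectivityStats:
    """Classify cell pairs by their strong directed E->E connections.

    A directed connection counts as strong iff its weight is at least
    ``strong_threshold * g_ee_max``.  Pairs are 'bidirectional' (both
    directions strong), 'unidirectional' (exactly one) or 'unconnected'.
    Reported separately for GJ-coupled pairs and a size-matched random
    sample of non-GJ excitatory pairs.
    """
    rng = np.random.default_rng(rng_seed)
    thr = strong_threshold * g_ee_max

    def classify(pairs):
        counts = {"bidirectional": 0, "unidirectional": 0, "unconnected": 0}
        for a, b in pairs:
            s = int(w_ee[b, a] >= thr) + int(w_ee[a, b] >= thr)
            key = ("unconnected", "unidirectional", "bidirectional")[s]
            counts[key] += 1
        total = max(len(pairs), 1)
        return {k: v / total for k, v in counts.items()}

    gj_pairs = graph.gj_edges
    ctrl = sample_non_gj_pairs(graph, max(len(gj_pairs), 1), rng)
    return ConnectivityStats(
        gj=classify(gj_pairs),
        non_gj=classify(ctrl),
        n_gj_pairs=len(gj_pairs),
        strong_threshold=strong_threshold,
    )


def gj_degree_stats(graph: NetworkGraph) -> tuple[float, np.ndarray]:
    """Mean GJ degree over all excitatory cells (degree-0 included) and
    the degree histogram."""
    deg = graph.gj_degree()[graph.excitatory_ids]
    hist = np.bincount(deg)
    return float(deg.mean()) if len(deg) else 0.0, hist
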