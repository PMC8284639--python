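"""Deterministic micro-networks and independent brute-force oracles.

These validate the dynamics and plasticity kernels without running full
developmental simulations.  The oracles are deliberately scalar and
event-driven (exact exponential decay between events) so they share no code
with the vectorized clock-driven path they check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gjcortex.dynamics import DEFAULT_DT, NetworkState, NeuronParams, step
from gjcortex.network import NetworkGraph
from gjcortex.plasticity import PlasticityParams

__all__ = [
    "ScriptedScenario",
    "make_two_cell_gj_scenario",
    "event_driven_plasticity_oracle",
    "clock_driven_plasticity",
]


@dataclass
class ScriptedScenario:
    """Two-cell electrically coupled scenario with scripted Poisson drive.

    Both cells receive a shared Poisson conductance-increment train (rate
    ``shared_rate``) plus an independent train each (rate
    ``independent_rate``); this exercises the GJ resistive term and the
    spikelet.  Fully deterministic given its seed; runs in well under a
    second.
    """

    g_c: float
    shared_rate: float  # Hz
    independent_rate: float = 200.0  # Hz
    increment: float = 0.05  # conductance jump per drive spike
    duration: float = 2.0  # s
    dt: float = DEFAULT_DT
    seed: int = 0
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def graph(self) -> NetworkGraph:
        g = NetworkGraph(
            n_cells=4,
            grid_side=2,
            positions=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
            is_excitatory=np.array([True, True, True, True]),
            gj_edges=np.array([[0, 1]], dtype=np.int64),
        )
        return g

    def run(self) -> tuple[list[np.ndarray], np.ndarray]:
        """Simulate with the reference stepper.

        Returns (spike_times per cell for the coupled pair, voltage trace
        of shape (n_steps, 2)).
        """
        params = NeuronParams(
            **{
                **self.neuron.__dict__,
                "g_c": self.g_c,
            }
        )
        graph = self.graph()
        rng = np.random.default_rng(self.seed)
        n_steps = int(round(self.duration / self.dt))
        state = NetworkState.at_rest(graph.n_cells, params)
        spikes: list[list[float]] = [[], []]
        vtrace = np.empty((n_steps, 2))
        p_shared = self.shared_rate * self.dt
        p_ind = self.independent_rate * self.dt
        for k in range(n_steps):
            inc = np.zeros(graph.n_cells)
            if rng.random() < p_shared:
                inc[0] += self.increment
                inc[1] += self.increment
            hits = rng.random(2) < p_ind
            inc[:2] += hits * self.increment
            state, spikers = step(
                state, graph, params, incoming_increments_E=inc, dt=self.dt
            )
            t = (k + 1) * self.dt
            for c in spikers:
                if c < 2:
                    spikes[c].append(t)
            vtrace[k] = state.v[:2]
        return [np.asarray(s) for s in spikes], vtrace

    def contraction_rate(self, g_E: float = 0.0, g_I: float = 0.0) -> float:
        """Analytic decay rate (1/s) of the voltage difference of the pair
        under matched, constant conductances."""
        return (1.0 + g_E + g_I + 2.0 * self.g_c) / self.neuron.tau_m


def make_two_cell_gj_scenario(
    g_c: float, shared_rate: float, **kwargs
) -> ScriptedScenario:
    """Factory for the two-cell GJ scenario (see ScriptedScenario)."""
    return ScriptedScenario(g_c=g_c, shared_rate=shared_rate, **kwargs)


def event_driven_plasticity_oracle(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    params: PlasticityParams,
    rule: str = "triplet",
    w0: float = 0.0,
    g_max: float | None = None,
    learning_rate: float | None = None,
    tie: str = "pre_first",
    return_trajectory: bool = False,
):
    """Exact event-driven evaluation of the plasticity rules for one synapse.

    Tracers decay analytically between events; updates follow the module's
    event order (depression before the pre tracer increment, potentiation
    with the slow postsynaptic tracer read before its own increment).  For
    the triplet rule the postsynaptic rate estimate mu is rebuilt from the
    post train with the 1-second low-pass filter.

    ``tie`` selects which side of a simultaneous pre/post pair is processed
    first (both occur in the clock-driven path when two coupled cells spike
    in the same step, in cell-index order).

    Returns the final weight, or (times, weights) when
    ``return_trajectory``.
    """
    pre_times = np.asarray(pre_times, dtype=float)
    post_times = np.asarray(post_times, dtype=float)
    for name, t in (("pre_times", pre_times), ("post_times", post_times)):
        if np.any(np.diff(t) < 0):
            raise ValueError(f"{name} must be sorted")
    if rule not in ("triplet", "istdp"):
        raise ValueError("rule must be 'triplet' or 'istdp'")
    if tie not in ("pre_first", "post_first"):
        raise ValueError("tie must be 'pre_first' or 'post_first'")
    if rule == "triplet":
        if g_max is None or learning_rate is None:
            raise ValueError("triplet rule needs g_max and learning_rate")
    else:
        g_max = params.g_i_max

    # merge events; PRE=0, POST=1
    tie_rank = {"pre_first": (0, 1), "post_first": (1, 0)}[tie]
    events = [(t, tie_rank[0], 0) for t in pre_times] + [
        (t, tie_rank[1], 1) for t in post_times
    ]
    events.sort()

    r1 = o1 = o2 = mu = xE = xI = 0.0
    w = float(w0)
    t_now = 0.0
    traj_t, traj_w = [0.0], [w]
    for t, _, kind in events:
        dtau = t - t_now
        r1 *= math.exp(-dtau / params.tau_r1)
        o1 *= math.exp(-dtau / params.tau_o1)
        o2 *= math.exp(-dtau / params.tau_o2)
        mu *= math.exp(-dtau / params.tau_rate_filter)
        xE *= math.exp(-dtau / params.tau_istdp)
        xI *= math.exp(-dtau / params.tau_istdp)
        t_now = t
        if rule == "triplet":
            if kind == 0:  # pre spike: depression, then r1 jump
                a_ltd = (
                    params.tau_r1
                    * params.tau_o2
                    * mu
                    * mu
                    / (params.rho_target * params.tau_o1)
                    * learning_rate
                )
                w = min(max(w - o1 * a_ltd, 0.0), g_max)
                r1 += 1.0
            else:  # post spike: potentiation with o2(t - eps)
                w = min(max(w + r1 * o2 * learning_rate, 0.0), g_max)
                o1 += 1.0
                o2 += 1.0
                mu += 1.0 / params.tau_rate_filter
        else:
            if kind == 0:  # inhibitory pre spike
                dw = (xE - 2.0 * params.rho_target * params.tau_istdp) * params.A_istdp
                w = min(max(w + dw, 0.0), g_max)
                xI += 1.0
            else:  # excitatory post spike
                w = min(max(w + xI * params.A_istdp, 0.0), g_max)
                xE += 1.0
        traj_t.append(t)
        traj_w.append(w)
    if return_trajectory:
        return np.asarray(traj_t), np.asarray(traj_w)
    return w


def clock_driven_plasticity(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    params: PlasticityParams,
    dt: float = DEFAULT_DT,
    rule: str = "triplet",
    w0: float = 0.0,
    g_max: float | None = None,
    learning_rate: float | None = None,
    tie: str = "pre_first",
) -> float:
    """Clock-driven counterpart of the oracle for one synapse.

    Spike times are rounded to the step grid; tracers decay by the exact
    per-step exponential factor each step and updates fire on spike steps
    in the oracle's event order.  Used to measure the O(dt) discretization
    error of the simulator's plasticity bookkeeping.
    """
    pre_steps = np.round(np.asarray(pre_times, dtype=float) / dt).astype(int)
    post_steps = np.round(np.asarray(post_times, dtype=float) / dt).astype(int)
    if rule == "triplet" and (g_max is None or learning_rate is None):
        raise ValueError("triplet rule needs g_max and learning_rate")
    if rule == "istdp":
        g_max = params.g_i_max
    n_steps = int(max(pre_steps.max(initial=0), post_steps.max(initial=0))) + 1
    pre_count = np.bincount(pre_steps, minlength=n_steps)
    post_count = np.bincount(post_steps, minlength=n_steps)
    d_r1 = math.exp(-dt / params.tau_r1)
    d_o1 = math.exp(-dt / params.tau_o1)
    d_o2 = math.exp(-dt / params.tau_o2)
    d_mu = math.exp(-dt / params.tau_rate_filter)
    d_x = math.exp(-dt / params.tau_istdp)
    r1 = o1 = o2 = mu = xE = xI = 0.0
    w = float(w0)
    for k in range(n_steps):
        r1 *= d_r1
        o1 *= d_o1
        o2 *= d_o2
        mu *= d_mu
        xE *= d_x
        xI *= d_x
        order = ((0, pre_count[k]), (1, post_count[k]))
        if tie == "post_first":
            order = order[::-1]
        for kind, count in order:
            for _ in range(count):
                if rule == "triplet":
                    if kind == 0:
                        a_ltd = (
                            params.tau_r1
                            * params.tau_o2
                            * mu
                            * mu
                            / (params.rho_target * params.tau_o1)
                            * learning_rate
                        )
                        w = min(max(w - o1 * a_ltd, 0.0), g_max)
                        r1 += 1.0
                    else:
                        w = min(max(w + r1 * o2 * learning_rate, 0.0), g_max)
                        o1 += 1.0
                        o2 += 1.0
                        mu += 1.0 / params.tau_rate_filter
                else:
                    if kind == 0:
                        dw = (
                            xE - 2.0 * params.rho_target * params.tau_istdp
                        ) * params.A_istdp
                        w = min(max(w + dw, 0.0), g_max)
                        xI += 1.0
                    else:
                        w = min(max(w + xI * params.A_istdp, 0.0), g_max)
                        xE += 1.0
    return w
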