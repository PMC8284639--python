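"""Conductance-based leaky integrate-and-fire dynamics with gap junctions.

The subthreshold voltage of cell i obeys

    tau_m dv_i/dt = -(v_i - v_l) - g_E,i (v_i - v_E) - g_I,i (v_i - v_I)
                    - g_c sum_j (v_i - v_j),

with the gap-junction (GJ) sum over the cell's electrically coupled
partners (excitatory cells only).  Conductances have instantaneous rise and
exponential decay; a spike at threshold -45 mV resets the cell to -60 mV
and delivers a 1 mV instantaneous "spikelet" to each GJ partner.

This module provides the reference clock-driven step used by unit tests and
scripted scenarios; long simulations run through the numba kernel in
:mod:`gjcortex._kernels`, which reproduces the exact same event ordering
(conductance decay -> apply arrivals -> Euler voltage update with the
previous step's voltages in the GJ sum -> threshold detection -> reset ->
spikelets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gjcortex.network import NetworkGraph

__all__ = ["NeuronParams", "NetworkState", "step", "DEFAULT_DT"]

DEFAULT_DT = 1e-4  # s; resolves spike timing well below every STDP timescale


@dataclass(frozen=True)
class NeuronParams:
    """Membrane and coupling constants (conductances are normalized by the
    leak conductance and unitless)."""

    tau_m: float = 0.020  # s
    v_leak: float = -60.0  # mV
    v_exc: float = 0.0  # mV
    v_inh: float = -80.0  # mV
    v_threshold: float = -45.0  # mV
    v_reset: float = -60.0  # mV
    g_c: float = 0.06  # GJ conductance when coupling is on
    spikelet_mv: float = 1.0  # mV jump in the post-junctional cell
    sigma_E: float = 0.011  # s, excitatory conductance decay
    sigma_I: float = 0.015  # s, inhibitory conductance decay
    # Absolute refractory period (voltage clamped at reset).  Without it the
    # all-to-all recurrent phase admits an unphysical every-step-firing
    # attractor in which the excitatory volley capacity outruns the maximal
    # inhibitory capacity; 2 ms caps instantaneous rates at physiological
    # values and restores the burst-then-balance regime.
    refractory: float = 0.002  # s

    def __post_init__(self):
        if self.v_reset >= self.v_threshold:
            raise ValueError("v_reset must lie below v_threshold")
        for name in ("tau_m", "sigma_E", "sigma_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NetworkState:
    """Per-cell dynamical variables."""

    v: np.ndarray  # mV
    g_E: np.ndarray  # unitless
    g_I: np.ndarray
    last_spike_flags: np.ndarray  # bool, spikes of the current step
    refrac_steps_left: np.ndarray | None = None  # int; None = all zero

    @classmethod
    def at_rest(cls, n_cells: int, params: NeuronParams) -> "NetworkState":
        return cls(
            v=np.full(n_cells, params.v_leak, dtype=float),
            g_E=np.zeros(n_cells),
            g_I=np.zeros(n_cells),
            last_spike_flags=np.zeros(n_cells, dtype=bool),
            refrac_steps_left=np.zeros(n_cells, dtype=np.int64),
        )

    @classmethod
    def random_v(
        cls, n_cells: int, params: NeuronParams, rng: np.random.Generator
    ) -> "NetworkState":
        """Voltages uniform on [v_reset, v_threshold) to avoid an initial
        artificial synchrony of identical cells."""
        st = cls.at_rest(n_cells, params)
        st.v = rng.uniform(params.v_reset, params.v_threshold, size=n_cells)
        return st


def step(
    state: NetworkState,
    graph: NetworkGraph,
    params: NeuronParams,
    incoming_increments_E: np.ndarray | None = None,
    incoming_increments_I: np.ndarray | None = None,
    dt: float = DEFAULT_DT,
    gj_on: bool = True,
) -> tuple[NetworkState, np.ndarray]:
    """Advance the network by one step of length ``dt``.

    Order of events: (i) conductances decay by their exact exponential
    factors, then receive the non-negative ``incoming_increments``;
    (ii) voltages advance one forward-Euler step, with the GJ resistive term
    evaluated from the previous step's voltages (a spiking cell contributes
    its pre-reset voltage); refractory cells stay clamped at ``v_reset``;
    (iii) non-refractory cells at or above threshold are recorded as
    spiking, reset, and enter the refractory period; (iv) each spiker adds
    ``spikelet_mv`` to every GJ partner's post-reset voltage, capped at
    threshold so a spikelet alone cannot trigger a spike.

    Returns the new state and the array of spiking cell ids.

    Raises
    ------
    FloatingPointError
        If any voltage becomes non-finite (dt too large / instability).
    """
    n = graph.n_cells
    g_E = state.g_E * np.exp(-dt / params.sigma_E)
    g_I = state.g_I * np.exp(-dt / params.sigma_I)
    if incoming_increments_E is not None:
        if np.any(np.asarray(incoming_increments_E) < 0):
            raise ValueError("conductance increments must be non-negative")
        g_E = g_E + incoming_increments_E
    if incoming_increments_I is not None:
        if np.any(np.asarray(incoming_increments_I) < 0):
            raise ValueError("conductance increments must be non-negative")
        g_I = g_I + incoming_increments_I

    v_prev = state.v
    gj_term = np.zeros(n)
    if gj_on and params.g_c != 0.0 and len(graph.gj_edges):
        a = graph.gj_edges[:, 0]
        b = graph.gj_edges[:, 1]
        diff = v_prev[a] - v_prev[b]
        np.add.at(gj_term, a, diff)
        np.add.at(gj_term, b, -diff)

    dv = (
        -(v_prev - params.v_leak)
        - g_E * (v_prev - params.v_exc)
        - g_I * (v_prev - params.v_inh)
        - params.g_c * gj_term * (1.0 if gj_on else 0.0)
    ) * (dt / params.tau_m)
    v = v_prev + dv
    if not np.all(np.isfinite(v)):
        bad = np.flatnonzero(~np.isfinite(v))
        raise FloatingPointError(
            f"non-finite voltage in cells {bad[:5]}: integration unstable "
            "(reduce dt)"
        )

    refrac = state.refrac_steps_left
    if refrac is None:
        refrac = np.zeros(n, dtype=np.int64)
    refrac = refrac.copy()
    in_refrac = refrac > 0
    v[in_refrac] = params.v_reset
    refrac[in_refrac] -= 1

    spiking = (v >= params.v_threshold) & ~in_refrac
    spikers = np.flatnonzero(spiking)
    v[spiking] = params.v_reset
    refrac[spiking] = int(round(params.refractory / dt))

    if len(spikers) and len(graph.gj_edges):
        # spikelets land after this step's threshold detection, so they can
        # recruit the partner at the next step but never within this one
        a = graph.gj_edges[:, 0]
        b = graph.gj_edges[:, 1]
        kick = np.zeros(n)
        np.add.at(kick, b[spiking[a]], params.spikelet_mv)
        np.add.at(kick, a[spiking[b]], params.spikelet_mv)
        v = v + kick

    new_state = NetworkState(
        v=v, g_E=g_E, g_I=g_I, last_spike_flags=spiking, refrac_steps_left=refrac
    )
    return new_state, spikers
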