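"""Triplet STDP with a homeostatic depression amplitude, and inhibitory STDP.

Plastic synapses
----------------
* LGN -> E and E -> E excitatory synapses follow the *minimal triplet rule*:
  at a presynaptic spike the weight is depressed by ``o1 * A_LTD`` (o1: fast
  postsynaptic tracer); at a postsynaptic spike it is potentiated by
  ``r1 * o2(t - eps) * A_LTP`` (r1: presynaptic tracer, o2: slow
  postsynaptic tracer read *before* its own spike increment).  Potentiation
  therefore requires the postsynaptic cell to have fired recently — a pre
  spike flanked by two post spikes.
* The depression amplitude is homeostatic,

      A_LTD(t) = (tau_r1 * tau_o2 * mu_E(t)^2) / (rho * tau_o1) * A_LTP,

  where mu_E is a 1-second low-pass estimate of the postsynaptic firing
  rate and rho = 8 Hz the target rate: above-target firing boosts
  depression quadratically, pinning excitatory rates near rho.
* I -> E synapses follow iSTDP: at an inhibitory pre spike the weight moves
  by ``(x_E - 2 rho tau_istdp) * A_istdp`` (potentiation when the excitatory
  target fired recently, depression otherwise); at an excitatory post spike
  it is potentiated by ``x_I * A_istdp``.

All tracers jump by +1 at their neuron's spike (the convention under which
the learning-rate constants are calibrated) and decay exponentially between
spikes.  All plastic weights are hard-clipped to [0, g_max].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gjcortex.network import NetworkGraph

__all__ = [
    "PlasticityParams",
    "PlasticityTraces",
    "a_ltd",
    "decay_traces",
    "on_pre_spike_triplet",
    "on_post_spike_triplet",
    "update_rate_estimate",
    "on_pre_spike_istdp",
    "on_post_spike_istdp",
    "initialize_weights",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Learning rates, tracer time constants and weight bounds."""

    A_LTP_lgn: float = 0.005  # LGN->E learning rate (weight units)
    A_LTP_cort: float = 0.015  # E->E learning rate
    tau_r1: float = 0.0168  # s, presynaptic tracer
    tau_o1: float = 0.0337  # s, fast postsynaptic tracer (depression)
    tau_o2: float = 0.114  # s, slow postsynaptic tracer (triplet LTP)
    rho_target: float = 8.0  # Hz, homeostatic target rate
    tau_rate_filter: float = 1.0  # s, low-pass of the post spike train
    A_istdp: float = 0.008  # iSTDP learning rate
    tau_istdp: float = 0.020  # s, iSTDP tracers x_E, x_I
    g_lgn_max: float = 0.02  # max LGN->E weight
    g_ee_max: float = 0.025  # max E->E weight
    g_i_max: float = 0.05  # max I->E weight
    g_ie_frac: float = 0.1  # fixed E->I strength, fraction of g_ee_max
    g_ii_frac: float = 0.3  # fixed I->I strength, fraction of g_i_max
    g_back: float = 0.02  # background spike strength
    lgn_init_lo: float = 0.0  # initial LGN->E weights, fraction of g_lgn_max
    lgn_init_hi: float = 1.0
    ee_init_lo: float = 0.25  # initial E->E weights, fraction of g_ee_max
    ee_init_hi: float = 0.35
    ei_init_frac: float = 0.5  # initial I->E weight, fraction of g_i_max

    def __post_init__(self):
        for name in ("tau_r1", "tau_o1", "tau_o2", "tau_rate_filter", "tau_istdp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_lgn_max", "g_ee_max", "g_i_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.g_ie_frac <= 1 or not 0 <= self.g_ii_frac <= 1:
            raise ValueError("fixed strengths must lie within their maxima")

    @property
    def g_ie_fixed(self) -> float:
        return self.g_ie_frac * self.g_ee_max

    @property
    def g_ii_fixed(self) -> float:
        return self.g_ii_frac * self.g_i_max


@dataclass
class PlasticityTraces:
    """Per-neuron tracers.  r1 is indexed over presynaptic units (cortical
    cells or LGN labels, depending on the pathway); o1, o2, mu_E over
    postsynaptic cells; x_E over excitatory and x_I over inhibitory cells."""

    r1: np.ndarray
    o1: np.ndarray
    o2: np.ndarray
    x_E: np.ndarray
    x_I: np.ndarray
    mu_E: np.ndarray  # Hz

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "PlasticityTraces":
        return cls(
            r1=np.zeros(n_pre),
            o1=np.zeros(n_post),
            o2=np.zeros(n_post),
            x_E=np.zeros(n_post),
            x_I=np.zeros(n_pre),
            mu_E=np.zeros(n_post),
        )


def a_ltd(mu_E, params: PlasticityParams, learning_rate: float):
    """Homeostatic depression amplitude for a postsynaptic rate estimate."""
    return (
        params.tau_r1
        * params.tau_o2
        * np.asarray(mu_E, dtype=float) ** 2
        / (params.rho_target * params.tau_o1)
        * learning_rate
    )


def decay_traces(traces: PlasticityTraces, dt: float, params: PlasticityParams) -> PlasticityTraces:
    """Exact exponential decay of every tracer over one time step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return PlasticityTraces(
        r1=traces.r1 * np.exp(-dt / params.tau_r1),
        o1=traces.o1 * np.exp(-dt / params.tau_o1),
        o2=traces.o2 * np.exp(-dt / params.tau_o2),
        x_E=traces.x_E * np.exp(-dt / params.tau_istdp),
        x_I=traces.x_I * np.exp(-dt / params.tau_istdp),
        mu_E=traces.mu_E * np.exp(-dt / params.tau_rate_filter),
    )


def on_pre_spike_triplet(
    w: float,
    o1: float,
    mu_E_post: float,
    params: PlasticityParams,
    learning_rate: float,
    g_max: float,
) -> float:
    """Depression at a presynaptic spike: w -> clip(w - o1 * A_LTD).

    The caller increments the presynaptic tracer r1 by 1 afterwards.
    """
    return float(np.clip(w - o1 * a_ltd(mu_E_post, params, learning_rate), 0.0, g_max))


def on_post_spike_triplet(
    w: float,
    r1: float,
    o2_before: float,
    params: PlasticityParams,
    learning_rate: float,
    g_max: float,
) -> float:
    """Potentiation at a postsynaptic spike: w -> clip(w + r1 * o2 * A_LTP),
    with o2 read before this spike's own increment.  The caller increments
    o1 and o2 by 1 afterwards."""
    return float(np.clip(w + r1 * o2_before * learning_rate, 0.0, g_max))


def update_rate_estimate(mu_E, spiked, dt: float, tau: float = 1.0):
    """One step of the low-pass rate filter: decay, then +1/tau per spike.

    Equals (1/tau) * sum_k exp(-(t - t_k)/tau) over past spike times t_k.
    """
    return np.asarray(mu_E, dtype=float) * np.exp(-dt / tau) + np.asarray(
        spiked, dtype=float
    ) / tau


def on_pre_spike_istdp(w_EI: float, x_E_post: float, params: PlasticityParams) -> float:
    """iSTDP at an inhibitory presynaptic spike.

    Potentiates when the excitatory target fired within ~tau_istdp (x_E
    large), otherwise depresses by the constant offset 2*rho*tau_istdp.
    The caller increments x_I by 1 afterwards.
    """
    dw = (x_E_post - 2.0 * params.rho_target * params.tau_istdp) * params.A_istdp
    return float(np.clip(w_EI + dw, 0.0, params.g_i_max))


def on_post_spike_istdp(w_EI: float, x_I_pre: float, params: PlasticityParams) -> float:
    """iSTDP at an excitatory postsynaptic spike: pure potentiation by
    x_I * A_istdp.  The caller increments x_E by 1 afterwards."""
    return float(np.clip(w_EI + x_I_pre * params.A_istdp, 0.0, params.g_i_max))


def initialize_weights(
    graph: NetworkGraph,
    params: PlasticityParams,
    phase: int,
    rng_seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Draw initial weight matrices for one developmental phase.

    Phase 1 initializes the plastic LGN->E weights (uniform on
    [lgn_init_lo, lgn_init_hi] * g_lgn_max on existing connections) and
    leaves every recurrent weight zero.  Phase 2 initializes E->E weights
    uniform on [0.25, 0.35] * g_ee_max on the recurrent mask and I->E
    weights at 0.5 * g_i_max.

    Returns a dict with keys ``w_lgn`` (n_cells x n_lgn; inhibitory rows
    carry their fixed strengths), ``w_ee`` and ``w_ei`` (n_cells x n_cells,
    post x pre).
    """
    if graph.lgn_map is None:
        raise ValueError("graph has no LGN projection")
    rng = np.random.default_rng(rng_seed)
    n = graph.n_cells
    exc = graph.is_excitatory

    w_lgn = np.array(graph.lgn_weights_inh, dtype=float, copy=True)
    lo = params.lgn_init_lo * params.g_lgn_max
    hi = params.lgn_init_hi * params.g_lgn_max
    draw = rng.uniform(lo, hi, size=(n, graph.n_lgn))
    w_lgn[exc] = draw[exc]
    w_lgn *= graph.lgn_map

    w_ee = np.zeros((n, n))
    w_ei = np.zeros((n, n))
    if phase == 2:
        if graph.recurrent_mask is None:
            raise ValueError("phase 2 requires a recurrent mask")
        ee_pairs = np.outer(exc, exc) & graph.recurrent_mask
        w_ee[ee_pairs] = rng.uniform(
            params.ee_init_lo * params.g_ee_max,
            params.ee_init_hi * params.g_ee_max,
            size=int(ee_pairs.sum()),
        )
        ei_pairs = np.outer(exc, ~exc) & graph.recurrent_mask
        w_ei[ei_pairs] = params.ei_init_frac * params.g_i_max
    elif phase != 1:
        raise ValueError("phase must be 1 or 2")
    return {"w_lgn": w_lgn, "w_ee": w_ee, "w_ei": w_ei}
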