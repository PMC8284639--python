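"""Two-phase developmental protocol and frozen-weight tuning measurement.

Phase 1 ("first postnatal week"): gap junctions couple the configured
excitatory subsets, the feedforward LGN synapses onto excitatory cells
learn under the triplet rule, and every recurrent synapse is silent.
Phase 2 ("second postnatal week"): gap junctions are switched off, the
plastic E->E and I->E synapses are initialized and start learning (the
LGN synapses keep learning), and the fixed E->I / I->I strengths switch
from zero to their nonzero values.

After development, tuning curves are measured with all weights frozen and
gap junctions off: each stimulus value 0, 20, ..., 980 is presented for two
seconds and per-cell firing rates are recorded and normalized by the
maximum rate across all cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gjcortex import _kernels
from gjcortex.dynamics import DEFAULT_DT, NeuronParams
from gjcortex.network import (
    NetworkGraph,
    build_lattice,
    build_lgn_projection,
    build_pairwise_gj,
    build_recurrent_mask,
    build_sister_gj,
)
from gjcortex.plasticity import PlasticityParams, initialize_weights
from gjcortex.records import SpikeRecord, TuningResult, WeightTrajectory
from gjcortex.stimulus import (
    LgnRateParams,
    StimulusTrace,
    sample_background_events,
    sample_lgn_events,
    sample_stimulus_trace,
    sweep_stimulus_trace,
)

__all__ = [
    "ProtocolConfig",
    "RunResult",
    "run_development",
    "measure_tuning",
    "scaled_plasticity",
    "study_plasticity",
]

NETWORK_MODES = ("pairwise", "sister_all_to_all", "sister_radius")


@dataclass
class ProtocolConfig:
    """Everything needed to reproduce one developmental run."""

    n_cells: int = 400
    n_lgn: int = 1000
    p_inhibitory: float = 0.2
    p_lgn_connect: float = 0.25
    network_mode: str = "pairwise"
    fraction_coupled: float = 0.5  # pairwise mode
    n_sister_groups: int = 6  # sister modes
    p_gj: float = 0.05  # sister modes
    ee_radius: float | None = None  # grid units; None = all-to-all E->E
    gj_population: str = "excitatory"
    phase1_duration: float = 600.0  # s; phase 2 starts here
    total_duration: float = 1200.0  # s
    gj_on_in_phase1: bool = True
    mean_stimulus_duration: float = 0.020  # s
    background_rate: float = 0.5  # Hz per cell
    dt: float = DEFAULT_DT
    snapshot_period: float = 10.0  # s of simulated time between snapshots
    seed: int = 0  # base seed; per-stream seeds below override when set
    graph_seed: int | None = None
    stimulus_seed: int | None = None
    dynamics_seed: int | None = None
    max_rate_hz: float = 300.0  # spike-buffer headroom per cell

    def __post_init__(self):
        if self.network_mode not in NETWORK_MODES:
            raise ValueError(f"network_mode must be one of {NETWORK_MODES}")
        if self.gj_population != "excitatory":
            raise ValueError(
                "Gap junctions are included only among excitatory neurons; "
                f"gj_population={self.gj_population!r} is not supported"
            )
        if not 0 <= self.phase1_duration <= self.total_duration:
            raise ValueError("need 0 <= phase1_duration <= total_duration")
        if self.network_mode == "sister_radius" and self.ee_radius is None:
            raise ValueError("sister_radius mode requires ee_radius")
        if self.graph_seed is None:
            self.graph_seed = _child_seed(self.seed, 0)
        if self.stimulus_seed is None:
            self.stimulus_seed = _child_seed(self.seed, 1)
        if self.dynamics_seed is None:
            self.dynamics_seed = _child_seed(self.seed, 2)

    @property
    def phase2_start(self) -> float:
        return self.phase1_duration


def _child_seed(base: int, stream: int) -> int:
    return int(
        np.random.SeedSequence([int(base), stream]).generate_state(1)[0] % (2**31)
    )


@dataclass
class RunResult:
    """Output of one developmental run (iterable as spikes, trajectory,
    graph for positional unpacking)."""

    spikes: SpikeRecord
    trajectory: WeightTrajectory
    graph: NetworkGraph
    config: ProtocolConfig

    def __iter__(self):
        return iter((self.spikes, self.trajectory, self.graph))

    @property
    def final_weights(self) -> dict[str, np.ndarray]:
        return self.trajectory.final


def scaled_plasticity(
    n_cells: int, reference_n_cells: int = 400, **overrides
) -> PlasticityParams:
    """Plasticity parameters for a cortex smaller than the reference sheet.

    The recurrent pathways are all-to-all with fixed per-synapse strengths,
    so the population-level conductance a cell receives per spike volley is
    proportional to the cell count.  Simulating a reduced sheet therefore
    scales the per-synapse recurrent quantities (E->E and I->E maxima, the
    fixed E->I / I->I strengths via their fractions, and the corresponding
    learning rates) by reference_n/n, which preserves the reference
    network's operating point — in particular the recruitment of
    interneurons by excitatory volleys, without which the inhibitory
    plasticity cannot balance the network.  The feedforward LGN bank is not
    scaled (it is kept at full size in every configuration).
    """
    s = reference_n_cells / n_cells
    base = dict(
        g_ee_max=0.025 * s,
        g_i_max=0.05 * s,
        A_LTP_cort=0.015 * s,
        A_istdp=0.008 * s,
    )
    base.update(overrides)
    return PlasticityParams(**base)


def study_plasticity(
    n_cells: int, reference_n_cells: int = 400, inhibitory_ceiling: float = 4.0,
    **overrides,
) -> PlasticityParams:
    """The stabilized parameter set used by the packaged study conditions.

    Starts from 1/N scaling of the recurrent pathway (see
    :func:`scaled_plasticity`) and applies the package's stabilizing
    choices, documented in docs/methods.md:

    * the I->E weight ceiling carries a x``inhibitory_ceiling`` headroom
      factor so the inhibitory plasticity controller never runs out of
      authority against saturated recurrent excitation, while the fixed
      I->I strength stays at its published absolute value;
    * I->E weights start at the ceiling (maximal inhibitory authority at
      the onset of recurrence);
    * initial feedforward weights are uniform on [0.5, 1] of maximum, which
      places the network in a firing regime so homeostatic depression can
      prune competitively (low-mean inits leave it silent forever);
    * the cortical triplet learning rate keeps its published absolute value
      rather than scaling with 1/N, so per-coincidence weight changes stay
      graded relative to the scaled ceiling.
    """
    s = reference_n_cells / n_cells
    base = dict(
        g_ee_max=0.025 * s,
        g_i_max=0.05 * s * inhibitory_ceiling,
        g_ii_frac=0.3 / inhibitory_ceiling,
        ei_init_frac=1.0,
        A_LTP_cort=0.015,
        A_istdp=0.008 * s,
        lgn_init_lo=0.5,
        lgn_init_hi=1.0,
    )
    base.update(overrides)
    return PlasticityParams(**base)


def build_network(config: ProtocolConfig) -> NetworkGraph:
    """Construct the full wiring for a protocol configuration."""
    graph = build_lattice(config.n_cells, config.p_inhibitory, config.graph_seed)
    gj_rng = np.random.default_rng(_child_seed(config.graph_seed, 10))
    if config.network_mode == "pairwise":
        graph.gj_edges = build_pairwise_gj(graph, config.fraction_coupled, gj_rng)
    else:
        graph.sister_group, graph.gj_edges = build_sister_gj(
            graph, config.n_sister_groups, config.p_gj, gj_rng
        )
    graph.recurrent_mask = build_recurrent_mask(graph, config.ee_radius)
    lgn_rng = np.random.default_rng(_child_seed(config.graph_seed, 11))
    graph.lgn_map, graph.lgn_weights_inh = build_lgn_projection(
        graph, config.n_lgn, config.p_lgn_connect, lgn_rng
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# kernel-facing engine

def _csr_from_lists(lists, n_items):
    indptr = np.zeros(n_items + 1, dtype=np.int64)
    for i, lst in enumerate(lists):
        indptr[i + 1] = indptr[i] + len(lst)
    idx = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists]) if lists else np.empty(0, np.int64)
    return indptr, idx


class _Engine:
    """Mutable simulation state bound to the numba kernel."""

    def __init__(
        self,
        graph: NetworkGraph,
        neuron: NeuronParams,
        plast: PlasticityParams,
        weights: dict[str, np.ndarray],
        dt: float,
        v_rng: np.random.Generator,
    ):
        n = graph.n_cells
        self.graph = graph
        self.neuron = neuron
        self.plast = plast
        self.dt = dt
        self.is_exc = np.ascontiguousarray(graph.is_excitatory, dtype=np.bool_)

        partners = [[] for _ in range(n)]
        for a, b in graph.gj_edges:
            partners[a].append(b)
            partners[b].append(a)
        self.gj_indptr, self.gj_idx = _csr_from_lists(partners, n)

        lgn_map = graph.lgn_map
        n_lgn = lgn_map.shape[1]
        self.n_lgn = n_lgn
        posts = [np.flatnonzero(lgn_map[:, a]) for a in range(n_lgn)]
        self.lgn_post_indptr, self.lgn_post_idx = _csr_from_lists(posts, n_lgn)
        labels = [np.flatnonzero(lgn_map[i]) for i in range(n)]
        self.cell_lgn_indptr, self.cell_lgn_idx = _csr_from_lists(labels, n)

        self.ee_mask = np.ascontiguousarray(graph.recurrent_mask, dtype=np.bool_)
        # own copies: the kernel mutates weights in place
        self.w_lgn = np.array(weights["w_lgn"], dtype=np.float64, order="C")
        self.w_ee = np.array(weights["w_ee"], dtype=np.float64, order="C")
        self.w_ei = np.array(weights["w_ei"], dtype=np.float64, order="C")

        self.v = v_rng.uniform(neuron.v_reset, neuron.v_threshold, size=n)
        self.g_E = np.zeros(n)
        self.g_I = np.zeros(n)
        self.pend_E = np.zeros(n)
        self.pend_I = np.zeros(n)
        self.refrac = np.zeros(n, dtype=np.int64)
        self.ref_steps = int(round(neuron.refractory / dt))
        # seeded LCG state for the per-step spike-processing shuffle
        self.shuffle_state = np.array(
            [int(v_rng.integers(1, 2**62))], dtype=np.int64
        )

        self.r1c = np.zeros(n)
        self.o1 = np.zeros(n)
        self.o2 = np.zeros(n)
        self.xE = np.zeros(n)
        self.xI = np.zeros(n)
        self.muE = np.zeros(n)
        self.r1_lgn = np.zeros(n_lgn)
        self.ts = {
            name: np.zeros(n if name != "r1_lgn" else n_lgn, dtype=np.int64)
            for name in ("r1c", "o1", "o2", "xE", "xI", "muE", "r1_lgn")
        }
        self.step = 0  # absolute step counter

        self.spike_steps: list[np.ndarray] = []
        self.spike_cells: list[np.ndarray] = []

    def run(
        self,
        n_steps: int,
        lgn_events: tuple[np.ndarray, np.ndarray],
        bg_events: tuple[np.ndarray, np.ndarray],
        g_c: float,
        lgn_plastic: bool,
        ee_on: bool,
        ee_plastic: bool,
        istdp_on: bool,
        max_rate_hz: float = 300.0,
    ) -> None:
        """Advance ``n_steps``, consuming the event slices for this window."""
        if n_steps <= 0:
            return
        n = self.graph.n_cells
        lo, hi = self.step, self.step + n_steps
        ls, ll = lgn_events
        a0, a1 = np.searchsorted(ls, [lo, hi])
        bs, bc = bg_events
        b0, b1 = np.searchsorted(bs, [lo, hi])
        cap = int(n * n_steps * self.dt * max_rate_hz) + 10_000
        out_steps = np.empty(cap, dtype=np.int64)
        out_cells = np.empty(cap, dtype=np.int64)
        np_probe = np.empty(0, dtype=np.int64)
        probe_buf = np.empty((0, 0), dtype=np.float64)
        nk = self.neuron
        pk = self.plast
        n_spk, _ = _kernels.run_steps(
            n_steps,
            self.step,
            self.dt,
            self.v,
            self.g_E,
            self.g_I,
            self.pend_E,
            self.pend_I,
            self.refrac,
            self.ref_steps,
            self.is_exc,
            self.gj_indptr,
            self.gj_idx,
            float(g_c),
            nk.spikelet_mv,
            nk.tau_m,
            nk.v_leak,
            nk.v_exc,
            nk.v_inh,
            nk.v_threshold,
            nk.v_reset,
            nk.sigma_E,
            nk.sigma_I,
            np.ascontiguousarray(ls[a0:a1]),
            np.ascontiguousarray(ll[a0:a1]),
            np.ascontiguousarray(bs[b0:b1]),
            np.ascontiguousarray(bc[b0:b1]),
            pk.g_back,
            self.lgn_post_indptr,
            self.lgn_post_idx,
            self.cell_lgn_indptr,
            self.cell_lgn_idx,
            self.w_lgn,
            self.w_ee,
            self.w_ei,
            self.ee_mask,
            self.r1c,
            self.o1,
            self.o2,
            self.xE,
            self.xI,
            self.muE,
            self.r1_lgn,
            self.ts["r1c"],
            self.ts["o1"],
            self.ts["o2"],
            self.ts["xE"],
            self.ts["xI"],
            self.ts["muE"],
            self.ts["r1_lgn"],
            pk.A_LTP_lgn,
            pk.A_LTP_cort,
            pk.tau_r1,
            pk.tau_o1,
            pk.tau_o2,
            pk.rho_target,
            pk.tau_rate_filter,
            pk.A_istdp,
            pk.tau_istdp,
            pk.g_lgn_max,
            pk.g_ee_max,
            pk.g_i_max,
            pk.g_ie_fixed,
            pk.g_ii_fixed,
            bool(lgn_plastic),
            bool(ee_on),
            bool(ee_plastic),
            bool(istdp_on),
            out_steps,
            out_cells,
            0,
            np_probe,
            probe_buf,
            self.shuffle_state,
        )
        if n_spk == -1:
            raise RuntimeError(
                "spike buffer overflow: firing rates exceeded "
                f"{max_rate_hz} Hz sustained — network unstable"
            )
        if n_spk == -2:
            raise FloatingPointError(
                "non-finite voltage: integration unstable (reduce dt)"
            )
        self.spike_steps.append(out_steps[:n_spk].copy())
        self.spike_cells.append(out_cells[:n_spk].copy())
        self.step = hi

    def spikes(self, stimulus: StimulusTrace | None = None) -> SpikeRecord:
        if self.spike_steps:
            steps = np.concatenate(self.spike_steps)
            cells = np.concatenate(self.spike_cells)
            order = np.lexsort((cells, steps))  # canonical within-step order
            steps, cells = steps[order], cells[order]
        else:
            steps = np.empty(0, dtype=np.int64)
            cells = np.empty(0, dtype=np.int64)
        return SpikeRecord(times=steps * self.dt, cells=cells, stimulus=stimulus)

    def weights_snapshot(self) -> dict[str, np.ndarray]:
        return {
            "w_lgn": self.w_lgn.copy(),
            "w_ee": self.w_ee.copy(),
            "w_ei": self.w_ei.copy(),
        }


# ---------------------------------------------------------------------------
# developmental protocol

def run_development(
    config: ProtocolConfig,
    neuron_params: NeuronParams | None = None,
    plasticity_params: PlasticityParams | None = None,
    lgn_params: LgnRateParams | None = None,
    graph: NetworkGraph | None = None,
) -> RunResult:
    """Run the two-phase developmental simulation.

    Phase 1 occupies [0, phase1_duration): gap junctions at ``g_c`` if
    ``gj_on_in_phase1``, LGN->E plasticity active, all recurrent synapses
    silent.  Phase 2 occupies [phase1_duration, total_duration): gap
    junctions off, E->E weights initialized uniform on [0.25, 0.35] of
    g_ee_max and plastic, I->E initialized and plastic under iSTDP, fixed
    E->I / I->I strengths on, LGN plasticity continuing.

    All randomness flows from three named seed streams (graph, stimulus,
    dynamics), so reruns are bit-identical.  A pre-built ``graph`` may be
    supplied to reuse one wiring across conditions.
    """
    neuron = neuron_params or NeuronParams()
    plast = plasticity_params or PlasticityParams()
    lgnp = lgn_params or LgnRateParams()
    if graph is None:
        graph = build_network(config)

    dt = config.dt
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    if config.total_duration > 0:
        trace = sample_stimulus_trace(
            config.total_duration,
            config.mean_stimulus_duration,
            config.stimulus_seed,
            period=lgnp.period,
        )
        ev_rng = np.random.default_rng(_child_seed(config.stimulus_seed, 20))
        lgn_events = sample_lgn_events(trace, config.n_lgn, dt, ev_rng, lgnp)
        bg_events = sample_background_events(
            graph.n_cells,
            config.total_duration,
            dt,
            np.random.default_rng(_child_seed(config.stimulus_seed, 21)),
            rate=config.background_rate,
        )
    else:
        trace = None
        lgn_events = bg_events = empty

    w_rng = np.random.default_rng(_child_seed(config.graph_seed, 12))
    weights = initialize_weights(graph, plast, phase=1, rng_seed=w_rng)
    v_rng = np.random.default_rng(_child_seed(config.dynamics_seed, 30))
    engine = _Engine(graph, neuron, plast, weights, dt, v_rng)

    total_steps = int(round(config.total_duration / dt))
    phase2_step = int(round(config.phase2_start / dt))
    snap_every = max(1, int(round(config.snapshot_period / dt)))
    boundaries = sorted(
        set(range(snap_every, total_steps, snap_every))
        | {phase2_step, total_steps}
        - {0}
    )

    # phase 2 starting at t=0 means there is no GJ phase at all; a phase-2
    # start at the very end means phase 2 never runs
    phase2_initialized = phase2_step == 0 and phase2_step < total_steps
    if phase2_initialized:
        _init_phase2(engine, graph, plast, config)
    snap_times = [0.0]
    snaps = [engine.weights_snapshot()]

    for b in boundaries:
        in_phase2 = engine.step >= phase2_step and phase2_initialized
        gc = neuron.g_c if (config.gj_on_in_phase1 and not in_phase2) else 0.0
        engine.run(
            b - engine.step,
            lgn_events,
            bg_events,
            g_c=gc,
            lgn_plastic=True,
            ee_on=in_phase2,
            ee_plastic=in_phase2,
            istdp_on=in_phase2,
            max_rate_hz=config.max_rate_hz,
        )
        if (
            engine.step == phase2_step
            and engine.step < total_steps
            and not phase2_initialized
        ):
            _init_phase2(engine, graph, plast, config)
            phase2_initialized = True
        if b % snap_every == 0 or b == total_steps:
            snap_times.append(b * dt)
            snaps.append(engine.weights_snapshot())

    trajectory = WeightTrajectory(
        times=np.asarray(snap_times),
        w_lgn=np.stack([s["w_lgn"] for s in snaps]).astype(np.float32),
        w_ee=np.stack([s["w_ee"] for s in snaps]).astype(np.float32),
        w_ei=np.stack([s["w_ei"] for s in snaps]).astype(np.float32),
    )
    return RunResult(
        spikes=engine.spikes(stimulus=trace),
        trajectory=trajectory,
        graph=graph,
        config=config,
    )


def _init_phase2(engine: _Engine, graph, plast, config) -> None:
    w_rng = np.random.default_rng(_child_seed(config.graph_seed, 13))
    w2 = initialize_weights(graph, plast, phase=2, rng_seed=w_rng)
    engine.w_ee[:] = w2["w_ee"]
    engine.w_ei[:] = w2["w_ei"]


# ---------------------------------------------------------------------------
# tuning measurement

def measure_tuning(
    graph: NetworkGraph,
    final_weights: dict[str, np.ndarray],
    neuron_params: NeuronParams | None = None,
    plasticity_params: PlasticityParams | None = None,
    lgn_params: LgnRateParams | None = None,
    recurrent_on: bool = True,
    sweep_step: float = 20.0,
    dwell: float = 2.0,
    dt: float = DEFAULT_DT,
    rng_seed: int = 12345,
    background_rate: float = 0.5,
) -> TuningResult:
    """Measure per-cell tuning curves with frozen weights and GJs off.

    Presents each stimulus 0, sweep_step, ..., period-sweep_step for
    ``dwell`` seconds, records each cell's firing rate per stimulus, and
    normalizes the curves by the maximum rate across all cells.  OP is the
    stimulus of maximal response; OSI = (R_pref - R_orth)/(R_pref + R_orth)
    with R_orth taken at the sweep stimulus closest to OP + period/2;
    width is the circular full width at half (the cell's own) maximum.
    Cells with an all-zero response are flagged unselective (NaN OP/OSI).
    """
    neuron = neuron_params or NeuronParams()
    plast = plasticity_params or PlasticityParams()
    lgnp = lgn_params or LgnRateParams()
    trace = sweep_stimulus_trace(sweep_step, dwell, lgnp.period)
    n_lgn = final_weights["w_lgn"].shape[1]
    ev_rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 40]))
    lgn_events = sample_lgn_events(trace, n_lgn, dt, ev_rng, lgnp)
    bg_events = sample_background_events(
        graph.n_cells,
        trace.total_time,
        dt,
        np.random.default_rng(np.random.SeedSequence([int(rng_seed), 41])),
        rate=background_rate,
    )
    v_rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 42]))
    engine = _Engine(graph, neuron, plast, final_weights, dt, v_rng)
    n_steps = int(round(trace.total_time / dt))
    engine.run(
        n_steps,
        lgn_events,
        bg_events,
        g_c=0.0,
        lgn_plastic=False,
        ee_on=recurrent_on,
        ee_plastic=False,
        istdp_on=False,
    )
    spikes = engine.spikes(stimulus=trace)

    stimuli = trace.labels
    n_stim = len(stimuli)
    rates = np.zeros((graph.n_cells, n_stim))
    block = np.minimum((spikes.times // dwell).astype(int), n_stim - 1)
    np.add.at(rates, (spikes.cells, block), 1.0)
    rates /= dwell
    return tuning_from_rates(stimuli, rates, graph.is_excitatory, lgnp.period)


def tuning_from_rates(
    stimuli: np.ndarray,
    rates: np.ndarray,
    is_excitatory: np.ndarray,
    period: float = 1000.0,
) -> TuningResult:
    """Derive OP, OSI, width and height from raw per-stimulus rates."""
    n_cells, n_stim = rates.shape
    global_max = rates.max()
    curves = rates / global_max if global_max > 0 else rates.copy()
    op = np.full(n_cells, np.nan)
    osi = np.full(n_cells, np.nan)
    width = np.full(n_cells, np.nan)
    height = np.zeros(n_cells)
    selective = np.zeros(n_cells, dtype=bool)
    half_offset = int(round(period / 2 / (stimuli[1] - stimuli[0])))
    sweep_step = stimuli[1] - stimuli[0]
    for i in range(n_cells):
        peak = rates[i].max()
        if peak <= 0:
            continue
        selective[i] = True
        k = int(np.argmax(rates[i]))
        op[i] = stimuli[k]
        r_orth = rates[i, (k + half_offset) % n_stim]
        osi[i] = (peak - r_orth) / (peak + r_orth)
        half = peak / 2.0
        above = rates[i] >= half
        # walk outwards from the peak on the circular sweep
        w = 1
        j = k
        while w < n_stim:
            j = (j + 1) % n_stim
            if not above[j]:
                break
            w += 1
        j = k
        while w < n_stim:
            j = (j - 1) % n_stim
            if not above[j]:
                break
            w += 1
        width[i] = w * sweep_step
        height[i] = curves[i, k]
    return TuningResult(
        stimuli=np.asarray(stimuli, dtype=float),
        curves=curves,
        rates=rates,
        op=op,
        osi=osi,
        width=width,
        height=height,
        selective=selective,
        is_excitatory=np.asarray(is_excitatory, dtype=bool),
    )
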