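# Methods

`gjcortex` simulates a small patch of developing rodent primary visual
cortex in which transient gap junctions (GJs) between excitatory neurons
shape the formation of orientation preference (OP) before chemical
recurrent synapses mature.  This note records the model, its parameters,
the numerical scheme, and — explicitly — the stabilizing completions this
package adds to make the published parameter set operable, so that users
can judge what the simulations do and do not show.

## Neuron and network model

Cortical cells sit on a square grid with periodic boundary conditions and
are excitatory (E) with probability 0.8, inhibitory (I) otherwise.  The
subthreshold voltage follows a conductance-based leaky integrate-and-fire
equation

    tau_m dv_i/dt = -(v_i - v_l) - g_E,i (v_i - v_E) - g_I,i (v_i - v_I)
                    - g_c sum_j (v_i - v_j),

with tau_m = 20 ms, v_l = -60 mV, v_E = 0 mV, v_I = -80 mV, threshold
-45 mV and reset -60 mV.  Conductances are normalized by the leak
conductance (unitless), rise instantaneously at presynaptic spikes by the
synaptic weight and decay exponentially (sigma_E = 11 ms, sigma_I = 15 ms).
The last term is the resistive gap-junction current over the cell's GJ
partners (excitatory cells only, g_c = 0.06 during the first developmental
phase); a partner's action potential additionally injects a 1 mV spikelet.
The spikelet lands after the current step's threshold detection: it can
recruit the partner at the next 0.1 ms step — this spikelet-mediated
recruitment, together with the resistive contraction of the pair's voltage
difference, is the synchronization mechanism that the developmental story
rests on.

**Absolute refractory period (package addition).**  The published
description has no refractory period.  Without one, the all-to-all
recurrent phase admits a pathological attractor in which the entire
excitatory population fires on every integration step: once recurrent
weights saturate, the excitatory volley capacity (n_E x g_EE^max, weighted
by a ~45 mV driving force at threshold) exceeds the maximal inhibitory
capacity (n_I x g_I^max at ~35 mV), so the state is self-sustaining at any
network size — we verified this at the reference 400-cell scale.  We
therefore clamp each cell at its reset potential for 2 ms after every
spike.  This caps instantaneous rates at physiological values and lets the
slower inhibitory conductance win during population bursts, restoring the
burst-then-balance regime the model is meant to operate in.

## Input stage

A bank of 1000 labelled LGN synapses drives the network.  One global
stimulus s(t), uniform on the circular input space [0, 1000), is redrawn
after exponentially distributed holding times (mean 20 ms).  Synapse `a`
fires as an inhomogeneous Poisson process at

    r_a(s) = R0 + R1 [ G(s-a) + G(s-a+1000) + G(s-a-1000) ],
    G(d) = exp(-d^2 / (2 sigma^2)),

with R0 = 5 Hz, R1 = 20 Hz, sigma = 80.  Each cortical cell is connected to
each LGN synapse independently with probability 0.25.  Inhibitory cells
receive fixed feedforward strengths uniform on [0, 0.18 g_LGN^max];
excitatory feedforward strengths are plastic.  An untuned 0.5 Hz Poisson
background (increment 0.02) reaches every cell.  The input stage is never
scaled down: reducing the synapse bank reduces the per-cell conductance
drive below threshold and silences the model, so all configurations keep
the full 1000-synapse bank and scale the cortical sheet only.

## Plasticity

LGN->E and E->E synapses follow the minimal triplet rule: depression
`-o1 A_LTD` at presynaptic spikes, potentiation `+r1 o2(t-eps) A_LTP` at
postsynaptic spikes, with tracer time constants tau_r1 = 16.8 ms,
tau_o1 = 33.7 ms, tau_o2 = 114 ms, and tracer jumps of +1 per spike (the
convention under which the learning rates are calibrated).  The depression
amplitude is homeostatic,

    A_LTD(t) = tau_r1 tau_o2 mu_E(t)^2 / (rho tau_o1) x A_LTP,

with mu_E a 1-second low-pass of the postsynaptic spike train and
rho = 8 Hz.  I->E synapses follow iSTDP with learning rate 0.008 and a
20 ms coincidence window; E->I and I->I strengths are fixed at 0.1 g_EE^max
and 0.3 g_I^max once recurrence switches on.  All plastic weights are
hard-clipped to [0, g_max]; g_LGN^max = 0.02, and at the 400-cell reference
scale g_EE^max = 0.025 and g_I^max carries a x4 ceiling (below).

Event order within a step: external LGN arrivals are processed first
(conductance increment, depression at the arrival using the target's
tracers and rate estimate at that instant, then the presynaptic tracer
jump); cortical cells that spiked this step are then processed one at a
time — weight updates first, own tracer jumps last.  Cells spiking in the
same 0.1 ms step are processed in a seeded random order: a fixed index
order would deterministically favour one direction of every co-active
synapse pair and imprint a spurious, purely unidirectional connectivity
(we observed exactly this before randomizing the order).

**Initial conditions (package choices).**  The recurrent E->E weights start
uniform on [0.25, 0.35] g_EE^max as stated for the model.  The initial
LGN->E distribution is not stated; we use uniform on [0.5, 1] g_LGN^max.
This choice is load-bearing: a shot-noise estimate of the feedforward
conductance (mean ~ N_syn r w sigma_E, s.d. a few percent of that) shows
that low-mean inits such as [0.25, 0.35] g_max leave every cell ~10
standard deviations below threshold.  Because depression vanishes at zero
rate but potentiation requires postsynaptic spikes, a silent network is an
absorbing state — it never ignites.  Initializing high puts the network in
a firing regime and lets the homeostatic depression *prune* competitively,
which is also the only direction in which this rule can act.  I->E weights
start at the inhibitory ceiling so that the onset of recurrence is met with
maximal inhibitory authority; the iSTDP controller then relaxes inhibition
toward the target-rate balance.

**Inhibitory ceiling (package addition).**  With the published I->E maximum
(0.05 at reference scale) the iSTDP controller saturates: the inhibitory
population, even at ceiling, cannot out-pull saturated recurrent
excitation, and the network locks into the refractory-paced attractor.  We
multiply the I->E ceiling by 4 and keep the fixed I->I strength at its
published absolute value (0.3 x 0.05).  The ceiling only extends the
controller's operating range; equilibrium inhibition is still set by the
target-rate fixed point, not by the bound.

## Network scaling

Small study networks (64 and 100 cells) preserve the reference operating
point by 1/N scaling of the recurrent pathway: per-synapse E->E and I->E
maxima and the fixed E->I / I->I strengths scale with 400/n, so each cell's
population-level recurrent conductance per volley is size-invariant — in
particular the recruitment of interneurons by excitatory volleys, without
which inhibitory plasticity never engages.  The iSTDP learning rate scales
likewise.  The cortical triplet learning rate is kept at its absolute
published value (0.015): scaling it up makes single coincidences move
weights by more than half their ceiling, which replaces gradual competitive
growth with per-burst saturation; the published weight trajectories are
gradual, so the slower relative rate is the faithful regime.

## Developmental protocol

Phase 1 ([0, t_2)): GJs on, feedforward plasticity on, all recurrent
synapses silent.  Phase 2 ([t_2, T]): GJs off, E->E initialized and plastic
under the triplet rule, I->E initialized and plastic under iSTDP, fixed
E->I / I->I on, feedforward plasticity continuing.  Three named seed
streams (graph, stimulus, dynamics) make runs bit-reproducible, and all
external drive is pre-sampled for the full run so checkpointing at any
chunk boundary is exact.

Tuning is measured with all weights frozen, GJs off, and plasticity
disabled: each stimulus 0, 20, ..., 980 is held for 2 s; per-cell rates are
normalized by the maximum rate over all cells.  OP is the stimulus of
maximal response; OSI = (R_pref - R_orth)/(R_pref + R_orth) with R_orth at
the sweep point closest to OP + 500; width is the circular full width at
half of the cell's own peak.  Silent cells are flagged unselective rather
than assigned OP 0.

## Numerics

Forward-Euler at dt = 0.1 ms with exact exponential decay of conductances
and tracers (tracers decay lazily, by timestamp, so per-step cost is the
voltage update).  Spikes emitted at step t reach chemical targets at step
t+1; the GJ resistive term uses the previous step's voltages; spikelets are
instantaneous.  The event-driven scalar oracle in
`gjcortex.fixtures` reproduces the same event order exactly and the test
suite verifies kernel/oracle agreement to 1e-6 g_max on recorded spike
trains, plus first-order convergence in dt for off-grid spike times.

## Study conditions and problem sizes

The packaged study configurations, chosen once:

* construction statistics (GJ degree, group sizes): the 256-cell network
  exactly as described, 1000 seeds;
* two-phase development (homeostatic rate level, feedforward bimodality):
  100-cell pairwise sheet, full LGN bank, 300 s phase 1 + 300 s phase 2,
  three seeds; end-state connectivity statistics use a longer 600 s
  phase 2;
* sister-group experiments (OP sharing vs density, learning-rate
  contrast): 64-cell sheet, six sister groups, 450 s phase 1,
  frozen-weight tuning, five seeds per density;
* synchrony events: 64-cell sister sheets at 5/10/20% coupling, 150 s of
  phase 1, events counted over the final 100 s, five seeds per density;
* map-disorder orderings: 64-cell sheet, E->E radius 2 grid units (the
  published radius-4 disc scaled with the grid side), phase-2 start times
  100/300/500 s with 250 s of recurrent learning each, three seeds per
  arm.

## Known limitations

* With the published homeostatic form, stimulus-locked firing is bursty:
  the 1-second rate estimate jumps by 1 Hz-unit per spike, so the
  depression amplitude (quadratic in the estimate) penalizes bursts
  heavily.  The network therefore equilibrates at mean excitatory rates of
  a few Hz — below the 8 Hz target — and potentiates roughly 15-25% of a
  cell's feedforward synapses to ceiling rather than "about half".
  Quantities tied to the absolute rate level inherit this bias.
* All-to-all phase-2 runs can drift into global up/down bursting whose
  high-rate epochs erode the feedforward weights (the quadratic
  depression term) until the network falls silent; silence is absorbing.
  This happens seed-dependently — for some seeds within a few hundred
  seconds of recurrence — and is insensitive to the initial inhibitory
  level.  Statistics averaged over seeds therefore mix live and dead
  networks.
* All-to-all recurrence homogenizes OPs (as described for networks without
  GJs), so OP-sharing contrasts are measured at the end of phase 1, before
  recurrent influence overwrites them.
* The synthetic stimulus is an abstract circular input space: no retinal
  waves, ON/OFF structure, or natural-image statistics; passing tests show
  the mechanism's internal consistency, not quantitative agreement with
  biological cortex.
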