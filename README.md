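# gjcortex

A spiking-network model of the first two postnatal weeks of mouse primary
visual cortex, built to study how transient **gap junctions (GJs) between
excitatory neurons** shape the development of orientation preference (OP)
and recurrent connectivity.  It is aimed at computational neuroscientists
who want a compact, fully reproducible testbed for the
"electrical-coupling-seeds-the-salt-and-pepper-map" hypothesis.

## The model

Cortical cells (80% excitatory) sit on a periodic square grid and follow a
conductance-based leaky integrate-and-fire equation

```
tau_m dv_i/dt = -(v_i - v_l) - g_E,i (v_i - v_E) - g_I,i (v_i - v_I)
                - g_c  sum_j (v_i - v_j)
```

where the last term is the resistive gap-junction current over the cell's
electrically coupled partners; a partner's spike also injects a 1 mV
spikelet.  A bank of 1000 Poisson "LGN" synapses drives the network with
stimulus-tuned rates `r_a(s) = R0 + R1 G_sigma(s - a)` (circularly
wrapped; R0 = 5 Hz, R1 = 20 Hz, sigma = 80) under a global stimulus
redrawn every ~20 ms.

Plasticity: feedforward (LGN→E) and recurrent (E→E) synapses follow the
minimal **triplet STDP rule** — depression `-o1 A_LTD` at presynaptic
spikes, potentiation `+r1 o2 A_LTP` at postsynaptic spikes — with a
homeostatic depression amplitude `A_LTD ∝ mu_E^2 / rho` (mu_E: 1-s
low-passed firing rate, rho = 8 Hz target).  Inhibitory→excitatory
synapses follow iSTDP.  Development has two phases: phase 1 with GJs on
and only feedforward learning, phase 2 with GJs off and plastic recurrence.

The package implements the published parameter set plus a small number of
stabilizing completions (an absolute refractory period, an inhibitory
weight-ceiling headroom factor, high feedforward initial weights) without
which the printed model either never fires or saturates; these are derived
and documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Build a 100-cell pairwise-coupled network, run 300 s of GJ-coupled
feedforward learning plus 300 s of recurrent learning, then measure tuning
and statistics:

```bash
gjcortex simulate --out run.h5 --seed 7 --n-cells 100 \
    --phase2-start 300 --total 600
gjcortex measure-tuning --run run.h5 --out tuning.csv
gjcortex analyze --run run.h5 --tuning tuning.csv --out stats.json
```

which prints

```
wrote run.h5: 93436 spikes, 19 GJ edges, mean E rate (last window) 3.48 Hz
wrote tuning.csv: 77/77 selective excitatory cells, median OSI 1.00
wrote stats.json
```

Reading: after development most excitatory cells are orientation selective
(OSI near 1 means the cell responds at its preferred stimulus and barely
at the orthogonal one), the network fires at a few Hz, and `stats.json`
contains the GJ-vs-control OP-difference means, the Kullback–Leibler
divergence of the OP histogram from uniform, network-synchronous-event
rates per GJ group and the bidirectional/unidirectional connectivity
fractions.  The same pipeline is available as a library
(`gjcortex.run_development`, `gjcortex.measure_tuning`,
`gjcortex.analysis`); every run is bit-reproducible from its seed.

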