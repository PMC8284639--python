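"""Clock-driven simulation kernel (numba).

Reproduces exactly the per-step event order of :func:`gjcortex.dynamics.step`
(conductance decay -> arrivals -> Euler voltage update with previous-step
voltages in the GJ sum -> threshold/reset -> spikelets) and interleaves the
plasticity updates of :mod:`gjcortex.plasticity`:

* external LGN events scheduled for a step are applied at the start of that
  step (conductance increment, then Eq.-order depression of the target
  weight using the postsynaptic o1 and rate estimate at arrival time, then
  the presynaptic tracer increment);
* cortical spikes detected at a step deliver their conductance increments
  to targets at the *next* step and are processed sequentially in ascending
  cell index, each cell applying its weight updates with tracer values as
  of that point and incrementing its own tracers last.

All plasticity tracers and the low-pass rate estimate decay lazily: each
carries the step at which it was last touched and is decayed by the exact
exponential factor on access, so the per-step cost is dominated by the
voltage update.
"""

from __future__ import annotations

import math

import numba
import numpy as np

__all__ = ["run_steps"]


@numba.njit(inline="always")
def _lazy(vals, ts, k, step, dt, tau):
    """Decay tracer k exactly from its last-update step to ``step``."""
    if ts[k] != step:
        vals[k] *= math.exp(-(step - ts[k]) * dt / tau)
        ts[k] = step
    return vals[k]


@numba.njit(cache=True)
def run_steps(
    n_steps,
    step0,
    dt,
    # dynamical state (modified in place)
    v,
    g_E,
    g_I,
    pend_E,
    pend_I,
    refrac,
    ref_steps,
    # wiring
    is_exc,
    gj_indptr,
    gj_idx,
    # neuron parameters
    g_c,
    spikelet_mv,
    tau_m,
    v_leak,
    v_exc,
    v_inh,
    v_th,
    v_reset,
    sig_E,
    sig_I,
    # pre-sampled external events for this chunk (absolute steps, sorted)
    lgn_ev_steps,
    lgn_ev_labels,
    bg_ev_steps,
    bg_ev_cells,
    g_back,
    # LGN projection (CSR both ways)
    lgn_post_indptr,
    lgn_post_idx,
    cell_lgn_indptr,
    cell_lgn_idx,
    # weights (modified in place) and recurrent adjacency
    w_lgn,
    w_ee,
    w_ei,
    ee_mask,
    # plasticity tracers and their last-update steps (modified in place)
    r1c,
    o1,
    o2,
    xE,
    xI,
    muE,
    r1_lgn,
    ts_r1c,
    ts_o1,
    ts_o2,
    ts_xE,
    ts_xI,
    ts_mu,
    ts_r1lgn,
    # plasticity parameters
    A_ltp_lgn,
    A_ltp_cort,
    tau_r1,
    tau_o1,
    tau_o2,
    rho,
    tau_mu,
    A_istdp,
    tau_istdp,
    g_lgn_max,
    g_ee_max,
    g_i_max,
    g_ie_fixed,
    g_ii_fixed,
    # phase switches
    lgn_plastic,
    ee_on,
    ee_plastic,
    istdp_on,
    # outputs
    out_steps,
    out_cells,
    probe_every,
    probe_cells,
    probe_buf,
    shuffle_state,
):
    """Advance the network ``n_steps`` steps from absolute step ``step0``.

    Returns (n_spikes, n_probe_samples); n_spikes is -1 if the spike buffer
    overflowed and -2 if a voltage became non-finite.
    """
    n = v.shape[0]
    dec_E = math.exp(-dt / sig_E)
    dec_I = math.exp(-dt / sig_I)
    a_ltd_scale_lgn = tau_r1 * tau_o2 / (rho * tau_o1) * A_ltp_lgn
    a_ltd_scale_cort = tau_r1 * tau_o2 / (rho * tau_o1) * A_ltp_cort

    lgn_ptr = 0
    bg_ptr = 0
    n_lgn_ev = lgn_ev_steps.shape[0]
    n_bg_ev = bg_ev_steps.shape[0]
    n_out = 0
    cap = out_steps.shape[0]
    n_probe = 0

    v_prev = np.empty(n)
    spikers = np.empty(n, dtype=np.int64)

    for local in range(n_steps):
        step = step0 + local

        # (i) conductance decay, then arrivals
        for i in range(n):
            g_E[i] = g_E[i] * dec_E + pend_E[i]
            g_I[i] = g_I[i] * dec_I + pend_I[i]
            pend_E[i] = 0.0
            pend_I[i] = 0.0

        while bg_ptr < n_bg_ev and bg_ev_steps[bg_ptr] == step:
            g_E[bg_ev_cells[bg_ptr]] += g_back
            bg_ptr += 1

        while lgn_ptr < n_lgn_ev and lgn_ev_steps[lgn_ptr] == step:
            a = lgn_ev_labels[lgn_ptr]
            for p in range(lgn_post_indptr[a], lgn_post_indptr[a + 1]):
                i = lgn_post_idx[p]
                g_E[i] += w_lgn[i, a]
                if lgn_plastic and is_exc[i]:
                    o1_i = _lazy(o1, ts_o1, i, step, dt, tau_o1)
                    mu_i = _lazy(muE, ts_mu, i, step, dt, tau_mu)
                    w = w_lgn[i, a] - o1_i * a_ltd_scale_lgn * mu_i * mu_i
                    w_lgn[i, a] = min(max(w, 0.0), g_lgn_max)
            _lazy(r1_lgn, ts_r1lgn, a, step, dt, tau_r1)
            r1_lgn[a] += 1.0
            lgn_ptr += 1

        # (ii) Euler voltage update; GJ sum from previous-step voltages
        for i in range(n):
            v_prev[i] = v[i]
        for i in range(n):
            gj = 0.0
            if g_c != 0.0:
                for p in range(gj_indptr[i], gj_indptr[i + 1]):
                    gj += v_prev[i] - v_prev[gj_idx[p]]
            dv = (
                -(v_prev[i] - v_leak)
                - g_E[i] * (v_prev[i] - v_exc)
                - g_I[i] * (v_prev[i] - v_inh)
                - g_c * gj
            ) * (dt / tau_m)
            v[i] = v_prev[i] + dv
            if not math.isfinite(v[i]):
                return -2, n_probe

        # (iii) refractory clamp, then threshold detection and reset
        n_spk = 0
        for i in range(n):
            if refrac[i] > 0:
                v[i] = v_reset
                refrac[i] -= 1
            elif v[i] >= v_th:
                spikers[n_spk] = i
                n_spk += 1
                v[i] = v_reset
                refrac[i] = ref_steps

        # (iv) spikelets to GJ partners (land after this step's detection,
        # so they can recruit the partner next step, never within this one)
        for k in range(n_spk):
            i = spikers[k]
            for p in range(gj_indptr[i], gj_indptr[i + 1]):
                j = gj_idx[p]
                v[j] = v[j] + spikelet_mv

        # conductance delivery (next step) and plasticity.  Cells spiking in
        # the same step are processed in a per-step random order (seeded
        # LCG): a fixed index order would systematically favour one
        # direction of every mutually-active synapse pair.
        if n_spk > 1:
            for k in range(n_spk - 1, 0, -1):
                shuffle_state[0] = (
                    shuffle_state[0] * 6364136223846793005 + 1442695040888963407
                ) & 0x7FFFFFFFFFFFFFFF
                j = (shuffle_state[0] >> 17) % (k + 1)
                tmp = spikers[k]
                spikers[k] = spikers[j]
                spikers[j] = tmp
        for k in range(n_spk):
            i = spikers[k]
            if n_out >= cap:
                return -1, n_probe
            out_steps[n_out] = step
            out_cells[n_out] = i
            n_out += 1

            if is_exc[i]:
                if ee_on:
                    for j in range(n):
                        if is_exc[j]:
                            if ee_mask[j, i]:
                                pend_E[j] += w_ee[j, i]
                        elif j != i:
                            pend_E[j] += g_ie_fixed
                # pre-role depression on outgoing E->E synapses
                if ee_plastic:
                    for j in range(n):
                        if is_exc[j] and ee_mask[j, i]:
                            o1_j = _lazy(o1, ts_o1, j, step, dt, tau_o1)
                            mu_j = _lazy(muE, ts_mu, j, step, dt, tau_mu)
                            w = w_ee[j, i] - o1_j * a_ltd_scale_cort * mu_j * mu_j
                            w_ee[j, i] = min(max(w, 0.0), g_ee_max)
                # post-role potentiation, o2 read before its own increment
                o2_i = _lazy(o2, ts_o2, i, step, dt, tau_o2)
                if lgn_plastic:
                    for p in range(cell_lgn_indptr[i], cell_lgn_indptr[i + 1]):
                        a = cell_lgn_idx[p]
                        r1_a = _lazy(r1_lgn, ts_r1lgn, a, step, dt, tau_r1)
                        w = w_lgn[i, a] + r1_a * o2_i * A_ltp_lgn
                        w_lgn[i, a] = min(max(w, 0.0), g_lgn_max)
                if ee_plastic:
                    for j in range(n):
                        if is_exc[j] and ee_mask[i, j]:
                            r1_j = _lazy(r1c, ts_r1c, j, step, dt, tau_r1)
                            w = w_ee[i, j] + r1_j * o2_i * A_ltp_cort
                            w_ee[i, j] = min(max(w, 0.0), g_ee_max)
                if istdp_on:
                    for j in range(n):
                        if not is_exc[j]:
                            xI_j = _lazy(xI, ts_xI, j, step, dt, tau_istdp)
                            w = w_ei[i, j] + xI_j * A_istdp
                            w_ei[i, j] = min(max(w, 0.0), g_i_max)
                # own tracer increments, after all weight updates
                _lazy(r1c, ts_r1c, i, step, dt, tau_r1)
                r1c[i] += 1.0
                _lazy(o1, ts_o1, i, step, dt, tau_o1)
                o1[i] += 1.0
                o2[i] += 1.0  # already decayed above
                _lazy(xE, ts_xE, i, step, dt, tau_istdp)
                xE[i] += 1.0
                _lazy(muE, ts_mu, i, step, dt, tau_mu)
                muE[i] += 1.0 / tau_mu
            else:
                if ee_on:
                    for j in range(n):
                        if is_exc[j]:
                            pend_I[j] += w_ei[j, i]
                        elif j != i:
                            pend_I[j] += g_ii_fixed
                if istdp_on:
                    for j in range(n):
                        if is_exc[j]:
                            xE_j = _lazy(xE, ts_xE, j, step, dt, tau_istdp)
                            w = w_ei[j, i] + (xE_j - 2.0 * rho * tau_istdp) * A_istdp
                            w_ei[j, i] = min(max(w, 0.0), g_i_max)
                _lazy(xI, ts_xI, i, step, dt, tau_istdp)
                xI[i] += 1.0

        if probe_every > 0 and step % probe_every == 0:
            if n_probe < probe_buf.shape[0]:
                for q in range(probe_cells.shape[0]):
                    probe_buf[n_probe, q] = v[probe_cells[q]]
                n_probe += 1

    return n_out, n_probe
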