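"""Tests of the triplet/iSTDP update kernels against hand calculations and
the event-driven oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gjcortex.fixtures import clock_driven_plasticity, event_driven_plasticity_oracle
from gjcortex.plasticity import (
    PlasticityParams,
    PlasticityTraces,
    a_ltd,
    decay_traces,
    initialize_weights,
    on_post_spike_istdp,
    on_post_spike_triplet,
    on_pre_spike_istdp,
    on_pre_spike_triplet,
    update_rate_estimate,
)

P = PlasticityParams()


class TestTraceDecay:
    def test_single_time_constant(self):
        tr = PlasticityTraces.zeros(1, 1)
        tr.r1[:] = 1.0
        out = decay_traces(tr, P.tau_r1, P)
        assert out.r1[0] == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_zero_traces_stay_zero(self):
        tr = PlasticityTraces.zeros(3, 3)
        out = decay_traces(tr, 0.01, P)
        for name in ("r1", "o1", "o2", "x_E", "x_I", "mu_E"):
            assert np.all(getattr(out, name) == 0.0)

    def test_rate_estimate_single_spike_curve(self):
        # one spike at t0: mu(t) = (1/tau) exp(-(t - t0)/tau)
        mu = update_rate_estimate(0.0, True, dt=1e-4, tau=1.0)
        for k in range(5):
            mu = update_rate_estimate(mu, False, dt=0.25, tau=1.0)
        t = 5 * 0.25
        assert mu == pytest.approx(math.exp(-t), rel=1e-9)

    def test_rate_estimate_periodic_train_converges_to_rate(self):
        """An 8 Hz periodic train drives the low-pass filter to a sawtooth
        whose mean is 8 Hz (geometric-series closed form)."""
        dt = 1e-4
        period = int(round(1 / 8.0 / dt))
        mu = 0.0
        vals = []
        for k in range(20 * 8 * period):
            spiked = k % period == 0
            mu = update_rate_estimate(mu, spiked, dt=dt, tau=1.0)
            if k > 10 * 8 * period:
                vals.append(mu)
        assert np.mean(vals) == pytest.approx(8.0, rel=0.01)


class TestTripletRule:
    def test_depression_amplitude_at_target_rate(self):
        # hand evaluation of the homeostatic amplitude at mu = rho
        expected = 0.0168 * 0.114 * 8.0**2 / (8.0 * 0.0337) * 0.005
        assert a_ltd(8.0, P, P.A_LTP_lgn) == pytest.approx(expected, abs=1e-15)

    def test_no_depression_without_postsynaptic_tracer_or_rate(self):
        w = 0.01
        assert on_pre_spike_triplet(w, 0.0, 8.0, P, P.A_LTP_lgn, P.g_lgn_max) == w
        assert on_pre_spike_triplet(w, 1.0, 0.0, P, P.A_LTP_lgn, P.g_lgn_max) == w

    def test_first_post_spike_never_potentiates(self):
        # o2(t - eps) = 0 at the first-ever post spike
        w = 0.01
        assert on_post_spike_triplet(w, 5.0, 0.0, P, P.A_LTP_lgn, P.g_lgn_max) == w
        assert on_post_spike_triplet(w, 0.0, 5.0, P, P.A_LTP_lgn, P.g_lgn_max) == w

    def test_post_pre_post_triplet_hand_computation(self):
        """post(0) - pre(10 ms) - post(20 ms), scalar bookkeeping by hand."""
        A = P.A_LTP_cort
        g_max = P.g_ee_max
        w0 = 0.5 * g_max
        # independent scalar bookkeeping
        o1 = o2 = r1 = mu = 0.0
        w = w0
        # t=0: post spike; o2 before increment = 0 -> no LTP
        o1, o2, mu = 1.0, 1.0, 1.0
        # t=10ms: pre spike: depression with decayed o1, mu
        o1_d = o1 * math.exp(-0.010 / P.tau_o1)
        mu_d = mu * math.exp(-0.010 / P.tau_rate_filter)
        w = w - o1_d * (P.tau_r1 * P.tau_o2 * mu_d**2 / (P.rho_target * P.tau_o1)) * A
        r1 = 1.0
        # t=20ms: post spike: LTP with r1, o2 decayed from their jumps
        r1_d = r1 * math.exp(-0.010 / P.tau_r1)
        o2_d = o2 * math.exp(-0.020 / P.tau_o2)
        w_expected = w + r1_d * o2_d * A

        got = event_driven_plasticity_oracle(
            np.array([0.010]),
            np.array([0.0, 0.020]),
            P,
            rule="triplet",
            w0=w0,
            g_max=g_max,
            learning_rate=A,
        )
        assert got == pytest.approx(w_expected, abs=1e-15)

    def test_weight_hard_bounds(self):
        up = on_post_spike_triplet(P.g_lgn_max, 100.0, 100.0, P, 1.0, P.g_lgn_max)
        assert up == P.g_lgn_max
        down = on_pre_spike_triplet(0.0, 100.0, 100.0, P, 1.0, P.g_lgn_max)
        assert down == 0.0


class TestIstdp:
    def test_fixed_point_of_pre_update(self):
        w = 0.02
        x_star = 2 * P.rho_target * P.tau_istdp
        assert on_pre_spike_istdp(w, x_star, P) == w

    def test_depression_magnitude_hand_computed(self):
        w = 0.02
        out = on_pre_spike_istdp(w, 0.0, P)
        assert out == pytest.approx(w - 2 * 8.0 * 0.020 * 0.008, abs=1e-15)

    def test_silent_post_drives_weight_to_zero(self):
        w = P.g_i_max
        for _ in range(1000):
            w = on_pre_spike_istdp(w, 0.0, P)
        assert w == 0.0

    def test_post_update_is_pure_potentiation(self):
        for x_I in (0.0, 0.3, 2.0):
            w = 0.01
            assert on_post_spike_istdp(w, x_I, P) >= w

    @pytest.mark.parametrize("delta_ms", [5, 20, 60])
    def test_pre_post_pair_closed_form(self, delta_ms):
        # pre at t, post at t + delta: potentiation A * exp(-delta / tau)
        delta = delta_ms / 1000.0
        w0 = 0.01
        got = event_driven_plasticity_oracle(
            np.array([0.0]), np.array([delta]), P, rule="istdp", w0=w0
        )
        pre_dep = (0.0 - 2 * P.rho_target * P.tau_istdp) * P.A_istdp
        expected = w0 + pre_dep + P.A_istdp * math.exp(-delta / P.tau_istdp)
        assert got == pytest.approx(expected, abs=1e-15)


class TestOracleEquivalence:
    """The clock-driven bookkeeping matches the event-driven oracle."""

    @pytest.mark.parametrize("rule", ["triplet", "istdp"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_trains_agree_at_default_dt(self, rule, seed):
        rng = np.random.default_rng(seed)
        # on-grid spike times so rounding introduces no extra error
        dt = 1e-4
        pre = np.sort(rng.choice(np.arange(1, 5000), size=40, replace=False)) * dt
        post = np.sort(rng.choice(np.arange(1, 5000), size=40, replace=False)) * dt
        kwargs = dict(w0=0.5 * P.g_lgn_max, g_max=P.g_lgn_max, learning_rate=P.A_LTP_lgn)
        if rule == "istdp":
            kwargs = dict(w0=0.5 * P.g_i_max)
        w_ev = event_driven_plasticity_oracle(pre, post, P, rule=rule, **kwargs)
        w_ck = clock_driven_plasticity(pre, post, P, dt=dt, rule=rule, **kwargs)
        g_max = P.g_lgn_max if rule == "triplet" else P.g_i_max
        assert abs(w_ev - w_ck) < 1e-6 * g_max

    def test_discretization_error_shrinks_with_dt(self):
        """Off-grid spike times: the clock-driven error is O(dt) from spike
        rounding, so averaged over realizations it shrinks as dt does."""
        kwargs = dict(w0=0.5 * P.g_lgn_max, g_max=P.g_lgn_max, learning_rate=0.001)
        dts = (4e-4, 1e-4, 2.5e-5)
        errs = np.zeros(len(dts))
        for seed in range(6):
            rng = np.random.default_rng(seed)
            pre = np.sort(rng.uniform(0, 1.0, 20))
            post = np.sort(rng.uniform(0, 1.0, 20))
            exact = event_driven_plasticity_oracle(pre, post, P, rule="triplet", **kwargs)
            for k, dt in enumerate(dts):
                errs[k] += abs(
                    clock_driven_plasticity(pre, post, P, dt=dt, rule="triplet", **kwargs)
                    - exact
                )
        assert errs[2] < errs[1] < errs[0]
        assert errs[1] < 0.5 * errs[0]

    def test_oracle_rejects_unsorted_input(self):
        with pytest.raises(ValueError, match="sorted"):
            event_driven_plasticity_oracle(
                np.array([0.2, 0.1]), np.array([]), P, rule="istdp"
            )

    def test_empty_trains_leave_weight_unchanged(self):
        w = event_driven_plasticity_oracle(
            np.array([]), np.array([]), P, rule="triplet", w0=0.013,
            g_max=P.g_lgn_max, learning_rate=P.A_LTP_lgn,
        )
        assert w == 0.013


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.floats(0.001, 1.0), st.booleans()), min_size=0, max_size=40
    ),
    rule=st.sampled_from(["triplet", "istdp"]),
)
def test_weight_stays_bounded_for_arbitrary_trains(data, rule):
    """Invariant: plastic weights remain within [0, g_max] for any event
    sequence."""
    pre = np.sort([t for t, is_pre in data if is_pre])
    post = np.sort([t for t, is_pre in data if not is_pre])
    kwargs = (
        dict(w0=0.5 * P.g_lgn_max, g_max=P.g_lgn_max, learning_rate=0.01)
        if rule == "triplet"
        else dict(w0=0.5 * P.g_i_max)
    )
    t, w = event_driven_plasticity_oracle(
        pre, post, P, rule=rule, return_trajectory=True, **kwargs
    )
    g_max = P.g_lgn_max if rule == "triplet" else P.g_i_max
    assert np.all(w >= 0.0)
    assert np.all(w <= g_max + 1e-15)


class TestInitializeWeights:
    def test_phase1_has_no_recurrent_weights(self, small_graph):
        w = initialize_weights(small_graph, P, phase=1, rng_seed=0)
        assert w["w_ee"].sum() == 0.0
        assert w["w_ei"].sum() == 0.0

    def test_phase2_ee_weights_in_stated_interval(self, small_graph):
        w = initialize_weights(small_graph, P, phase=2, rng_seed=0)
        exc = small_graph.is_excitatory
        ee = w["w_ee"][np.ix_(exc, exc)]
        mask = small_graph.recurrent_mask[np.ix_(exc, exc)]
        vals = ee[mask]
        assert vals.min() >= 0.25 * P.g_ee_max
        assert vals.max() <= 0.35 * P.g_ee_max

    def test_same_seed_identical(self, small_graph):
        a = initialize_weights(small_graph, P, phase=2, rng_seed=5)
        b = initialize_weights(small_graph, P, phase=2, rng_seed=5)
        for key in a:
            assert np.array_equal(a[key], b[key])

    def test_weights_vanish_off_connectivity(self, small_graph):
        w = initialize_weights(small_graph, P, phase=1, rng_seed=1)
        assert np.all(w["w_lgn"][~small_graph.lgn_map] == 0.0)
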