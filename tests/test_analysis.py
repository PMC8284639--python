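"""Tests of the OP, disorder, synchrony and connectivity statistics."""

import numpy as np
import pytest
from scipy import stats

from gjcortex.analysis import (
    connectivity_stats,
    gj_degree_stats,
    gj_groups,
    group_op_distributions,
    kld_to_uniform,
    learning_slope,
    local_disorder,
    nse_count,
    op_difference,
    sample_non_gj_pairs,
)
from gjcortex.network import NetworkGraph, build_lattice, build_pairwise_gj
from gjcortex.records import WeightTrajectory


class TestOpDifference:
    def test_circular_metric(self):
        assert op_difference(0.0, 980.0) == 20.0
        assert op_difference(100.0, 600.0) == 500.0
        assert op_difference(300.0, 300.0) == 0.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 1000, (2, 500))
        d = op_difference(a, b)
        assert np.allclose(d, op_difference(b, a))
        assert np.all((d >= 0) & (d <= 500))

    def test_uniform_pairs_mean_is_quarter_period(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 1000, (2, 200_000))
        assert np.mean(op_difference(a, b)) == pytest.approx(250.0, rel=0.01)


class TestGroupOpDistributions:
    def test_identical_pair_ops_concentrate_in_first_bin(self, lattice_400):
        g = lattice_400
        g.gj_edges = build_pairwise_gj(g, 0.5, 1)
        op = np.random.default_rng(2).uniform(0, 1000, g.n_cells)
        for a, b in g.gj_edges:
            op[b] = op[a]
        dists = group_op_distributions(op, g, rng_seed=3)
        assert dists.gj_hist[0] == dists.gj_hist.sum()

    def test_uniform_ops_fill_bins_evenly(self, lattice_400):
        g = lattice_400
        g.gj_edges = build_pairwise_gj(g, 1.0, 4)
        rng = np.random.default_rng(5)
        pooled_gj, pooled_ctrl = [], []
        for s in range(50):
            op = rng.uniform(0, 1000, g.n_cells)
            d = group_op_distributions(op, g, rng_seed=s)
            pooled_gj.append(d.gj_diffs)
            pooled_ctrl.append(d.control_diffs)
        for pooled in (pooled_gj, pooled_ctrl):
            vals = np.concatenate(pooled)
            hist, _ = np.histogram(vals, bins=10, range=(0, 500))
            _, p = stats.chisquare(hist)
            assert p > 0.01

    def test_undefined_ops_are_excluded_and_counted(self, lattice_400):
        g = lattice_400
        g.gj_edges = build_pairwise_gj(g, 0.5, 6)
        op = np.full(g.n_cells, 100.0)
        op[g.gj_edges[0, 0]] = np.nan
        d = group_op_distributions(op, g, rng_seed=7)
        assert d.n_excluded >= 1
        assert len(d.gj_diffs) == len(g.gj_edges) - 1

    def test_control_pairs_avoid_gj_edges(self, lattice_400):
        g = lattice_400
        g.gj_edges = build_pairwise_gj(g, 0.5, 8)
        pairs = sample_non_gj_pairs(g, 200, np.random.default_rng(9))
        gj_set = {tuple(sorted(e)) for e in g.gj_edges}
        assert all(tuple(sorted(p)) not in gj_set for p in pairs)
        assert np.all(g.is_excitatory[pairs.ravel()])


class TestLearningSlope:
    def make_traj(self, curves):
        """curves: (T, n_synapses) for one cell."""
        T, m = curves.shape
        w_lgn = np.zeros((T, 1, m))
        w_lgn[:, 0, :] = curves
        z = np.zeros((T, 1, 1))
        return WeightTrajectory(
            times=np.arange(T, dtype=float), w_lgn=w_lgn, w_ee=z, w_ei=z
        )

    def test_constant_trajectory_flat_curve(self):
        traj = self.make_traj(np.full((5, 3), 0.8))
        out = learning_slope(traj, np.array([0]), g_max=1.0, potentiation_criterion=0.7)
        assert np.allclose(out.mean, 0.8)
        assert np.allclose(out.sd, 0.0)
        assert out.n_synapses == 3

    def test_criterion_zero_averages_everything(self):
        rng = np.random.default_rng(0)
        curves = rng.uniform(0, 1.0, (6, 10))
        traj = self.make_traj(curves)
        out = learning_slope(traj, np.array([0]), g_max=1.0, potentiation_criterion=0.0)
        assert out.n_synapses == 10
        assert np.all((out.mean >= 0) & (out.mean <= 1.0))

    def test_time_to_half_max_interpolates(self):
        curves = np.array([[0.0], [0.2], [0.4], [0.8], [1.0]])
        traj = self.make_traj(curves)
        out = learning_slope(traj, np.array([0]), g_max=1.0)
        # mean crosses 0.5 between t=2 (0.4) and t=3 (0.8)
        assert out.time_to_half_max == pytest.approx(2.25)

    def test_no_potentiated_synapse_raises(self):
        traj = self.make_traj(np.full((4, 2), 0.1))
        with pytest.raises(ValueError, match="criterion"):
            learning_slope(traj, np.array([0]), g_max=1.0)


class TestKld:
    def test_uniform_histogram_is_zero(self):
        op = np.repeat(np.arange(25) * 40.0 + 5.0, 8)
        assert kld_to_uniform(op, n_bins=25) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_maximum(self):
        op = np.full(100, 123.0)
        assert kld_to_uniform(op, n_bins=25) == pytest.approx(np.log(25))

    def test_finite_sample_bias_of_uniform_draws(self):
        """Plug-in KLD of N uniform draws has mean ~ (n_bins - 1) / (2 N)."""
        rng = np.random.default_rng(10)
        n, bins = 200, 25
        vals = [kld_to_uniform(rng.uniform(0, 1000, n), bins) for _ in range(300)]
        expected = (bins - 1) / (2 * n)
        assert np.mean(vals) == pytest.approx(expected, rel=0.2)

    def test_nonnegative(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            assert kld_to_uniform(rng.uniform(0, 1000, 30)) >= 0.0


class TestLocalDisorder:
    def test_constant_map_is_zero(self):
        g = build_lattice(64, 0.0, rng_seed=0)
        val, excluded = local_disorder(np.full(64, 300.0), g, radius=2.0)
        assert val == 0.0
        assert excluded == 0

    def test_uniform_map_near_quarter_period(self):
        g = build_lattice(256, 0.0, rng_seed=1)
        rng = np.random.default_rng(2)
        vals = [
            local_disorder(rng.uniform(0, 1000, 256), g, radius=4.0)[0]
            for _ in range(20)
        ]
        assert np.mean(vals) == pytest.approx(250.0, rel=0.05)

    def test_gradient_map_matches_enumeration(self):
        """OP = 50 * col mod 1000 on a 16x16 grid: deterministic value."""
        g = build_lattice(256, 0.0, rng_seed=3)
        op = (50.0 * g.positions[:, 1]) % 1000.0
        val, _ = local_disorder(op, g, radius=4.0)
        # independent brute-force enumeration
        from gjcortex.network import wrapped_grid_distance

        dist = wrapped_grid_distance(g.positions, 16)
        per_cell = []
        for i in range(256):
            nbrs = [j for j in range(256) if j != i and dist[i, j] <= 4.0]
            diffs = [min(abs(op[i] - op[j]), 1000 - abs(op[i] - op[j])) for j in nbrs]
            per_cell.append(np.mean(diffs))
        assert val == pytest.approx(np.mean(per_cell), abs=1e-9)
        assert 0.0 < val < 250.0

    def test_inhibitory_and_undefined_cells_excluded(self):
        g = build_lattice(64, 0.3, rng_seed=4)
        op = np.full(64, 100.0)
        op[g.excitatory_ids[0]] = np.nan
        val, excluded = local_disorder(op, g, radius=2.0)
        assert val == 0.0
        assert excluded == 1


class TestNse:
    def test_no_spikes_zero_rate(self):
        assert nse_count([np.array([]), np.array([])], window_total=10.0) == 0.0

    def test_simultaneous_volley_single_crossing(self):
        trains = [np.array([1.0])] * 5
        rate = nse_count(trains, window_total=10.0)
        assert rate == pytest.approx(0.1)  # exactly one event in 10 s

    def test_single_cell_spike_below_threshold(self):
        trains = [np.array([1.0]), np.array([]), np.array([]), np.array([])]
        assert nse_count(trains, window_total=10.0) == 0.0

    def test_requires_group_of_two(self):
        with pytest.raises(ValueError, match="at least 2"):
            nse_count([np.array([1.0])], window_total=10.0)

    def test_dispersed_spikes_cross_less_than_synchronous(self):
        rng = np.random.default_rng(5)
        sync = [np.sort(rng.uniform(0, 10, 40)) for _ in range(1)]
        sync = [sync[0] + rng.normal(0, 0.001, 40) for _ in range(4)]
        disp = [np.sort(rng.uniform(0, 10, 40)) for _ in range(4)]
        assert nse_count(sync, 10.0) > nse_count(disp, 10.0)


class TestConnectivity:
    def test_all_max_weights_bidirectional(self, lattice_400):
        g = lattice_400
        g.gj_edges = build_pairwise_gj(g, 0.5, 1)
        w = np.full((400, 400), 0.025)
        out = connectivity_stats(w, g, g_ee_max=0.025, rng_seed=0)
        assert out.gj["bidirectional"] == 1.0
        assert out.non_gj["bidirectional"] == 1.0

    def test_all_zero_weights_unconnected(self, lattice_400):
        g = lattice_400
        g.gj_edges = build_pairwise_gj(g, 0.5, 2)
        out = connectivity_stats(np.zeros((400, 400)), g, g_ee_max=0.025, rng_seed=0)
        assert out.gj["unconnected"] == 1.0

    def test_fractions_sum_to_one(self, lattice_400):
        g = lattice_400
        g.gj_edges = build_pairwise_gj(g, 0.5, 3)
        w = np.random.default_rng(4).uniform(0, 0.025, (400, 400))
        out = connectivity_stats(w, g, g_ee_max=0.025, rng_seed=5)
        assert sum(out.gj.values()) == pytest.approx(1.0)
        assert sum(out.non_gj.values()) == pytest.approx(1.0)


class TestGjGroupsAndDegree:
    def test_empty_edge_set(self):
        g = build_lattice(16, 0.0, rng_seed=0)
        mean_deg, hist = gj_degree_stats(g)
        assert mean_deg == 0.0
        assert gj_groups(g) == []

    def test_perfect_matching_degree_one(self, lattice_400):
        g = NetworkGraph(**{**lattice_400.__dict__})
        g.gj_edges = build_pairwise_gj(lattice_400, 1.0, 1)
        mean_deg, _ = gj_degree_stats(g)
        n_e = lattice_400.is_excitatory.sum()
        assert mean_deg == pytest.approx(2 * len(g.gj_edges) / n_e)
        groups = gj_groups(g)
        assert all(len(grp) == 2 for grp in groups)

    def test_chain_components_merge(self):
        g = build_lattice(16, 0.0, rng_seed=0)
        g.gj_edges = np.array([[0, 1], [1, 2], [4, 5]])
        groups = gj_groups(g)
        sizes = sorted(len(grp) for grp in groups)
        assert sizes == [2, 3]
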