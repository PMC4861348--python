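"""Surrogate significance testing, network construction, degree statistics."""

import numpy as np
import networkx as nx
import pytest
from scipy import stats

import spikepid as sp
from spikepid.binning import LONG_TIMESCALE, SpikeTrainSet, Timescale, bin_spikes
from spikepid.infotheory import TEResult
from spikepid.network_inference import (
    DegreeSummary,
    EffectiveNetwork,
    build_network,
    connection_significance,
    degree_distribution_comparison,
    fit_lognormal,
    infer_network,
    jitter_surrogates,
    network_from_frame,
    pair_transfer_entropy,
    sample_subnetworks,
)

FAST_TS = Timescale(3.5, (1, 2), "fast-test")


class TestJitterSurrogates:
    def test_spike_count_preserved(self):
        rng = np.random.default_rng(0)
        train = np.sort(rng.uniform(0, 100, 500))
        for surr in jitter_surrogates(train, 5, 20.0, 0.0, 100.0, seed=1):
            assert surr.size == train.size
            assert surr.min() >= 0 and surr.max() <= 100.0
            assert np.all(np.diff(surr) >= 0)

    def test_vanishing_window_recovers_original(self):
        train = np.array([1.0, 2.0, 3.0])
        surr = next(iter(jitter_surrogates(train, 1, 1e-6, 0.0, 10.0, seed=2)))
        assert np.allclose(surr, train, atol=1e-8)

    def test_empty_train_passes_through(self):
        surr = list(jitter_surrogates(np.array([]), 3, 20.0, 0.0, 10.0, seed=3))
        assert all(s.size == 0 for s in surr)

    def test_null_pvalues_roughly_uniform_and_false_positives_rare(self):
        # independent Poisson neurons: p-values from jittered nulls should be
        # near-uniform and essentially no edges pass the 1/n_surr threshold
        rng = np.random.default_rng(4)
        n, dur, n_surr = 8, 300.0, 50
        trains = {
            i: np.sort(rng.uniform(0, dur, rng.poisson(2.0 * dur)))
            for i in range(n)
        }
        spikes = SpikeTrainSet(trains, 0.0, dur)
        net = infer_network(spikes, FAST_TS, n_surrogates=n_surr,
                            alpha=1.1, seed=5)  # keep every edge: inspect p
        pvals = np.array([d["p_value"] for _, _, d in net.graph.edges(data=True)])
        assert pvals.size == n * (n - 1)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        # expected false edges at p < 1/n_surr is ~ n_pairs/(n_surr+1) ~ 1.1
        assert (pvals < 1.0 / n_surr).sum() <= 6


class TestConnectionSignificance:
    def test_real_above_all_surrogates(self):
        p, sig = connection_significance(1.0, np.zeros(5000))
        assert p == 0.0 and sig

    def test_exactly_five_of_5000_is_not_significant(self):
        surr = np.zeros(5000)
        surr[:5] = 2.0
        p, sig = connection_significance(1.0, surr)
        assert p == pytest.approx(0.001)
        assert not sig

    def test_four_of_5000_is_significant(self):
        surr = np.zeros(5000)
        surr[:4] = 2.0
        p, sig = connection_significance(1.0, surr)
        assert p == pytest.approx(0.0008)
        assert sig

    def test_decision_monotone_in_te(self):
        surr = np.linspace(0, 1, 200)
        ps = [connection_significance(te, surr)[0] for te in (0.2, 0.5, 0.9)]
        assert ps[0] >= ps[1] >= ps[2]


class TestBuildNetwork:
    def test_empty_input_gives_empty_network(self):
        net = build_network([], nodes=[0, 1])
        assert net.n_edges == 0 and set(net.nodes) == {0, 1}

    def test_only_significant_edges_kept(self):
        mk = lambda s, t: TEResult(s, t, "ts", 1, 0.1, 0.5, 100)
        net = build_network([(mk(0, 1), 0.0), (mk(1, 0), 0.05)], alpha=0.001)
        assert list(net.graph.edges) == [(0, 1)]

    def test_self_edges_rejected(self):
        net = EffectiveNetwork.empty([0])
        with pytest.raises(ValueError):
            net.add_connection(TEResult(0, 0, "ts", 1, 0.1, 0.5, 10), 0.0)

    def test_edge_frame_roundtrip(self):
        mk = lambda s, t: TEResult(s, t, "ts", 2, 0.1, 0.5, 100)
        net = build_network([(mk(0, 1), 0.0), (mk(2, 1), 0.0)], nodes=[0, 1, 2])
        df = net.to_frame()
        net2 = network_from_frame(df, timescale="ts")
        assert set(net2.graph.edges) == set(net.graph.edges)
        assert net2.edge_delay(0, 1) == 2


class TestPlantedEdgeRecovery:
    def test_planted_edge_detected_and_reverse_rejected(self):
        rec = sp.generate_recording(2, 600.0, [], [(0, 1, 5.0)], 1.0, seed=6)
        net = infer_network(rec.spike_trains, LONG_TIMESCALE,
                            n_surrogates=100, seed=7)
        assert (0, 1) in net.graph.edges
        assert (1, 0) not in net.graph.edges

    def test_te_peaks_at_planted_delay(self):
        rec = sp.generate_recording(2, 600.0, [], [(0, 1, 7.0)], 1.0, seed=8)
        st = rec.spike_trains
        b0 = bin_spikes(st.trains[0], 3.5, 0, 600)
        b1 = bin_spikes(st.trains[1], 3.5, 0, 600)
        res = pair_transfer_entropy(b1, b0, LONG_TIMESCALE, source=0, target=1)
        assert res.delay_bins == 2  # 7 ms = 2 bins of 3.5 ms
        assert res.te_bits > 0


class TestSubnetworkSampling:
    @staticmethod
    def _net_with_density(n_nodes, avg_total_degree, seed):
        n_edges = int(avg_total_degree * n_nodes / 2)
        g = nx.DiGraph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(sp.random_network(n_nodes, n_edges, seed))
        return EffectiveNetwork(graph=g)

    def test_requested_count_returned(self):
        # induced subgraphs dilute degree by (size/n)(size-1)/(n-1); the
        # parent needs avg total degree ~ 3 * (120*119)/(50*49) ~ 7.3 for
        # 50-node samples to land near 3
        net = self._net_with_density(120, 7.3, seed=9)
        subs = sample_subnetworks(net, n_sub=20, size=50, seed=10)
        assert len(subs) == 20
        for nodes in subs:
            assert len(set(nodes)) == 50
            sub = net.graph.subgraph(nodes)
            assert abs(2 * sub.number_of_edges() / 50 - 3.0) <= 0.2

    def test_too_small_network_rejected(self):
        net = self._net_with_density(40, 3.0, seed=11)
        with pytest.raises(ValueError, match="need 50"):
            sample_subnetworks(net, n_sub=5, size=50)

    def test_infeasible_target_reports_shortfall(self):
        net = self._net_with_density(60, 0.2, seed=12)  # far too sparse
        with pytest.raises(RuntimeError, match="accepted only"):
            sample_subnetworks(net, n_sub=5, size=50, max_retries=200, seed=13)


class TestDegreeComparison:
    def test_matched_ensemble_has_same_mean_total_degree(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(30))
        g.add_edges_from(sp.random_network(30, 60, seed=14))
        net = EffectiveNetwork(graph=g)
        real, rand = degree_distribution_comparison(net, n_random=20, seed=15)
        assert np.mean(list(real.total_degree.values())) == pytest.approx(
            np.mean(list(rand.total_degree.values()))
        )

    def test_planted_hub_exceeds_random_tail(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(40))
        hub_edges = [(0, t) for t in range(1, 31)]
        rng = np.random.default_rng(16)
        extra = [(int(s), int(t)) for s, t in
                 zip(rng.integers(1, 40, 30), rng.integers(1, 40, 30))
                 if s != t]
        g.add_edges_from(hub_edges + extra)
        net = EffectiveNetwork(graph=g)
        real, rand = degree_distribution_comparison(net, n_random=50, seed=17)
        rand_q99 = np.percentile(list(rand.total_degree.values()), 99)
        assert max(real.total_degree.values()) > rand_q99

    def test_degree_summary_conservation(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(20))
        g.add_edges_from(sp.random_network(20, 50, seed=18))
        s = DegreeSummary.of(g)
        assert sum(s.in_degree.values()) == sum(s.out_degree.values()) == 50
        assert all(
            s.total_degree[n] == s.in_degree[n] + s.out_degree[n]
            for n in g.nodes
        )


class TestLogNormalFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(19)
        x = 10 ** rng.normal(-3.0, 0.5, 100_000)
        fit = fit_lognormal(x)
        assert fit.mu == pytest.approx(-3.0, abs=0.05)
        assert fit.sigma == pytest.approx(0.5, abs=0.05)

    def test_scaling_shifts_mu_only(self):
        rng = np.random.default_rng(20)
        x = 10 ** rng.normal(-2.0, 0.4, 50_000)
        f1 = fit_lognormal(x)
        f2 = fit_lognormal(10 * x)
        assert f2.mu - f1.mu == pytest.approx(1.0, abs=0.02)
        assert f2.sigma == pytest.approx(f1.sigma, abs=0.02)

    def test_degenerate_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_lognormal(np.ones(200))
        with pytest.raises(ValueError, match="positive"):
            fit_lognormal(np.concatenate([np.full(150, 0.5), [-1.0]]))
        with pytest.raises(ValueError, match="at least"):
            fit_lognormal(np.full(50, 0.5))
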