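"""TSPE weights, edge filtering, coincidence index, and variation summaries."""

import numpy as np
import pytest

from measeq import (ConnectivityConfig, Edge, ConnectivityGraph, Layout,
                    PlantedConnection, SpikeTrainSet, coincidence_index,
                    default_layout_4q, filter_edges, plant_connectivity,
                    surrogate_weight_threshold, tspe, tspe_pair_weight,
                    variation_vs_baseline)
from tests.conftest import make_poisson_set


def _pair_set(layout, seed, rate=1.0, duration=600.0):
    ids = (layout.electrodes[0], layout.electrodes[16])
    sub = Layout(ids, layout.positions, layout.clusters)
    return make_poisson_set(sub, rate, duration, seed), ids


class TestTspe:
    def test_independent_trains_below_surrogate_null(self, layout):
        sts, (e0, e1) = _pair_set(layout, seed=0)
        w, _ = tspe_pair_weight(sts.spikes[e0], sts.spikes[e1])
        thr = surrogate_weight_threshold(sts, n_surrogates=100, seed=1)
        assert abs(w) < thr

    def test_planted_excitation_direction_and_delay(self, layout):
        sts, (e0, e1) = _pair_set(layout, seed=2)
        planted = plant_connectivity(
            sts, [PlantedConnection(e0, e1, +1, 5.0, 0.5)], seed=3)
        w_fwd, d_fwd = tspe_pair_weight(planted.spikes[e0], planted.spikes[e1])
        w_rev, _ = tspe_pair_weight(planted.spikes[e1], planted.spikes[e0])
        assert w_fwd > 0
        assert abs(d_fwd - 5.0) <= 1.0
        assert w_fwd > w_rev

    def test_planted_inhibition_negative_weight(self, layout):
        sts, (e0, e1) = _pair_set(layout, seed=4, rate=2.0)
        planted = plant_connectivity(
            sts, [PlantedConnection(e0, e1, -1, 2.0, 0.9)], seed=5)
        w, _ = tspe_pair_weight(planted.spikes[e0], planted.spikes[e1])
        assert w < 0

    def test_sparse_trains_skipped_with_warning(self, layout):
        ids = tuple(layout.electrodes[:3])
        sub = Layout(ids, layout.positions, layout.clusters)
        trains = {ids[0]: np.linspace(1, 59, 100),
                  ids[1]: np.linspace(1.5, 58.5, 100),
                  ids[2]: np.array([1.0, 2.0])}       # below min_spikes_per_train
        sts = SpikeTrainSet(sub, trains, 60.0)
        with pytest.warns(UserWarning, match="skipped"):
            g = tspe(sts)
        assert {e.source for e in g.edges} == {ids[0], ids[1]}

    def test_direction_recovery_auc_on_planted_network(self):
        """Ranking pairs by weight separates 30 planted edges (AUC >= 0.9)."""
        full = default_layout_4q()
        ids = tuple(full.electrodes[i] for i in range(0, 60, 3))  # 20 electrodes
        sub = Layout(ids, full.positions, full.clusters)
        sts = make_poisson_set(sub, rate=2.0, duration=300.0, seed=6)
        rng = np.random.default_rng(7)
        pairs = [(a, b) for a in ids for b in ids if a != b]
        chosen = [pairs[i] for i in rng.choice(len(pairs), 30, replace=False)]
        conns = [PlantedConnection(a, b, +1, float(rng.uniform(3, 10)), 0.5)
                 for a, b in chosen]
        planted = plant_connectivity(sts, conns, seed=8)
        g = tspe(planted)
        truth = {(c.source, c.target) for c in conns}
        scores = np.array([e.weight for e in g.edges])
        labels = np.array([(e.source, e.target) in truth for e in g.edges])
        # Mann-Whitney AUC
        from scipy.stats import rankdata
        r = rankdata(scores)
        n1, n0 = labels.sum(), (~labels).sum()
        auc = (r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc >= 0.9


class TestFilterEdges:
    def _graph(self, layout, edges):
        return ConnectivityGraph(layout, tuple(edges))

    def test_latency_filter_removes_fast_edge(self, layout):
        e = Edge(layout.electrodes[0], layout.electrodes[16], 1.0, 0.5, "inter")
        g = self._graph(layout, [e])
        out = filter_edges(g, speed_bounds_m_s=None, latency_bounds_ms=(1, 25))
        assert out.edges == ()

    def test_speed_filter_keeps_plausible_edge(self, layout):
        # pick a pair ~2000 um apart; 25 ms delay -> 0.08 m/s inside [0.02, 2]
        a, b = layout.electrodes[0], layout.electrodes[16]
        dist = layout.distance_um(a, b)
        assert dist > 500
        e = Edge(a, b, 1.0, 25.0, "inter")
        g = self._graph(layout, [e])
        out = filter_edges(g, speed_bounds_m_s=(0.02, 2.0), latency_bounds_ms=None)
        assert out.edges == (e,)
        speed = dist / 25.0 * 1e-3
        assert 0.02 <= speed <= 2.0

    def test_speed_filter_removes_implausible_edge(self, layout):
        a, b = "q1e15", "q3e15"             # opposite far corners, ~3.4 mm
        assert layout.distance_um(a, b) > 2000
        e = Edge(a, b, 1.0, 1.0, "inter")   # >2 mm in 1 ms -> > 2 m/s
        out = filter_edges(self._graph(layout, [e]),
                           speed_bounds_m_s=(0.02, 2.0), latency_bounds_ms=None)
        assert out.edges == ()

    def test_disabled_filters_are_identity_and_idempotent(self, layout):
        edges = [Edge(layout.electrodes[0], layout.electrodes[16], 0.5, 5.0, "inter"),
                 Edge(layout.electrodes[1], layout.electrodes[2], -0.2, 3.0, "intra")]
        g = self._graph(layout, edges)
        out = filter_edges(g, None, None, None)
        assert out.edges == g.edges
        once = filter_edges(g, (0.02, 2.0), (1, 25), 0.3)
        twice = filter_edges(once, (0.02, 2.0), (1, 25), 0.3)
        assert set(once.edges) <= set(g.edges)
        assert once.edges == twice.edges

    def test_self_edges_rejected(self, layout):
        with pytest.raises(ValueError):
            ConnectivityGraph(layout, (Edge("a", "a", 1.0, 5.0, "intra"),))


class TestCoincidenceIndex:
    def test_identical_sparse_trains_give_unity(self):
        t = np.arange(1.0, 60.0, 1.0)   # ISIs far beyond the lag window
        assert coincidence_index(t, t) == 1.0

    def test_flat_correlogram_expectation(self, layout):
        """Independent trains: CI0 ~ 2 ms / 200 ms = 0.01."""
        sts, (e0, e1) = _pair_set(layout, seed=9, rate=10.0, duration=600.0)
        ci = coincidence_index(sts.spikes[e0], sts.spikes[e1])
        assert ci == pytest.approx(0.01, abs=0.005)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            coincidence_index(np.array([]), np.array([1.0]))

    def test_symmetric_under_exchange(self, layout):
        sts, (e0, e1) = _pair_set(layout, seed=10, rate=3.0, duration=120.0)
        a = coincidence_index(sts.spikes[e0], sts.spikes[e1])
        b = coincidence_index(sts.spikes[e1], sts.spikes[e0])
        assert abs(a - b) < 1e-9


class TestVariation:
    def _graphs(self, layout):
        a, b = layout.electrodes[0], layout.electrodes[16]
        c, d = layout.electrodes[1], layout.electrodes[2]
        base = ConnectivityGraph(layout, (
            Edge(a, b, 1.0, 5.0, "inter", ci0=0.2),
            Edge(b, a, 0.5, 6.0, "inter", ci0=0.1),
            Edge(c, d, 0.8, 4.0, "intra", ci0=0.3),
        ))
        return base

    def test_identical_graphs_zero_variation(self, layout):
        base = self._graphs(layout)
        v = variation_vs_baseline(base, base)
        assert (v.inter_count_pct, v.intra_count_pct) == (0.0, 0.0)
        assert (v.inter_weight_pct, v.intra_weight_pct) == (0.0, 0.0)
        assert (v.inter_ci0_pct, v.intra_ci0_pct) == (0.0, 0.0)

    def test_halved_count_and_doubled_weights(self, layout):
        base = self._graphs(layout)
        cond = ConnectivityGraph(layout, (
            Edge(base.edges[0].source, base.edges[0].target, 2.0, 5.0, "inter", ci0=0.2),
            Edge(base.edges[2].source, base.edges[2].target, 1.6, 4.0, "intra", ci0=0.3),
        ))
        v = variation_vs_baseline(base, cond)
        assert v.inter_count_pct == pytest.approx(-50.0)
        assert v.intra_count_pct == pytest.approx(0.0)
        assert v.intra_weight_pct == pytest.approx(100.0)

    def test_zero_baseline_flagged_undefined(self, layout):
        empty = ConnectivityGraph(layout, ())
        cond = self._graphs(layout)
        v = variation_vs_baseline(empty, cond)
        assert v.inter_count_pct is None
        assert v.intra_ci0_pct is None
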