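"""Delayed-synchrony matrix, edge selection, hubs and the graph."""

import numpy as np
import pytest

from culturenet import (DelayedSynchronyModel, DelayParams, SpikeRaster,
                       build_graph, count_delayed_synchronous,
                       cross_correlation_matrix, hub_analysis, select_edges)
from culturenet.connectivity import ConnectivityResults

from conftest import brute_force_c_matrix, brute_force_count


def small_random_raster(rng, max_electrodes=5, max_spikes=50):
    n_el = int(rng.integers(2, max_electrodes + 1))
    duration = float(rng.uniform(0.5, 5.0))
    ids = [f"e{i}" for i in range(n_el)]
    budget = int(rng.integers(0, max_spikes + 1))
    times = {}
    for eid in ids:
        n = int(rng.integers(0, budget // n_el + 1))
        times[eid] = rng.uniform(0, duration, n)
    return SpikeRaster(ids, times, duration)


class TestCountDelayedSynchronous:
    def test_hand_enumeration(self, hand_trains):
        pre, post = hand_trains
        assert count_delayed_synchronous(pre, post, 0.005, 0.002) == 2

    def test_empty_post(self, hand_trains):
        pre, _ = hand_trains
        assert count_delayed_synchronous(pre, [], 0.005, 0.002) == 0

    def test_copied_train_zero_lag_not_in_window(self, hand_trains):
        pre, _ = hand_trains
        assert count_delayed_synchronous(pre, pre, 0.005, 0.002) == 0

    def test_post_spike_counted_once(self):
        # two pre spikes both inside one post spike's window
        assert count_delayed_synchronous(
            [0.0045, 0.0055], [0.010], 0.005, 0.002) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_loop(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.uniform(0, 1, rng.integers(0, 30)))
        post = np.sort(rng.uniform(0, 1, rng.integers(0, 30)))
        for tau in (0.002, 0.01, 0.02):
            assert count_delayed_synchronous(pre, post, tau, 0.002) == \
                brute_force_count(pre, post, tau, 0.002)


class TestCrossCorrelationMatrix:
    def test_hand_example(self, hand_trains):
        pre, post = hand_trains
        raster = SpikeRaster(["1", "2"], {"1": pre, "2": post}, 1.0)
        res = cross_correlation_matrix(raster)
        assert res.c_matrix[0, 1] == pytest.approx(2 / 3)
        assert res.best_tau[0, 1] == pytest.approx(0.005)

    def test_perfect_relay(self):
        pre = np.arange(10) * 0.1
        raster = SpikeRaster(["a", "b"], {"a": pre, "b": pre + 0.005}, 2.0)
        res = cross_correlation_matrix(raster)
        assert res.c_matrix[0, 1] == 1.0

    def test_silent_electrode_zero_row_col(self):
        raster = SpikeRaster(["a", "b", "c"],
                             {"a": [0.1, 0.2], "b": [0.105, 0.205], "c": []},
                             1.0)
        res = cross_correlation_matrix(raster)
        i = raster.electrode_ids.index("c")
        assert np.all(res.c_matrix[i, :] == 0)
        assert np.all(res.c_matrix[:, i] == 0)
        assert res.n_post[i] == 0

    def test_bounds(self):
        rng = np.random.default_rng(2)
        raster = small_random_raster(rng)
        res = cross_correlation_matrix(raster)
        assert np.all(res.c_matrix >= 0) and np.all(res.c_matrix <= 1)
        assert np.all(np.diag(res.c_matrix) == 0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        """Vectorized matrix equals the triple loop over (pre, post, tau)."""
        rng = np.random.default_rng(seed)
        raster = small_random_raster(rng)
        params = DelayParams()
        res = cross_correlation_matrix(raster, params)
        c, best, nsyn = brute_force_c_matrix(raster, params.tau_grid_s,
                                             params.delta_s)
        np.testing.assert_allclose(res.c_matrix, c)
        np.testing.assert_allclose(res.best_tau, best)
        np.testing.assert_array_equal(res.n_synchr, nsyn)

    def test_chance_level_poisson(self):
        """Independent 0.2-Hz Poisson trains give small mean C."""
        cs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ids = [f"e{i}" for i in range(8)]
            raster = SpikeRaster(
                ids, {e: rng.uniform(0, 300, rng.poisson(60)) for e in ids},
                300.0)
            res = cross_correlation_matrix(raster)
            off = res.c_matrix[~np.eye(8, dtype=bool)]
            cs.append(off.mean())
        assert np.mean(cs) < 0.1

    def test_burst_scope_restricts_spikes(self):
        from culturenet import condition_preset, generate_mea_recording
        net, _ = condition_preset("sham_DIV21")
        raster, _ = generate_mea_recording(net, 60.0, 4)
        res_all = cross_correlation_matrix(raster, spike_scope="all")
        res_burst = cross_correlation_matrix(raster, spike_scope="burst")
        assert res_burst.n_post.sum() < res_all.n_post.sum()
        assert res_burst.n_post.sum() > 0


def _synthetic_result(n, c, nsyn=None, ids=None):
    ids = ids or [f"e{i:02d}" for i in range(n)]
    c = np.asarray(c, dtype=float)
    nsyn = np.asarray(nsyn if nsyn is not None else (c * 100).astype(int))
    return ConnectivityResults(
        electrode_ids=ids, c_matrix=c, best_tau=np.full((n, n), 0.005),
        n_synchr=nsyn, n_post=np.full(n, 100), params=DelayParams())


class TestSelectEdges:
    def test_k_for_59_electrodes(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0.01, 1.0, (59, 59))
        np.fill_diagonal(c, 0.0)
        res = _synthetic_result(59, c)
        edges = select_edges(res, 0.05)
        assert len(edges) == 171  # floor(0.05 * 59 * 58)

    def test_single_nonzero(self):
        c = np.zeros((4, 4))
        c[1, 2] = 0.4
        edges = select_edges(_synthetic_result(4, c), 0.05)
        assert len(edges) == 1
        assert (edges.iloc[0]["pre"], edges.iloc[0]["post"]) == ("e01", "e02")

    def test_zero_edges_never_selected(self):
        c = np.zeros((6, 6))
        c[0, 1] = 0.2
        c[2, 3] = 0.1
        edges = select_edges(_synthetic_result(6, c), 0.5)  # k = 15 > nonzero
        assert len(edges) == 2

    def test_tie_break_deterministic(self):
        c = np.full((5, 5), 0.5)
        np.fill_diagonal(c, 0.0)
        res = _synthetic_result(5, c)
        first = select_edges(res, 0.05)
        for _ in range(3):
            again = select_edges(res, 0.05)
            assert (again[["pre", "post"]].values ==
                    first[["pre", "post"]].values).all()
        # lexicographic order among full ties
        assert first.iloc[0]["pre"] == "e00"


class TestHubAnalysis:
    def _edges(self, pairs):
        import pandas as pd
        return pd.DataFrame(
            [(a, b, 0.5, 0.005, 50) for a, b in pairs],
            columns=["pre", "post", "c", "tau", "n_synchr"])

    def test_star_is_hub(self):
        pairs = [("H", f"f{i}") for i in range(12)]
        nodes = ["H"] + [f"f{i}" for i in range(12)]
        table = hub_analysis(self._edges(pairs), nodes)
        row = table[table["electrode_id"] == "H"].iloc[0]
        assert row["n_connections"] == 12
        assert bool(row["is_hub"])

    def test_nine_connections_not_hub(self):
        pairs = [("H", f"f{i}") for i in range(9)]
        nodes = ["H"] + [f"f{i}" for i in range(9)]
        table = hub_analysis(self._edges(pairs), nodes)
        assert not bool(table[table["electrode_id"] == "H"]["is_hub"].iloc[0])
        # no hub qualifies -> fallback mean over top-degree nodes
        assert table.attrs["mean_hub_connections"] > 0

    def test_degree_counts_in_plus_out(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "b")]
        table = hub_analysis(self._edges(pairs), ["a", "b", "c"],
                             hub_min_connections=3)
        lookup = dict(zip(table["electrode_id"], table["n_connections"]))
        assert lookup == {"a": 1, "b": 3, "c": 2}
        assert table.attrs["mean_hub_connections"] == 3.0


class TestBuildGraph:
    def test_no_edges_isolated_nodes(self):
        import pandas as pd
        res = _synthetic_result(4, np.zeros((4, 4)))
        empty = pd.DataFrame(columns=["pre", "post", "c", "tau", "n_synchr"])
        g = build_graph(res, empty)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 0
        assert all(g.nodes[n]["degree"] == 0 for n in g.nodes)

    def test_hand_example_edge(self, hand_trains):
        pre, post = hand_trains
        raster = SpikeRaster(["1", "2"], {"1": pre, "2": post}, 1.0)
        res = cross_correlation_matrix(raster)
        edges = select_edges(res)
        g = build_graph(res, edges)
        assert g.edges["1", "2"]["weight"] == pytest.approx(2 / 3)

    def test_degree_matches_hub_analysis(self):
        rng = np.random.default_rng(7)
        c = rng.uniform(0, 0.8, (10, 10))
        np.fill_diagonal(c, 0)
        res = _synthetic_result(10, c)
        edges = select_edges(res, 0.3)
        g = build_graph(res, edges)
        table = hub_analysis(edges, res.electrode_ids)
        for _, row in table.iterrows():
            assert g.nodes[row["electrode_id"]]["degree"] == \
                row["n_connections"]


class TestPlantedRecovery:
    def test_model_recovers_planted_network(self):
        """Top-5% edges and top-degree nodes recover the planted hubs."""
        from culturenet import condition_preset, generate_mea_recording

        net, _ = condition_preset("sham_DIV21")
        raster, truth = generate_mea_recording(net, 300.0, 12)
        res = DelayedSynchronyModel(raster).fit()
        edges = res.select_edges()
        selected = set(zip(edges["pre"], edges["post"]))
        planted = set(truth.planted_edges())
        assert len(planted & selected) / len(planted) >= 0.8
        hubs = res.hub_table(edges)
        top5 = set(hubs.sort_values(
            ["n_connections", "electrode_id"],
            ascending=[False, True]).head(5)["electrode_id"])
        assert len(top5 & set(truth.hub_ids)) >= 4
        assert "hubs" in res.summary()

    def test_monotone_in_transmission_probability(self):
        """Median planted-edge C is non-decreasing in w (same seed)."""
        from culturenet import generate_mea_recording, hub_network_spec

        medians = []
        for w in (0.0, 0.3, 0.6, 0.9):
            spec = hub_network_spec(n_hubs=2, n_followers=5, w=w,
                                    burst_rate_per_min=6.0)
            raster, truth = generate_mea_recording(spec, 120.0, 3)
            res = cross_correlation_matrix(raster)
            idx = {e: k for k, e in enumerate(res.electrode_ids)}
            cs = [res.c_matrix[idx[i], idx[j]]
                  for i, j in truth.planted_edges()]
            medians.append(np.median(cs))
        assert all(b >= a - 1e-12 for a, b in zip(medians, medians[1:]))
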