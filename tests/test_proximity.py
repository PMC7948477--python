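"""Closest-distance statistic, degree-matched sampling, randomization test."""

import networkx as nx
import numpy as np
import pytest

from proxikit.proximity import (
    DegreeBins,
    ProximityWarning,
    closest_distance,
    degree_matched_sample,
    induced_subnetwork,
    load_network,
    map_to_network,
    proximity_test,
)


def dc_oracle(graph, S, T):
    """Exhaustive all-pairs-BFS closest distance (independent oracle)."""
    lengths = dict(nx.all_pairs_shortest_path_length(graph))
    terms, excluded = [], []
    for s in sorted(S):
        reach = [lengths[s][t] for t in T if t in lengths[s]]
        if reach:
            terms.append(min(reach))
        else:
            excluded.append(s)
    if not terms:
        raise ValueError("all sources unreachable")
    return float(np.mean(terms)), excluded


class TestLoadNetwork:
    def test_cleaning_rules(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nb\ta\nb\tb\n")
        g = load_network(p)
        assert set(g.nodes) == {"a", "b"}
        assert g.number_of_edges() == 1
        assert g.graph["self_loops_dropped"] == 1
        assert g.graph["duplicates_collapsed"] == 1

    def test_roundtrip_preserves_edges(self, tmp_path):
        from proxikit.io import write_network
        from proxikit.synthetic_data import generate_network

        g = generate_network(40, 2, seed=8)
        path = tmp_path / "net.tsv"
        write_network(g, path)
        back = load_network(path)
        assert set(map(frozenset, back.edges())) == set(map(frozenset, g.edges()))

    def test_path_graph_degrees(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\nb\tc\n")
        g = load_network(p)
        assert dict(g.degree()) == {"a": 1, "b": 2, "c": 1}

    def test_header_and_extra_columns_handled(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("source\ttarget\tscore\na\tb\t0.9\nb\tc\t0.5\n")
        g = load_network(p)
        assert set(g.nodes) == {"a", "b", "c"}

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("a\tb\njustone\n")
        with pytest.raises(ValueError, match=":2"):
            load_network(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            load_network(p)


class TestMapToNetwork:
    def test_partition(self, path5):
        mapped, unmapped = map_to_network({"a", "b", "X"}, path5)
        assert mapped == {"a", "b"}
        assert unmapped == ["X"]

    def test_all_present(self, path5):
        mapped, unmapped = map_to_network({"a", "e"}, path5)
        assert mapped == {"a", "e"} and unmapped == []

    def test_none_present_warns(self, path5):
        with pytest.warns(ProximityWarning):
            mapped, unmapped = map_to_network({"X", "Y"}, path5)
        assert mapped == set() and unmapped == ["X", "Y"]


class TestInducedSubnetwork:
    def test_identity(self, path5):
        sub = induced_subnetwork(path5, set(path5.nodes))
        assert set(sub.edges()) == set(path5.edges())

    def test_edgeless(self, path5):
        sub = induced_subnetwork(path5, {"a", "c", "e"})
        assert sub.number_of_edges() == 0
        assert sub.graph["component_sizes"] == [1, 1, 1]

    def test_triangle_two_adjacent(self):
        g = nx.complete_graph(["x", "y", "z"])
        sub = induced_subnetwork(g, {"x", "y"})
        assert list(sub.edges()) == [("x", "y")]


class TestClosestDistance:
    def test_path_endpoints(self, path5):
        dc, excluded = closest_distance(path5, {"a"}, {"e"})
        assert dc == 4.0 and excluded == []

    def test_source_subset_of_target_is_zero(self, path5):
        dc, _ = closest_distance(path5, {"b", "c"}, {"a", "b", "c"})
        assert dc == 0.0

    def test_mean_of_per_source_minima(self, path5):
        dc, _ = closest_distance(path5, {"a", "e"}, {"a"})
        assert dc == 2.0  # (0 + 4) / 2

    def test_unreachable_sources_excluded_and_listed(self):
        g = nx.Graph()
        nx.add_path(g, ["a", "b"])
        g.add_edge("x", "y")
        dc, excluded = closest_distance(g, {"a", "x"}, {"b"})
        assert dc == 1.0 and excluded == ["x"]

    def test_all_unreachable_errors(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_edge("x", "y")
        with pytest.raises(ValueError):
            closest_distance(g, {"x"}, {"a"})

    def test_empty_or_unmapped_errors(self, path5):
        with pytest.raises(ValueError):
            closest_distance(path5, set(), {"a"})
        with pytest.raises(ValueError):
            closest_distance(path5, {"nope"}, {"a"})

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bfs_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        g = nx.gnp_random_graph(n, 0.15, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nodes = sorted(g.nodes)
        S = set(rng.choice(nodes, size=int(rng.integers(1, max(2, n // 3))),
                           replace=False).tolist())
        T = set(rng.choice(nodes, size=int(rng.integers(1, max(2, n // 3))),
                           replace=False).tolist())
        try:
            expected = dc_oracle(g, S, T)
        except ValueError:
            with pytest.raises(ValueError):
                closest_distance(g, S, T)
            return
        assert closest_distance(g, S, T) == expected

    def test_adding_target_never_increases_dc(self, ba_network):
        rng = np.random.default_rng(11)
        nodes = sorted(ba_network.nodes)
        S = set(rng.choice(nodes, 8, replace=False).tolist())
        T = set(rng.choice(nodes, 8, replace=False).tolist())
        dc0, _ = closest_distance(ba_network, S, T)
        extra = next(v for v in nodes if v not in T)
        dc1, _ = closest_distance(ba_network, S, T | {extra})
        assert dc1 <= dc0

    def test_adding_source_updates_mean_exactly(self, ba_network):
        rng = np.random.default_rng(12)
        nodes = sorted(ba_network.nodes)
        S = set(rng.choice(nodes, 6, replace=False).tolist())
        T = set(rng.choice(nodes, 6, replace=False).tolist())
        s_new = next(v for v in nodes if v not in S)
        dc0, _ = closest_distance(ba_network, S, T)
        d_new, _ = closest_distance(ba_network, {s_new}, T)
        dc1, _ = closest_distance(ba_network, S | {s_new}, T)
        assert dc1 == pytest.approx((len(S) * dc0 + d_new) / (len(S) + 1))

    def test_zero_iff_source_subset_of_target(self, ba_network):
        rng = np.random.default_rng(13)
        nodes = sorted(ba_network.nodes)
        T = set(rng.choice(nodes, 10, replace=False).tolist())
        S_in = set(list(T)[:3])
        assert closest_distance(ba_network, S_in, T)[0] == 0.0
        S_out = S_in | {next(v for v in nodes if v not in T)}
        assert closest_distance(ba_network, S_out, T)[0] > 0.0


class TestDegreeMatchedSample:
    def test_size_and_distinctness(self, ba_network):
        template = set(sorted(ba_network.nodes)[:12])
        sample = degree_matched_sample(ba_network, template, seed=1)
        assert len(sample) == len(template)
        assert sample <= set(ba_network.nodes)

    def test_same_seed_same_sample(self, ba_network):
        template = set(sorted(ba_network.nodes)[:12])
        assert degree_matched_sample(ba_network, template, seed=5) == \
            degree_matched_sample(ba_network, template, seed=5)
        assert degree_matched_sample(ba_network, template, seed=5) != \
            degree_matched_sample(ba_network, template, seed=6)

    def test_star_hub_is_its_own_bin(self):
        g = nx.star_graph(20)
        g = nx.relabel_nodes(g, {i: ("hub" if i == 0 else f"leaf{i}")
                                 for i in g.nodes})
        sample = degree_matched_sample(g, {"hub"}, seed=3, min_bin_size=1)
        assert sample == {"hub"}

    def test_binned_degree_histogram_preserved(self, ba_network):
        rng = np.random.default_rng(21)
        nodes = sorted(ba_network.nodes)
        template = set(rng.choice(nodes, 25, replace=False).tolist())
        bins = DegreeBins.from_network(ba_network, min_bin_size=10)
        sample = bins.sample_like(template, np.random.default_rng(4))

        def hist(nodeset):
            out = {}
            for v in nodeset:
                out[bins.bin_of[v]] = out.get(bins.bin_of[v], 0) + 1
            return out

        assert hist(sample) == hist(template)

    def test_template_outside_network_errors(self, ba_network):
        with pytest.raises(ValueError):
            degree_matched_sample(ba_network, {"NOT_A_NODE"}, seed=0)


class TestProximityTest:
    def test_empirical_p_matches_pseudocount_formula(self, ba_network):
        rng = np.random.default_rng(31)
        nodes = sorted(ba_network.nodes)
        S = set(rng.choice(nodes, 10, replace=False).tolist())
        T = set(rng.choice(nodes, 10, replace=False).tolist())
        res = proximity_test(ba_network, S, T, n_randomizations=100, seed=7)
        r = int(np.sum(res.null_values <= res.observed_dc + 1e-12))
        assert res.empirical_p == pytest.approx((r + 1) / 101)
        assert res.null_mean == pytest.approx(float(res.null_values.mean()))

    def test_planted_sets_detected_as_proximal(self, ba_network):
        from proxikit.synthetic_data import plant_proximal_sets

        S, T, _ = plant_proximal_sets(ba_network, 12, 12, 1, seed=9)
        res = proximity_test(ba_network, S, T, n_randomizations=200, seed=10)
        assert res.observed_dc <= 1.0
        assert res.empirical_p <= 0.05
        assert res.z_score < 0

    def test_determinism(self, ba_network):
        rng = np.random.default_rng(32)
        nodes = sorted(ba_network.nodes)
        S = set(rng.choice(nodes, 8, replace=False).tolist())
        T = set(rng.choice(nodes, 8, replace=False).tolist())
        r1 = proximity_test(ba_network, S, T, n_randomizations=50, seed=3)
        r2 = proximity_test(ba_network, S, T, n_randomizations=50, seed=3)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.empirical_p == r2.empirical_p

    def test_degenerate_null_flags_undefined_z(self):
        g = nx.complete_graph([f"n{i}" for i in range(12)])
        T = set(g.nodes)  # every draw and the observed distance are 0
        with pytest.warns(ProximityWarning):
            res = proximity_test(g, {"n0"}, T, n_randomizations=20, seed=1)
        assert res.observed_dc == 0.0
        assert np.isnan(res.z_score)
        assert res.empirical_p == 1.0

    def test_randomize_modes_run(self, ba_network):
        rng = np.random.default_rng(33)
        nodes = sorted(ba_network.nodes)
        S = set(rng.choice(nodes, 6, replace=False).tolist())
        T = set(rng.choice(nodes, 6, replace=False).tolist())
        for mode in ("S", "T", "both"):
            res = proximity_test(ba_network, S, T, n_randomizations=20,
                                 seed=2, randomize=mode)
            assert res.n_randomizations == 20
        with pytest.raises(ValueError):
            proximity_test(ba_network, S, T, randomize="neither")

    def test_json_output(self, tmp_path, ba_network):
        import json

        rng = np.random.default_rng(34)
        nodes = sorted(ba_network.nodes)
        S = set(rng.choice(nodes, 5, replace=False).tolist())
        T = set(rng.choice(nodes, 5, replace=False).tolist())
        res = proximity_test(ba_network, S, T, n_randomizations=25, seed=4)
        out = tmp_path / "prox.json"
        null = tmp_path / "null.tsv"
        res.to_json(out, null_path=null)
        payload = json.loads(out.read_text())
        assert payload["empirical_p"] == res.empirical_p
        assert payload["null_distribution_file"] == "null.tsv"
        vals = [float(x) for x in null.read_text().splitlines()[1:]]
        assert vals == pytest.approx(list(res.null_values))
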