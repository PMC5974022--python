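import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fmnet import fmn_network as net
from fmnet.abundance import AbundanceTable
from tests.conftest import make_relative


def merged_from(values, kinds=None, columns=None):
    arr = np.asarray(values, dtype=float)
    cols = columns or [f"f{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=cols)
    meta = pd.DataFrame(
        {
            "kind": kinds or ["taxon"] * len(cols),
            "mean_rel_abund": [np.nan] * len(cols),
        },
        index=cols,
    )
    return net.MergedFeatureMatrix(df, meta)


def network_from_r(rmat, columns=None):
    cols = columns or [f"f{j}" for j in range(len(rmat))]
    R = pd.DataFrame(np.asarray(rmat, dtype=float), index=cols, columns=cols)
    rng = np.random.default_rng(0)
    features = merged_from(rng.uniform(1, 2, size=(5, len(cols))), columns=cols)
    return net.build_network(R, features)


class TestMergeFeatures:
    def test_kind_tags_and_shapes(self):
        taxa = make_relative(np.full((5, 3), 1 / 3), index=[f"s{i}" for i in range(5)])
        mets = pd.DataFrame(
            np.ones((5, 2)), index=[f"s{i}" for i in range(5)], columns=["m1", "m2"]
        )
        m = net.merge_features(taxa, mets)
        assert m.df.shape == (5, 5)
        assert m.feature_meta["kind"].tolist() == ["taxon"] * 3 + ["metabolite"] * 2
        assert np.allclose(m.feature_meta["mean_rel_abund"].iloc[:3], 1 / 3)

    def test_disjoint_samples_rejected(self):
        taxa = make_relative(np.full((3, 2), 0.5), index=["a", "b", "c"])
        mets = pd.DataFrame(np.ones((2, 2)), index=["x", "y"], columns=["m1", "m2"])
        with pytest.raises(ValueError, match="no shared samples"):
            net.merge_features(taxa, mets)

    def test_partial_overlap_warns_and_intersects(self):
        taxa = make_relative(np.full((5, 2), 0.5), index=list("abcde"))
        mets = pd.DataFrame(
            np.ones((4, 1)), index=list("abcd"), columns=["m1"]
        )
        with pytest.warns(UserWarning, match="shared"):
            m = net.merge_features(taxa, mets)
        assert m.sample_ids == list("abcd")


class TestPearsonMatrix:
    def test_exact_linear_relations(self):
        x = np.arange(6, dtype=float)
        m = merged_from(np.column_stack([x, 2 * x + 1, -x]))
        R, P = net.pearson_matrix(m)
        assert R.loc["f0", "f1"] == pytest.approx(1.0)
        assert R.loc["f0", "f2"] == pytest.approx(-1.0)
        assert P.loc["f0", "f1"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 6))
        R, P = net.pearson_matrix(merged_from(x))
        for i, j in itertools.combinations(range(6), 2):
            a, b = x[:, i], x[:, j]
            manual = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
                ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
            )
            assert abs(R.iloc[i, j] - manual) < 1e-12

    def test_constant_feature_flagged_nan(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="constant"):
            R, P = net.pearson_matrix(merged_from(x))
        assert np.isnan(R.loc["f1", "f0"])

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            net.pearson_matrix(merged_from(np.ones((2, 3))))


class TestBuildNetwork:
    def test_signed_edges(self):
        n = network_from_r([[1, 0.8, -0.75], [0.8, 1, 0.1], [-0.75, 0.1, 1]])
        assert n.n_edges == 2
        signs = {d["sign"] for *_, d in n.graph.edges(data=True)}
        assert signs == {"synergistic", "competitive"}
        assert n.edge_signs() == (1, 1)

    def test_threshold_is_strict(self):
        n = network_from_r([[1, 0.7], [0.7, 1]])
        assert n.n_edges == 0

    def test_all_below_threshold_keeps_isolated_nodes(self):
        n = network_from_r(np.eye(4))
        assert n.n_nodes == 4 and n.n_edges == 0

    def test_nan_never_creates_edges(self):
        n = network_from_r([[1, np.nan], [np.nan, 1]])
        assert n.n_edges == 0

    def test_threshold_validation(self):
        features = merged_from(np.random.default_rng(0).uniform(size=(5, 2)))
        R = pd.DataFrame(np.eye(2), index=["f0", "f1"], columns=["f0", "f1"])
        with pytest.raises(ValueError, match="threshold"):
            net.build_network(R, features, threshold=1.5)


def brute_force_betweenness(g):
    """Exhaustive unordered-pair shortest-path enumeration."""
    bc = dict.fromkeys(g, 0.0)
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


class TestNodeMetrics:
    def _annotate(self, g):
        for u, v in g.edges:
            g[u][v].update(r=0.9, weight=0.9, sign="synergistic", cooccurrence=1)
        n = net.CorrelationNetwork(g, 0.7)
        return net.node_metrics(n)

    def test_path_and_star(self):
        path = self._annotate(nx.path_graph(3))
        assert path.graph.nodes[1]["betweenness"] == 1.0
        assert path.graph.nodes[0]["betweenness"] == 0.0
        star = self._annotate(nx.star_graph(4))
        assert star.graph.nodes[0]["betweenness"] == 6.0  # C(4,2) leaf pairs

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(123)
        for trial in range(30):
            n_nodes = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n_nodes, 0.35, seed=int(rng.integers(1 << 30)))
            annotated = self._annotate(g)
            oracle = brute_force_betweenness(g)
            for v in g.nodes:
                assert annotated.graph.nodes[v]["betweenness"] == pytest.approx(
                    oracle[v], abs=1e-9
                )

    def test_degree_equals_incident_edges(self):
        g = nx.path_graph(4)
        annotated = self._annotate(g)
        assert [annotated.graph.nodes[v]["degree"] for v in g] == [1, 2, 2, 1]


def weighted_network(edges):
    g = nx.Graph()
    for u, v, r in edges:
        g.add_edge(u, v, r=r, weight=abs(r), sign="synergistic" if r > 0 else "competitive",
                   cooccurrence=1)
    return net.CorrelationNetwork(g, 0.7)


class TestDetectFmcs:
    def test_two_disconnected_triangles(self):
        n = weighted_network(
            [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0)]
        )
        part = net.detect_fmcs(n, seed=0)
        assert part.n_communities == 2
        assert part.modularity == pytest.approx(0.5)  # 2 * (3/6 - (6/12)^2)

    def test_single_triangle_q_zero(self):
        n = weighted_network([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        part = net.detect_fmcs(n, seed=0)
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0)

    def test_dominates_trivial_partitions(self):
        rng = np.random.default_rng(4)
        edges = [
            (i, j, float(rng.uniform(0.71, 1.0)) * (1 if rng.random() < 0.7 else -1))
            for i, j in itertools.combinations(range(10), 2)
            if rng.random() < 0.4
        ]
        n = weighted_network(edges)
        part = net.detect_fmcs(n, seed=1)
        g = n.graph
        singletons = [{v} for v in g]
        whole = [set(g.nodes)]
        q_single = nx.community.modularity(g, singletons, weight="weight")
        q_whole = nx.community.modularity(g, whole, weight="weight")
        assert part.modularity >= q_single - 1e-12
        assert part.modularity >= q_whole - 1e-12

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(9)
        edges = [
            (i, j, 0.8)
            for i, j in itertools.combinations(range(12), 2)
            if rng.random() < 0.3
        ]
        n = weighted_network(edges)
        p1 = net.detect_fmcs(n, seed=3, n_restarts=5)
        p2 = net.detect_fmcs(n, seed=3, n_restarts=5)
        assert p1 == p2

    def test_edgeless_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        with pytest.raises(ValueError, match="edgeless"):
            net.detect_fmcs(net.CorrelationNetwork(g, 0.7), seed=0)


class TestNetworkSummary:
    @pytest.mark.parametrize(
        "nodes, edges, syn, com, density, ratio, pct_syn",
        [
            (63, 263, 223, 40, 0.135, 5.58, 84.8),
            (62, 112, 88, 24, 0.059, 3.67, 78.6),
            (14, 73, 36, 37, 0.802, 0.97, 49.3),
            (26, 108, 78, 30, 0.332, 2.60, 72.2),
        ],
    )
    def test_descriptor_arithmetic(self, nodes, edges, syn, com, density, ratio, pct_syn):
        s = net.NetworkSummary.from_counts(nodes, edges, syn, com)
        assert s.density == density
        assert s.syn_com_ratio == ratio
        assert s.pct_synergistic == pct_syn
        assert s.n_synergistic + s.n_competitive == s.n_edges
        assert 0 <= s.density <= 1
        assert s.pct_synergistic + s.pct_competitive == pytest.approx(100, abs=0.11)

    def test_keystone_ranking_and_tiebreak(self):
        g = nx.Graph()
        attrs = {
            "a": (5.0, 0.01),
            "b": (5.0, 0.05),  # tie on betweenness -> higher abundance wins
            "c": (9.0, 0.02),
            "d": (1.0, 0.03),
        }
        for v, (bc, mra) in attrs.items():
            g.add_node(v, kind="taxon", mean_rel_abund=mra, degree=0, betweenness=bc)
        g.add_edge("a", "b", r=0.8, weight=0.8, sign="synergistic", cooccurrence=1)
        n = net.CorrelationNetwork(g, 0.7)
        s = net.network_summary(n, partition=None, keystone_k=3)
        assert [k["id"] for k in s.keystone_features] == ["c", "b", "a"]

    def test_zero_competitive_ratio_is_null(self):
        s = net.NetworkSummary.from_counts(5, 3, 3, 0)
        assert s.syn_com_ratio is None


class TestValidatePartition:
    def test_planted_blocks_score_high(self):
        block = np.ones((3, 3)) * 0.95
        R = np.kron(np.eye(2), block)
        np.fill_diagonal(R, 1.0)
        ids = [f"f{i}" for i in range(6)]
        Rdf = pd.DataFrame(R, index=ids, columns=ids)
        part = net.FmcPartition({f: i // 3 for i, f in enumerate(ids)}, 0.4, 1.0, 0, 1)
        scores = net.validate_partition(Rdf, part)
        assert scores["silhouette"] > 0.9

    def test_random_labels_near_zero_silhouette(self):
        rng = np.random.default_rng(0)
        sils = []
        for _ in range(20):
            x = rng.normal(size=(30, 12))
            R = pd.DataFrame(
                np.corrcoef(x), index=[f"f{i}" for i in range(30)],
                columns=[f"f{i}" for i in range(30)],
            )
            labels = rng.integers(0, 2, 30)
            part = net.FmcPartition(
                {f"f{i}": int(l) for i, l in enumerate(labels)}, 0, 1.0, 0, 1
            )
            sils.append(net.validate_partition(R, part)["silhouette"])
        assert np.mean(np.abs(sils)) < 0.2

    def test_true_partition_beats_random_relabellings(self):
        rng = np.random.default_rng(1)
        block = np.ones((4, 4)) * 0.9
        R = np.kron(np.eye(2), block) + rng.normal(0, 0.01, (8, 8))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        ids = [f"f{i}" for i in range(8)]
        Rdf = pd.DataFrame(R, index=ids, columns=ids)
        true = {f: i // 4 for i, f in enumerate(ids)}
        ch_true = net.validate_partition(
            Rdf, net.FmcPartition(true, 0, 1.0, 0, 1)
        )["calinski_harabasz"]
        for _ in range(50):
            labels = rng.permutation([0] * 4 + [1] * 4)
            truth = np.array([true[f] for f in ids])
            if np.array_equal(labels, truth) or np.array_equal(1 - labels, truth):
                continue
            ch = net.validate_partition(
                Rdf, net.FmcPartition({f: int(l) for f, l in zip(ids, labels)}, 0, 1.0, 0, 1)
            )["calinski_harabasz"]
            assert ch < ch_true

    def test_single_community_rejected(self):
        R = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        part = net.FmcPartition({"a": 0, "b": 0, "c": 0}, 0, 1.0, 0, 1)
        with pytest.raises(ValueError, match="2 communities"):
            net.validate_partition(R, part)


class TestExport:
    def _network(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 6))
        x[:, 1] = x[:, 0] + rng.normal(0, 0.1, 20)
        x[:, 2] = -x[:, 0] + rng.normal(0, 0.1, 20)
        m = merged_from(x, kinds=["taxon"] * 3 + ["metabolite"] * 3)
        R, _ = net.pearson_matrix(m)
        n = net.build_network(R, m)
        return net.node_metrics(n)

    @pytest.mark.parametrize("fmt", ["graphml", "gexf"])
    def test_round_trip(self, tmp_path, fmt):
        n = self._network()
        part = net.detect_fmcs(n, seed=0, n_restarts=3)
        path = tmp_path / f"net.{fmt}"
        net.export_network(n, part, path, format=fmt)
        back = net.read_network(path, format=fmt)
        assert set(back.graph.nodes) == set(n.graph.nodes)
        assert {frozenset(e) for e in back.graph.edges} == {
            frozenset(e) for e in n.graph.edges
        }
        for u, v, d in n.graph.edges(data=True):
            assert back.graph[u][v]["r"] == pytest.approx(d["r"])
            assert back.graph[u][v]["sign"] == d["sign"]

    def test_edge_tsv_rows_and_signs(self, tmp_path):
        n = self._network()
        path = tmp_path / "edges.tsv"
        net.export_network(n, None, path, format="edge-tsv")
        df = pd.read_csv(path, sep="\t")
        assert len(df) == n.n_edges
        for _, row in df.iterrows():
            assert (row["sign"] == "synergistic") == (row["r"] > 0)

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            net.export_network(self._network(), None, tmp_path / "x", format="dot")
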