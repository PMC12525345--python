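"""Embedding, similarity calibration and Fisher-combined proximity scores."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from degnet import interactome as ia
from degnet import proximity as px
from degnet.projection import ClusterSet


def _net(graph: nx.Graph) -> ia.Interactome:
    return ia.Interactome.from_edges(
        [ia.EdgeRecord(str(a), str(b), 500) for a, b in graph.edges()]
    )


def _embed_graph(graph: nx.Graph, seed=0, **kw):
    net = _net(graph)
    adj = ia.normalized_adjacency(net)
    cfg = px.EmbeddingConfig(seed=seed, **kw)
    return net, px.embed(adj, net.node_order, cfg)


class TestEmbed:
    def test_two_cliques_separate_in_cosine_space(self):
        g = nx.disjoint_union(nx.complete_graph(20), nx.complete_graph(20))
        net, emb = _embed_graph(g, seed=1, dimensions=32, walk_length=40, num_walks=5)
        sim = px.cosine_sim(emb)
        order = net.node_order
        a = [i for i, n in enumerate(order) if int(n) < 20]
        b = [i for i, n in enumerate(order) if int(n) >= 20]
        within = np.mean([sim[i, j] for i in a for j in a if i != j])
        between = np.mean([sim[i, j] for i in a for j in b])
        assert within > between

    def test_identical_seed_gives_identical_vectors(self):
        g = nx.gnp_random_graph(30, 0.2, seed=2)
        _, emb1 = _embed_graph(g, seed=9, dimensions=16, walk_length=20, num_walks=4)
        _, emb2 = _embed_graph(g, seed=9, dimensions=16, walk_length=20, num_walks=4)
        assert np.array_equal(emb1.vectors, emb2.vectors)

    def test_shape_contract_on_path(self):
        _, emb = _embed_graph(nx.path_graph(5), dimensions=4, walk_length=10, num_walks=3)
        assert emb.vectors.shape == (5, 4)

    def test_second_order_bias_path_matches_first_order_when_pq_one(self):
        # p=q=1 fast path and the biased walker sample the same distribution;
        # check structural agreement rather than bitwise equality
        g = nx.disjoint_union(nx.complete_graph(10), nx.complete_graph(10))
        net = _net(g)
        adj = ia.normalized_adjacency(net)
        cfg = px.EmbeddingConfig(dimensions=8, walk_length=15, num_walks=5, p=2.0, q=0.5, seed=3)
        emb = px.embed(adj, net.node_order, cfg)
        sim = px.cosine_sim(emb)
        order = net.node_order
        a = [i for i, n in enumerate(order) if int(n) < 10]
        b = [i for i, n in enumerate(order) if int(n) >= 10]
        within = np.mean([sim[i, j] for i in a for j in a if i != j])
        between = np.mean([sim[i, j] for i in a for j in b])
        assert within > between


class TestCosineSim:
    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        vec = rng.normal(size=(10, 8))
        emb = px.Embedding(node_order=[f"g{i}" for i in range(10)], vectors=vec)
        sim = px.cosine_sim(emb)
        for i in range(10):
            for j in range(10):
                expected = vec[i] @ vec[j] / (np.linalg.norm(vec[i]) * np.linalg.norm(vec[j]))
                assert sim[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(5)
        emb = px.Embedding(node_order=[f"g{i}" for i in range(6)], vectors=rng.normal(size=(6, 4)))
        sim = px.cosine_sim(emb)
        assert np.array_equal(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)

    def test_zero_vector_raises(self):
        vec = np.zeros((3, 4))
        vec[0] = [1, 0, 0, 0]
        emb = px.Embedding(node_order=["a", "b", "c"], vectors=vec)
        with pytest.raises(Exception, match="b"):
            px.cosine_sim(emb)


@pytest.fixture(scope="module")
def sbm_setup():
    g = nx.stochastic_block_model([100, 100], [[0.3, 0.02], [0.02, 0.3]], seed=6)
    net, emb = _embed_graph(g, seed=6, dimensions=32, walk_length=40, num_walks=5)
    sim = px.cosine_sim(emb)
    return net, sim


class TestLinkModel:
    def test_positive_slope_on_modular_graph(self, sbm_setup):
        net, sim = sbm_setup
        model = px.fit_link_model(sim, net, net.node_order, seed=1)
        assert model.slope > 0
        assert model.n_positive == model.n_negative

    def test_edges_rank_above_nonedges(self, sbm_setup):
        net, sim = sbm_setup
        model = px.fit_link_model(sim, net, net.node_order, seed=1)
        order = net.node_order
        idx = {g: i for i, g in enumerate(order)}
        rng = np.random.default_rng(2)
        edges = list(net.graph.edges)
        edge_set = {tuple(sorted((idx[a], idx[b]))) for a, b in edges}
        pos = [sim[idx[a], idx[b]] for a, b in rng.choice(edges, size=200)]
        neg = []
        while len(neg) < 200:
            i, j = rng.integers(0, len(order), size=2)
            if i != j and tuple(sorted((int(i), int(j)))) not in edge_set:
                neg.append(sim[i, j])
        p_pos = model.predict(np.array(pos))
        p_neg = model.predict(np.array(neg))
        # Monte-Carlo ranking accuracy (AUC-like)
        wins = np.mean(p_pos[:, None] > p_neg[None, :])
        assert wins > 0.5

    def test_constant_similarity_gives_base_rate(self):
        g = nx.gnp_random_graph(40, 0.2, seed=7)
        net = _net(g)
        n = net.n_nodes
        sim = np.full((n, n), 0.5)
        model = px.fit_link_model(sim, net, net.node_order, seed=3)
        prob = model.predict(np.array([0.5]))[0]
        assert prob == pytest.approx(0.5, abs=0.1)  # balanced training set base rate


class TestAssociationProb:
    def test_zero_slope_gives_constant(self):
        model = px.LinkModel(intercept=-1.0, slope=0.0, n_positive=1, n_negative=1, seed=0)
        sim = np.eye(4)
        probs = px.association_prob(model, sim, ["a", "b", "c", "d"], "a")
        assert np.allclose(probs, 1 / (1 + math.exp(1.0)))
        assert "a" not in probs.index

    def test_monotone_in_similarity(self):
        model = px.LinkModel(intercept=0.0, slope=3.0, n_positive=1, n_negative=1, seed=0)
        sim = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.0], [0.1, 0.0, 1.0]])
        probs = px.association_prob(model, sim, ["causal", "hi", "lo"], "causal")
        assert probs["hi"] > probs["lo"]

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        n = 50
        sim = rng.uniform(-1, 1, size=(n, n))
        order = [f"g{i:02d}" for i in range(n)]
        model = px.LinkModel(intercept=0.3, slope=2.0, n_positive=1, n_negative=1, seed=0)
        probs = px.association_prob(model, sim, order, order[7])
        for g in probs.index:
            s = sim[order.index(g), 7]
            assert probs[g] == pytest.approx(1 / (1 + math.exp(-(0.3 + 2.0 * s))), abs=1e-12)

    def test_missing_causal_gene_raises(self):
        model = px.LinkModel(0, 1, 1, 1, 0)
        with pytest.raises(Exception, match="causal"):
            px.association_prob(model, np.eye(2), ["a", "b"], "zz")


class TestRankNormalize:
    def test_strictly_increasing_probs(self):
        probs = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        scores = px.rank_normalize(probs)
        assert list(scores) == [0.25, 0.5, 0.75, 1.0]

    def test_all_ties_get_mean_rank(self):
        n = 6
        probs = pd.Series([0.5] * n, index=[f"g{i}" for i in range(n)])
        scores = px.rank_normalize(probs)
        assert np.allclose(scores, 0.5 + 1 / (2 * n))

    def test_top_gene_scores_one(self):
        rng = np.random.default_rng(9)
        probs = pd.Series(rng.uniform(size=20), index=[f"g{i}" for i in range(20)])
        scores = px.rank_normalize(probs)
        assert scores[probs.idxmax()] == 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        probs = pd.Series(rng.uniform(size=15), index=[f"g{i}" for i in range(15)])
        perm = probs.sample(frac=1, random_state=1)
        assert px.rank_normalize(probs).sort_index().equals(
            px.rank_normalize(perm).sort_index()
        )


class TestFisherCombine:
    def test_all_ones_give_one(self):
        assert px.fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_two_halves_closed_form(self):
        x = -2 * (math.log(0.5) + math.log(0.5))
        expected = math.exp(-x / 2) * (1 + x / 2)
        assert px.fisher_combine([0.5, 0.5]) == pytest.approx(expected, abs=1e-12)
        assert px.fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    def test_single_p_identity(self):
        for p in (0.01, 0.2, 0.77):
            assert px.fisher_combine([p]) == pytest.approx(p, abs=1e-12)

    def test_df4_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p1, p2 = rng.uniform(1e-6, 1, size=2)
            x = -2 * (math.log(p1) + math.log(p2))
            expected = math.exp(-x / 2) * (1 + x / 2)
            assert px.fisher_combine([p1, p2]) == pytest.approx(expected, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(Exception):
            px.fisher_combine([])


class TestScoreClusters:
    def _cset(self, clusters, isolated=()):
        return ClusterSet(clusters=clusters, isolated=list(isolated))

    def test_top_ranked_members_score_one(self):
        ranks = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 0.2})
        df = px.score_clusters(self._cset({0: ["a", "b", "c"]}), ranks)
        assert df.loc[0, "score"] == 1.00

    def test_midline_cluster_matches_chi_square_oracle(self):
        ranks = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        df = px.score_clusters(self._cset({0: ["a", "b", "c"]}), ranks)
        expected = 1 - px.fisher_combine([0.5, 0.5, 0.5])
        assert df.loc[0, "score_exact"] == pytest.approx(expected, abs=1e-12)

    def test_ordering_by_score_then_id(self):
        ranks = pd.Series({"a": 0.99, "b": 0.98, "c": 0.97, "x": 0.2, "y": 0.3, "z": 0.1})
        df = px.score_clusters(
            self._cset({0: ["x", "y", "z"], 1: ["a", "b", "c"]}), ranks
        )
        assert list(df["cluster_id"]) == [1, 0]

    def test_missing_member_raises(self):
        ranks = pd.Series({"a": 0.5})
        with pytest.raises(Exception):
            px.score_clusters(self._cset({0: ["a", "zz"]}), ranks)

    def test_direct_probability_mode(self):
        ranks = pd.Series({"a": 0.9, "b": 0.8})
        probs = pd.Series({"a": 0.7, "b": 0.6})
        df = px.score_clusters(
            self._cset({0: ["a", "b"]}), ranks, probability_mode="direct",
            association_probs=probs,
        )
        expected = 1 - px.fisher_combine([0.3, 0.4])
        assert df.loc[0, "score_exact"] == pytest.approx(expected, abs=1e-12)


class TestRankIsolated:
    def test_sorted_descending(self):
        ranks = pd.Series({"a": 0.3, "b": 0.9, "c": 0.6})
        df = px.rank_isolated(["a", "b", "c"], ranks)
        assert list(df["gene_id"]) == ["b", "c", "a"]

    def test_fewer_than_k_returns_all(self):
        ranks = pd.Series({"a": 0.3, "b": 0.9})
        assert len(px.rank_isolated(["a", "b"], ranks, top_k=10)) == 2

    def test_top_k_equals_full_sort_head(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(100)]
        ranks = pd.Series(rng.uniform(size=100), index=genes)
        top = px.rank_isolated(genes, ranks, top_k=10)
        manual = ranks.sort_values(ascending=False).head(10)
        assert list(top["gene_id"]) == list(manual.index)


class TestUmap:
    def test_shape_determinism_and_separation(self):
        g = nx.disjoint_union(nx.complete_graph(15), nx.complete_graph(15))
        net = _net(g)
        c1 = px.umap_coords(net, seed=4)
        c2 = px.umap_coords(net, seed=4)
        assert c1.shape == (30, 3) and list(c1.columns) == ["gene_id", "x", "y"]
        pd.testing.assert_frame_equal(c1, c2)
        xy = c1[["x", "y"]].to_numpy()
        order = net.node_order
        a = np.array([int(n) < 15 for n in order])
        da = xy[a].mean(axis=0)
        db = xy[~a].mean(axis=0)
        within = np.linalg.norm(xy[a] - da, axis=1).mean()
        between = np.linalg.norm(da - db)
        assert between > within
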