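import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from lmdlink.exceptions import ContractError
from lmdlink.lmdn_graph import graph_from_edges
from lmdlink.node2vec import (
    AliasSampler,
    WalkConfig,
    build_alias_tables,
    generate_walks,
    read_corpus,
    read_embeddings,
    train_embeddings,
    transition_distribution,
    unnormalized_bias,
    write_corpus,
    write_embeddings,
)


def path_graph():
    return graph_from_edges([("A", "B"), ("B", "C")])


def oracle_distribution(edges, prev, cur, p, q):
    """Independent route: BFS distances + bias weights + normalization."""
    G = nx.Graph(edges)
    dist = nx.single_source_shortest_path_length(G, prev)
    weights = {
        x: {0: 1 / p, 1: 1.0, 2: 1 / q}[min(dist[x], 2)] for x in G.neighbors(cur)
    }
    Z = sum(weights.values())
    return {x: w / Z for x, w in weights.items()}


class TestUnnormalizedBias:
    def test_return_weight(self):
        assert unnormalized_bias(0, p=2.0, q=1.0) == 0.5

    def test_unit_weight_at_distance_one(self):
        assert unnormalized_bias(1, p=7.0, q=0.1) == 1.0

    def test_outward_weight(self):
        assert unnormalized_bias(2, p=1.0, q=0.25) == 4.0

    def test_other_distances_rejected(self):
        with pytest.raises(ContractError):
            unnormalized_bias(3, 1.0, 1.0)


class TestTransitionDistribution:
    def test_symmetric_at_unit_parameters(self):
        d = transition_distribution(path_graph(), "A", "B", p=1, q=1)
        assert d == {"A": 0.5, "C": 0.5}

    def test_high_p_discourages_backtracking(self):
        d = transition_distribution(path_graph(), "A", "B", p=4, q=1)
        assert np.isclose(d["A"], 0.2) and np.isclose(d["C"], 0.8)

    def test_triangle_all_neighbors_at_distance_one(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        d = transition_distribution(g, "A", "B", p=1, q=2)
        # C is adjacent to prev=A, so its weight is 1, like returning to A
        assert np.isclose(d["A"], 0.5) and np.isclose(d["C"], 0.5)

    def test_first_step_is_uniform(self):
        g = graph_from_edges([("A", "B"), ("A", "C"), ("A", "D")])
        d = transition_distribution(g, None, "A", p=9, q=0.1)
        assert all(np.isclose(v, 1 / 3) for v in d.values())

    def test_isolated_node_is_dead_end(self):
        g = graph_from_edges([("A", "B")], extra_nodes=["Z"])
        with pytest.raises(ContractError):
            transition_distribution(g, None, "Z", 1, 1)

    def test_nonadjacent_prev_rejected(self):
        with pytest.raises(ContractError):
            transition_distribution(path_graph(), "C", "A", 1, 1)

    @pytest.mark.parametrize("seed,p,q", [(0, 1, 1), (1, 4, 0.25), (2, 0.5, 2)])
    def test_matches_bfs_oracle_on_random_graphs(self, seed, p, q):
        G = nx.gnp_random_graph(12, 0.35, seed=seed)
        edges = [(f"n{u}", f"n{v}") for u, v in G.edges]
        g = graph_from_edges(edges)
        for u, v in edges + [(b, a) for a, b in edges]:
            got = transition_distribution(g, u, v, p, q)
            want = oracle_distribution(edges, u, v, p, q)
            assert set(got) == set(want)
            assert all(abs(got[x] - want[x]) < 1e-12 for x in got)
            assert abs(sum(got.values()) - 1.0) < 1e-12

    def test_deepwalk_limit_is_exactly_uniform(self):
        G = nx.gnp_random_graph(10, 0.5, seed=3)
        edges = [(f"n{u}", f"n{v}") for u, v in G.edges]
        g = graph_from_edges(edges)
        for u, v in edges:
            d = transition_distribution(g, u, v, p=1, q=1)
            assert all(x == 1.0 / len(d) for x in d.values())


class TestAliasSampler:
    def test_uniform_table_has_unit_acceptance(self):
        s = AliasSampler(np.full(4, 0.25))
        assert np.array_equal(s.prob, np.ones(4))

    def test_two_way_exact(self):
        s = AliasSampler(np.array([0.5, 0.5]))
        assert np.allclose(s.probabilities(), [0.5, 0.5])

    def test_analytic_reconstruction_random_distributions(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 12))
            p = rng.random(n) + 1e-3
            p /= p.sum()
            s = AliasSampler(p)
            assert np.abs(s.probabilities() - p).max() < 1e-12

    def test_empirical_frequencies_chi_square(self, rng):
        p = np.array([0.1, 0.2, 0.7])
        s = AliasSampler(p)
        draws = np.array([s.sample(rng) for _ in range(100_000)])
        observed = np.bincount(draws, minlength=3)
        assert stats.chisquare(observed, 100_000 * p).pvalue > 0.01

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ContractError):
            AliasSampler(np.array([0.5, 0.6]))

    def test_tables_reproduce_transition_distributions(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        tables = build_alias_tables(g, p=2.0, q=0.5)
        idx = g.index
        for (pi, ci), sampler in tables.second_order.items():
            prev, cur = g.nodes[pi], g.nodes[ci]
            want = transition_distribution(g, prev, cur, 2.0, 0.5)
            names = g.adjacency(cur)
            assert np.abs(
                sampler.probabilities() - np.array([want[x] for x in names])
            ).max() < 1e-12


class TestGenerateWalks:
    def test_single_edge_alternates(self):
        g = graph_from_edges([("A", "B")])
        cfg = WalkConfig(walk_length=3, walks_per_node=1, seed=0)
        walks = generate_walks(g, cfg)
        assert sorted(walks) == [["A", "B", "A", "B"], ["B", "A", "B", "A"]]

    def test_consecutive_nodes_always_adjacent(self):
        G = nx.gnp_random_graph(15, 0.3, seed=5)
        edges = [(f"n{u}", f"n{v}") for u, v in G.edges]
        g = graph_from_edges(edges)
        cfg = WalkConfig(walk_length=10, walks_per_node=2, seed=1)
        for walk in generate_walks(g, cfg):
            for a, b in itertools.pairwise(walk):
                assert g.has_edge(a, b)

    def test_walk_count_and_length(self):
        g = graph_from_edges([("A", "B"), ("B", "C")])
        cfg = WalkConfig(walk_length=4, walks_per_node=3, seed=0)
        walks = generate_walks(g, cfg)
        assert len(walks) == 9
        assert all(len(w) == 5 for w in walks)

    def test_star_center_transitions_uniform(self, rng):
        leaves = [f"leaf{i}" for i in range(5)]
        g = graph_from_edges([("hub", leaf) for leaf in leaves])
        cfg = WalkConfig(walk_length=40, walks_per_node=500, seed=9)
        counts = {leaf: 0 for leaf in leaves}
        for walk in generate_walks(g, cfg):
            for a, b in itertools.pairwise(walk):
                if a == "hub":
                    counts[b] += 1
        observed = np.array([counts[leaf] for leaf in leaves])
        expected = np.full(5, observed.sum() / 5)
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_seed_reproducibility(self):
        G = nx.gnp_random_graph(10, 0.4, seed=2)
        g = graph_from_edges([(f"n{u}", f"n{v}") for u, v in G.edges])
        cfg = WalkConfig(walk_length=8, walks_per_node=3, seed=42, p=2, q=0.5)
        assert generate_walks(g, cfg) == generate_walks(g, cfg)

    def test_isolated_nodes_skipped_with_warning(self, caplog):
        g = graph_from_edges([("A", "B")], extra_nodes=["Z"])
        cfg = WalkConfig(walk_length=2, walks_per_node=1, seed=0)
        with caplog.at_level("WARNING"):
            walks = generate_walks(g, cfg)
        assert len(walks) == 2
        assert any("isolated" in rec.message for rec in caplog.records)


class TestTrainEmbeddings:
    def test_one_vector_per_corpus_node_with_configured_dim(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        cfg = WalkConfig(
            walk_length=10, walks_per_node=5, dimensions=16, epochs=1, seed=0
        )
        emb = train_embeddings(generate_walks(g, cfg), cfg)
        assert set(emb.vectors) == {"A", "B", "C"}
        assert all(v.shape == (16,) for v in emb.vectors.values())

    def test_empty_corpus_rejected(self):
        with pytest.raises(ContractError):
            train_embeddings([], WalkConfig())

    def test_deterministic_given_seed(self):
        g = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        cfg = WalkConfig(
            walk_length=10, walks_per_node=4, dimensions=8, epochs=2, seed=11
        )
        walks = generate_walks(g, cfg)
        e1 = train_embeddings(walks, cfg)
        e2 = train_embeddings(walks, cfg)
        assert all(np.array_equal(e1.vectors[n], e2.vectors[n]) for n in e1.vectors)

    def test_two_cliques_separate_in_embedding_space(self):
        # two 10-cliques joined by a single bridge edge
        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(10)]
        edges = (
            list(itertools.combinations(a, 2))
            + list(itertools.combinations(b, 2))
            + [("a0", "b0")]
        )
        g = graph_from_edges(edges)
        cfg = WalkConfig(
            walk_length=20, walks_per_node=10, dimensions=8, epochs=3, seed=4
        )
        emb = train_embeddings(generate_walks(g, cfg), cfg)
        V = {n: v / np.linalg.norm(v) for n, v in emb.vectors.items()}

        def mean_cos(pairs):
            return float(np.mean([np.dot(V[u], V[v]) for u, v in pairs]))

        within = mean_cos(
            list(itertools.combinations(a, 2)) + list(itertools.combinations(b, 2))
        )
        between = mean_cos(list(itertools.product(a, b)))
        assert within > between


def test_corpus_and_embedding_files_round_trip(tmp_path):
    g = graph_from_edges([("A", "B"), ("B", "C")])
    cfg = WalkConfig(walk_length=5, walks_per_node=2, dimensions=4, epochs=1, seed=0)
    walks = generate_walks(g, cfg)
    cpath = tmp_path / "walks.txt"
    write_corpus(walks, cpath)
    assert read_corpus(cpath) == walks
    emb = train_embeddings(walks, cfg)
    epath = tmp_path / "emb.w2v"
    write_embeddings(emb, epath)
    back = read_embeddings(epath)
    assert back.d == emb.d
    assert all(np.array_equal(back.vectors[n], emb.vectors[n]) for n in emb.vectors)
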