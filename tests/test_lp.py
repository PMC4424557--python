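import numpy as np
import pytest
import scipy.sparse as sp

from bilex.context import cosine, extract_context_vectors
from bilex.corpus_io import SeedLexicon, TermType, build_vocabulary
from bilex.lp import (
    CooccurrenceGraph,
    SingularSystemError,
    build_graph,
    fixed_point_oracle,
    init_labels,
    propagate,
    rank_lp,
)
from tests.conftest import make_corpus, make_document
from tests.test_context import single_token_corpus


def graph_from_edges(n_vertices, edges, seed_dims, n_dims, language="en"):
    """Build a CooccurrenceGraph directly from (i, j, w) triples."""
    vertices = [TermType(language, (f"v{i}",)) for i in range(n_vertices)]
    rows, cols, vals = [], [], []
    for i, j, w in edges:
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    weights = sp.csr_matrix(
        (np.array(vals, float), (rows, cols)), shape=(n_vertices, n_vertices)
    )
    return CooccurrenceGraph(
        vertices=vertices,
        weights=weights,
        seed_dims={vertices[i]: dims for i, dims in seed_dims.items()},
        n_dims=n_dims,
    )


def random_connected_graph(rng, n_vertices, n_seeds, n_dims):
    """Random connected graph with small diameter; random seed vertices.

    Every vertex attaches to two earlier vertices (one for the spanning
    tree), keeping the diameter logarithmic so 500 propagation cycles
    reach the fixed point well within 1e-6.
    """
    edge_set = set()
    for i in range(1, n_vertices):
        edge_set.add((int(rng.integers(0, i)), i))
        if i >= 2:
            edge_set.add((int(rng.integers(0, i)), i))
    n_extra = int(rng.integers(0, n_vertices))
    for _ in range(n_extra):
        i, j = sorted(rng.choice(n_vertices, size=2, replace=False).tolist())
        edge_set.add((int(i), int(j)))
    edges = [(i, j, float(rng.uniform(0.1, 1.0))) for i, j in sorted(edge_set)]
    seeds = rng.choice(n_vertices, size=n_seeds, replace=False)
    seed_dims = {int(v): (d,) for d, v in enumerate(seeds)}
    return graph_from_edges(n_vertices, edges, seed_dims, n_dims=n_seeds)


class TestBuildGraph:
    def test_no_edge_without_cooccurrence(self, seed_lexicon_2):
        corpus = single_token_corpus("zh", [["s1", "a", "s2"], ["s1", "b", "s2"]])
        vocab = build_vocabulary(corpus)
        vectors = extract_context_vectors(corpus, seed_lexicon_2)
        graph = build_graph(vocab, vectors, corpus, seed_lexicon_2)
        ia = graph.vertex_index[TermType("zh", ("a",))]
        ib = graph.vertex_index[TermType("zh", ("b",))]
        assert graph.weights[ia, ib] == 0.0

    def test_identical_vectors_weight_one(self, seed_lexicon_2):
        corpus = single_token_corpus("zh", [["s1", "a", "b", "s2"]])
        vocab = build_vocabulary(corpus)
        vectors = extract_context_vectors(corpus, seed_lexicon_2)
        graph = build_graph(vocab, vectors, corpus, seed_lexicon_2)
        ia = graph.vertex_index[TermType("zh", ("a",))]
        ib = graph.vertex_index[TermType("zh", ("b",))]
        assert graph.weights[ia, ib] == pytest.approx(1.0)

    def test_matches_brute_force_cooccurrence_scan(self, seed_lexicon_2):
        sentences = [
            ["s1", "a", "b", "s2"],
            ["b", "c", "s1"],
            ["d", "s2", "a"],
            ["e", "f"],
        ]
        corpus = single_token_corpus("zh", sentences)
        vocab = build_vocabulary(corpus)
        vectors = extract_context_vectors(corpus, seed_lexicon_2)
        graph = build_graph(vocab, vectors, corpus, seed_lexicon_2)
        terms = sorted(vocab)
        for a in terms:
            for b in terms:
                if a >= b:
                    continue
                cooccur = any(
                    {a.words[0], b.words[0]} <= set(s) for s in sentences
                )
                expected = cosine(vectors[a], vectors[b]) if cooccur else 0.0
                got = graph.weights[graph.vertex_index[a], graph.vertex_index[b]]
                assert got == pytest.approx(expected), (a, b)

    def test_no_self_loops_and_symmetry(self, seed_lexicon_2):
        corpus = single_token_corpus("zh", [["s1", "a", "a", "s2"]])
        vocab = build_vocabulary(corpus)
        vectors = extract_context_vectors(corpus, seed_lexicon_2)
        graph = build_graph(vocab, vectors, corpus, seed_lexicon_2)
        dense = graph.weights.toarray()
        assert np.allclose(dense, dense.T)
        assert np.all(np.diag(dense) == 0)

    def test_freq_edge_weight(self, seed_lexicon_2):
        corpus = single_token_corpus("zh", [["a", "b"], ["a", "b"], ["a", "b"]])
        vocab = build_vocabulary(corpus)
        vectors = extract_context_vectors(corpus, seed_lexicon_2)
        graph = build_graph(vocab, vectors, corpus, seed_lexicon_2, "freq")
        ia = graph.vertex_index[TermType("zh", ("a",))]
        ib = graph.vertex_index[TermType("zh", ("b",))]
        assert graph.weights[ia, ib] == 3.0

    def test_empty_vocabulary(self, seed_lexicon_2):
        corpus = single_token_corpus("zh", [["x"]])
        with pytest.raises(ValueError, match="empty vocabulary"):
            build_graph({}, {}, corpus, seed_lexicon_2)


class TestInitLabels:
    def test_uniform_non_seed(self):
        graph = graph_from_edges(
            5, [(i, 4, 1.0) for i in range(4)], {i: (i,) for i in range(4)}, 4
        )
        labels = init_labels(graph)
        assert np.allclose(labels.values[4], [0.25, 0.25, 0.25, 0.25])

    def test_one_hot_seed(self):
        graph = graph_from_edges(
            5, [(i, 4, 1.0) for i in range(4)], {i: (i,) for i in range(4)}, 4
        )
        labels = init_labels(graph)
        assert labels.values[2].tolist() == [0.0, 0.0, 1.0, 0.0]

    def test_no_seeds_rejected(self):
        graph = graph_from_edges(2, [(0, 1, 1.0)], {}, 2)
        with pytest.raises(ValueError, match="no seed"):
            init_labels(graph)


class TestPropagate:
    def test_two_equal_weight_seed_neighbors_one_iteration(self):
        graph = graph_from_edges(
            3, [(0, 2, 1.0), (1, 2, 1.0)], {0: (0,), 1: (1,)}, 2
        )
        labels = propagate(graph, init_labels(graph), iterations=1)
        assert labels.values[2].tolist() == [0.5, 0.5]

    def test_seed_clamped_after_ten_iterations(self):
        rng = np.random.default_rng(0)
        graph = random_connected_graph(rng, 12, 3, 3)
        init = init_labels(graph)
        out = propagate(graph, init, iterations=10)
        for term in graph.seed_dims:
            i = graph.vertex_index[term]
            assert np.array_equal(out.values[i], init.values[i])

    def test_isolated_non_seed_stays_uniform(self):
        graph = graph_from_edges(3, [(0, 1, 1.0)], {0: (0,), 1: (1,)}, 2)
        out = propagate(graph, init_labels(graph), iterations=10)
        assert np.allclose(out.values[2], [0.5, 0.5])

    def test_synchronous_updates(self):
        # chain seed(dim0) - a - b: after one cycle b must use a's INITIAL
        # label (uniform), not its updated one
        graph = graph_from_edges(
            3, [(0, 1, 1.0), (1, 2, 1.0)], {0: (0,)}, 2
        )
        out = propagate(graph, init_labels(graph), iterations=1)
        assert np.allclose(out.values[2], [0.5, 0.5])
        assert np.allclose(out.values[1], [0.75, 0.25])

    def test_simplex_preserved_each_cycle(self):
        rng = np.random.default_rng(1)
        graph = random_connected_graph(rng, 15, 4, 4)
        labels = init_labels(graph)
        for _ in range(10):
            labels = propagate(graph, labels, iterations=1)
            assert np.all(labels.values >= 0)
            assert np.allclose(labels.values.sum(axis=1), 1.0, atol=1e-9)

    def test_convergence_threshold_stop(self):
        graph = graph_from_edges(
            3, [(0, 2, 1.0), (1, 2, 1.0)], {0: (0,), 1: (1,)}, 2
        )
        out = propagate(graph, init_labels(graph), iterations=500, tol=1e-8)
        assert out.iteration < 500


class TestFixedPointOracle:
    def test_chain_two_seeds(self):
        graph = graph_from_edges(
            3, [(0, 2, 1.0), (1, 2, 1.0)], {0: (0,), 1: (1,)}, 2
        )
        labels = fixed_point_oracle(graph)
        assert np.allclose(labels.values[2], [0.5, 0.5])

    def test_star_weighted(self):
        graph = graph_from_edges(
            4,
            [(0, 3, 1.0), (1, 3, 1.0), (2, 3, 2.0)],
            {0: (0,), 1: (1,), 2: (2,)},
            3,
        )
        labels = fixed_point_oracle(graph)
        assert np.allclose(labels.values[3], [0.25, 0.25, 0.5])

    def test_all_seeds_returns_initialization(self):
        graph = graph_from_edges(2, [(0, 1, 1.0)], {0: (0,), 1: (1,)}, 2)
        assert np.array_equal(
            fixed_point_oracle(graph).values, init_labels(graph).values
        )

    def test_seedless_component_reported(self):
        graph = graph_from_edges(
            4, [(0, 1, 1.0), (2, 3, 1.0)], {0: (0,)}, 1
        )
        with pytest.raises(SingularSystemError, match="v2"):
            fixed_point_oracle(graph)

    def test_residual_satisfies_update_equation(self):
        rng = np.random.default_rng(5)
        graph = random_connected_graph(rng, 18, 4, 4)
        labels = fixed_point_oracle(graph)
        after = propagate(graph, labels, iterations=1)
        assert np.abs(after.values - labels.values).max() < 1e-10


class TestProperties:
    def test_propagation_converges_to_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(5, 21))
            k = int(rng.integers(1, min(6, n)))
            graph = random_connected_graph(rng, n, k, k)
            oracle = fixed_point_oracle(graph)
            iterated = propagate(graph, init_labels(graph), iterations=500)
            assert np.abs(oracle.values - iterated.values).max() < 1e-6

    def test_homophily_two_clusters(self):
        # two dense clusters, each anchored on its own seed dimension,
        # bridged by one weak edge
        edges = [
            (0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0),
            (3, 4, 1.0), (3, 5, 1.0), (4, 5, 1.0),
            (2, 5, 0.05),
        ]
        graph = graph_from_edges(6, edges, {0: (0,), 3: (1,)}, 2)
        labels = propagate(graph, init_labels(graph), iterations=50)

        def cos(i, j):
            a, b = labels.values[i], labels.values[j]
            return a @ b / np.linalg.norm(a) / np.linalg.norm(b)

        assert cos(1, 2) > cos(1, 4)
        assert cos(4, 5) > cos(2, 5)

    def test_monotone_seed_influence(self):
        def seed_mass(w):
            graph = graph_from_edges(
                3, [(0, 2, w), (1, 2, 1.0)], {0: (0,), 1: (1,)}, 2
            )
            return fixed_point_oracle(graph).values[2][0]

        masses = [seed_mass(w) for w in (0.5, 1.0, 2.0, 4.0)]
        assert all(a <= b + 1e-12 for a, b in zip(masses, masses[1:]))


class TestRankLP:
    def test_identical_label_ranks_first(self):
        src = graph_from_edges(
            3, [(0, 2, 1.0), (1, 2, 1.0)], {0: (0,), 1: (1,)}, 2, "zh"
        )
        tgt = graph_from_edges(
            3, [(0, 2, 1.0), (1, 2, 1.0)], {0: (0,), 1: (1,)}, 2, "en"
        )
        sl = propagate(src, init_labels(src), 10)
        tl = propagate(tgt, init_labels(tgt), 10)
        ranking = rank_lp(sl, tl, TermType("zh", ("v2",)))
        assert ranking.candidates[0][0] == TermType("en", ("v2",))
        assert ranking.candidates[0][1] == pytest.approx(1.0)

    def test_seed_candidates_score_by_label_entry(self):
        src = graph_from_edges(
            3, [(0, 2, 1.0), (1, 2, 3.0)], {0: (0,), 1: (1,)}, 2, "zh"
        )
        tgt = graph_from_edges(2, [], {0: (0,), 1: (1,)}, 2, "en")
        sl = fixed_point_oracle(src)
        tl = init_labels(tgt)
        ranking = rank_lp(sl, tl, TermType("zh", ("v2",)))
        q = sl.values[2]
        expected = {
            TermType("en", ("v0",)): q[0] / np.linalg.norm(q),
            TermType("en", ("v1",)): q[1] / np.linalg.norm(q),
        }
        for cand, score in ranking.candidates:
            assert score == pytest.approx(expected[cand])

    def test_matches_brute_force_cosine_sort(self):
        rng = np.random.default_rng(9)
        src = random_connected_graph(rng, 10, 3, 3)
        tgt = random_connected_graph(rng, 10, 3, 3)
        sl = propagate(src, init_labels(src), 10)
        tl = propagate(tgt, init_labels(tgt), 10)
        test = src.vertices[5]
        ranking = rank_lp(sl, tl, test)
        q = sl.values[5]
        brute = []
        for i, term in enumerate(tgt.vertices):
            v = tl.values[i]
            brute.append((term, float(q @ v / np.linalg.norm(q) / np.linalg.norm(v))))
        brute.sort(key=lambda kv: (-kv[1], kv[0].words))
        assert [t for t, _ in ranking.candidates] == [t for t, _ in brute]
        for (_, s1), (_, s2) in zip(ranking.candidates, brute):
            assert s1 == pytest.approx(s2)

    def test_exclude_seeds_policy(self):
        src = graph_from_edges(2, [(0, 1, 1.0)], {0: (0,)}, 1, "zh")
        tgt = graph_from_edges(2, [(0, 1, 1.0)], {0: (0,)}, 1, "en")
        sl = propagate(src, init_labels(src), 5)
        tl = propagate(tgt, init_labels(tgt), 5)
        ranking = rank_lp(sl, tl, TermType("zh", ("v1",)), include_seeds=False)
        assert [t for t, _ in ranking.candidates] == [TermType("en", ("v1",))]

    def test_missing_test_term(self):
        src = graph_from_edges(2, [(0, 1, 1.0)], {0: (0,)}, 1, "zh")
        sl = init_labels(src)
        with pytest.raises(KeyError, match="absent|not in source"):
            rank_lp(sl, sl, TermType("zh", ("nope",)))
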