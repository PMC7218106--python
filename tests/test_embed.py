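import numpy as np
import pytest

from n2vhc import _kernels
from n2vhc.embed import (EmbedParams, WalkParams, alpha, embed_network,
                         simulate_walks, train_skipgram,
                         transition_distribution, Embedding)
from n2vhc.graph import Network


@pytest.mark.parametrize("p,q,d,expected", [
    (4.0, 0.25, 0, 0.25),
    (4.0, 0.25, 1, 1.0),
    (4.0, 0.25, 2, 4.0),
    (1.0, 1.0, 0, 1.0),
    (1.0, 1.0, 1, 1.0),
    (1.0, 1.0, 2, 1.0),
])
def test_alpha_cases(p, q, d, expected):
    assert alpha(p, q, d) == pytest.approx(expected)


def test_alpha_rejects_bad_distance():
    with pytest.raises(ValueError):
        alpha(1.0, 1.0, 3)


def test_transition_distribution_weighted_biased():
    # v's neighbors: x1 (w=2, adjacent to t), x2 (w=1, two steps from t)
    net = Network()
    net.add_edge("t", "v")
    net.add_edge("v", "x1", weight=2.0)
    net.add_edge("t", "x1")
    net.add_edge("v", "x2", weight=1.0)
    dist = transition_distribution(net, "t", "v", WalkParams(q=0.5))
    # pi = {t: 1*1/p, x1: 1*2, x2: 2*1}; with p=1: {1, 2, 2}
    assert dist["x1"] == pytest.approx(0.4)
    assert dist["x2"] == pytest.approx(0.4)
    assert dist["t"] == pytest.approx(0.2)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


def test_transition_distribution_corner_cases(triangle):
    single = Network()
    single.add_edge("a", "b")
    assert transition_distribution(single, None, "b", WalkParams()) == {"a": 1.0}
    # sink signals empty distribution
    sink = Network(directed=True)
    sink.add_edge("a", "b")
    assert transition_distribution(sink, None, "b", WalkParams()) == {}
    # uniform over neighbors when unweighted and p=q=1
    d = transition_distribution(triangle, "b", "a", WalkParams())
    assert d["b"] == pytest.approx(0.5) and d["c"] == pytest.approx(0.5)


def test_walks_respect_edges_and_truncate(path_graph):
    corpus = simulate_walks(path_graph, WalkParams(walk_length=3,
                                                   walks_per_node=2, seed=1))
    edge_set = {("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")}
    walks = corpus.to_lists()
    assert len(walks) == 2 * 3
    for w in walks:
        for u, v in zip(w, w[1:]):
            assert (u, v) in edge_set
    iso = Network()
    iso.add_edge("a", "b")
    iso.add_node("z")
    walks = simulate_walks(iso, WalkParams(walk_length=5, walks_per_node=1,
                                           seed=0)).to_lists()
    assert [w for w in walks if w[0] == "z"] == [["z"]]


def test_empirical_frequencies_match_exact_distribution():
    """Monte-Carlo walk steps agree with the exact biased rule within 3 sigma."""
    net = Network()
    net.add_edge("t", "v")
    net.add_edge("v", "x1", weight=2.0)
    net.add_edge("t", "x1")
    net.add_edge("v", "x2", weight=3.0)
    net.add_edge("v", "x3", weight=1.0)
    net.add_edge("x3", "t")
    params = WalkParams(p=2.0, q=0.5, walk_length=3, walks_per_node=4000,
                        seed=3)
    corpus = simulate_walks(net, params)
    exact = transition_distribution(net, "t", "v", params)
    counts = {x: 0 for x in exact}
    total = 0
    for w in corpus.to_lists():
        for i in range(len(w) - 2):
            if w[i] == "t" and w[i + 1] == "v":
                counts[w[i + 2]] += 1
                total += 1
    assert total > 1000
    for x, pr in exact.items():
        sigma = np.sqrt(pr * (1 - pr) * total)
        assert abs(counts[x] - pr * total) < 3 * sigma + 1e-9


def test_large_p_suppresses_backtracking(triangle):
    corpus = simulate_walks(triangle, WalkParams(p=1e6, q=1.0, walk_length=40,
                                                 walks_per_node=30, seed=5))
    backtracks = steps = 0
    for w in corpus.to_lists():
        for i in range(len(w) - 2):
            steps += 1
            if w[i + 2] == w[i]:
                backtracks += 1
    assert steps > 1000
    assert backtracks / steps < 1e-3


def test_embedding_shape_and_determinism(triangle):
    wp = WalkParams(walk_length=10, walks_per_node=5, seed=9)
    ep = EmbedParams(dimension=16, epochs=2, seed=9)
    e1 = embed_network(triangle, wp, ep)
    e2 = embed_network(triangle, wp, ep)
    assert e1.matrix.shape == (3, 16)
    assert np.array_equal(e1.matrix, e2.matrix)
    assert np.all(np.isfinite(e1.matrix))


def test_two_cliques_homophily():
    """Within-clique cosine similarity exceeds between-clique similarity."""
    net = Network()
    for base in ("a", "b"):
        for i in range(10):
            for j in range(i + 1, 10):
                net.add_edge(f"{base}{i}", f"{base}{j}")
    net.add_edge("a0", "b0")  # single bridge keeps the graph connected
    emb = embed_network(net, WalkParams(walk_length=20, walks_per_node=10,
                                        seed=4),
                        EmbedParams(dimension=32, epochs=3, seed=4))
    X = emb.matrix / np.linalg.norm(emb.matrix, axis=1, keepdims=True)
    idx_a = [i for i, n in enumerate(emb.ids) if n.startswith("a")]
    idx_b = [i for i, n in enumerate(emb.ids) if n.startswith("b")]
    cos = X @ X.T
    within = (cos[np.ix_(idx_a, idx_a)].mean()
              + cos[np.ix_(idx_b, idx_b)].mean()) / 2
    between = cos[np.ix_(idx_a, idx_b)].mean()
    assert within > between


def test_training_loss_decreases():
    net = Network()
    for i in range(12):
        net.add_edge(f"n{i:02d}", f"n{(i + 1) % 12:02d}")
    wp = WalkParams(walk_length=30, walks_per_node=10, seed=2)
    corpus = simulate_walks(net, wp)
    from n2vhc.embed import _negative_table
    table = _negative_table(corpus.walks, len(corpus.ids))
    losses = []
    for epochs in (1, 3, 6):
        emb = train_skipgram(corpus, EmbedParams(dimension=16, window=2,
                                                 epochs=epochs, seed=2))
        loss = _kernels.sgns_loss_kernel(
            corpus.walks, emb.matrix.astype(np.float32),
            emb.context_matrix.astype(np.float32), 2, 5, table,
            _kernels.seed_state(0))
        losses.append(loss)
    assert losses[-1] < losses[0]


def test_word2vec_text_round_trip(tmp_path):
    emb = Embedding(["a", "b"], np.array([[1.0, 2.0], [3.0, 4.0]]))
    path = tmp_path / "emb.txt"
    emb.save(path)
    header = path.read_text().splitlines()[0]
    assert header == "2 2"
    back = Embedding.load(path)
    assert back.ids == emb.ids
    assert np.allclose(back.matrix, emb.matrix)
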