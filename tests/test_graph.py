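"""K-NN nucleus graph construction and degree-scaled aggregation."""

import numpy as np
import pytest

from nucmil.graph import (
    NucleiGNN,
    NucleiGraph,
    aggregate,
    build_knn_graph,
    degree_scalers,
    directed_edges,
    fit_degree_normalizer,
)
from nucmil.nn import Adam, Tensor
from nucmil.losses import apl_loss, one_hot


def brute_knn_edges(points, k, dmin):
    """All-pairs oracle: union-symmetrized K-NN within dmin."""
    n = len(points)
    selected = set()
    for i in range(n):
        cands = []
        for j in range(n):
            if j == i:
                continue
            d = float(np.hypot(*(points[i] - points[j])))
            if d < dmin:
                cands.append((d, j))
        cands.sort()
        for _, j in cands[:k]:
            selected.add((i, j))
    return {(min(i, j), max(i, j)) for i, j in selected if (i, j) in selected or True}


def edge_positions(graph):
    return {
        frozenset([tuple(graph.positions[i]), tuple(graph.positions[j])])
        for i, j in graph.edges
    }


def test_three_collinear_points_fully_connected():
    g = build_knn_graph([(0, 0), (10, 0), (20, 0)], k=5, dmin=50)
    assert len(g.edges) == 3


def test_far_points_not_connected():
    g = build_knn_graph([(0, 0), (60, 0)], k=5, dmin=50)
    assert len(g.edges) == 0
    assert list(g.degrees) == [0, 0]


def test_knn_graph_matches_brute_force_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(5, 120))
        pts = rng.uniform(0, 300, size=(n, 2))
        g = build_knn_graph(pts, k=5, dmin=50)
        oracle = set()
        sel = np.zeros((n, n), dtype=bool)
        order = np.lexsort((np.arange(n), pts[:, 1], pts[:, 0]))
        spts = pts[order]
        for i in range(n):
            cands = sorted(
                (float(np.hypot(*(spts[i] - spts[j]))), j)
                for j in range(n)
                if j != i and float(np.hypot(*(spts[i] - spts[j]))) < 50
            )
            for _, j in cands[:5]:
                sel[i, j] = True
        adj = sel | sel.T
        oracle = {(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]}
        assert {(int(i), int(j)) for i, j in g.edges} == oracle


def test_out_neighborhood_bounded_by_k_within_dmin(rng):
    pts = rng.uniform(0, 200, size=(100, 2))
    g = build_knn_graph(pts, k=5, dmin=50)
    # before symmetrization each node selects at most k targets within dmin;
    # after union-symmetrization every edge must still be shorter than dmin
    for i, j in g.edges:
        assert np.hypot(*(g.positions[i] - g.positions[j])) < 50


def test_graph_is_permutation_invariant_as_a_point_set(rng):
    pts = rng.uniform(0, 100, size=(30, 2))
    perm = rng.permutation(30)
    g1 = build_knn_graph(pts, k=3, dmin=40)
    g2 = build_knn_graph(pts[perm], k=3, dmin=40)
    assert np.array_equal(g1.positions, g2.positions)
    assert np.array_equal(g1.edges, g2.edges)


def test_degree_matrix_consistent_with_edges(rng):
    pts = rng.uniform(0, 100, size=(40, 2))
    g = build_knn_graph(pts, k=4, dmin=30)
    deg = np.zeros(40, dtype=int)
    for i, j in g.edges:
        assert i < j
        deg[i] += 1
        deg[j] += 1
    assert np.array_equal(deg, g.degrees)


# ------------------------------------------------------------ degree scaler

def test_uniform_degree_graph_gives_unit_scaler():
    g = build_knn_graph([(0, 0), (10, 0), (0, 10), (10, 10)], k=5, dmin=50)
    assert np.all(g.degrees == 3)
    delta = fit_degree_normalizer([g])
    assert delta == pytest.approx(np.log(4.0))
    s = degree_scalers(g.degrees, delta)
    assert np.allclose(s[:, 1], 1.0)


def test_degree_normalizer_is_mean_log_degree_plus_one():
    g1 = NucleiGraph(np.zeros((3, 2)), np.zeros((3, 16)), np.array([[0, 1]]), order=None)
    g2 = NucleiGraph(np.zeros((2, 2)), np.zeros((2, 16)), np.array([[0, 1]]), order=None)
    # degrees: [1, 1, 0] and [1, 1]
    expected = np.mean(np.log(np.array([2, 2, 1, 2, 2], dtype=float)))
    assert fit_degree_normalizer([g1, g2]) == pytest.approx(expected)


def test_scaler_inverse_property(rng):
    degrees = rng.integers(1, 9, size=50)
    s = degree_scalers(degrees, delta=1.3)
    assert np.allclose(s[:, 1] * s[:, 2], 1.0)
    assert np.allclose(s[:, 0], 1.0)


def test_empty_training_graphs_rejected():
    with pytest.raises(ValueError):
        fit_degree_normalizer([])


# ------------------------------------------------------------- aggregation

def star_graph(n_leaves, feat_dim=2, rng=None):
    pts = np.vstack([[0, 0], [[10 * (i + 1), 0] for i in range(n_leaves)]])
    feats = (np.arange((n_leaves + 1) * feat_dim, dtype=float)).reshape(-1, feat_dim)
    edges = np.array([[0, i + 1] for i in range(n_leaves)])
    return NucleiGraph(pts, feats, edges, order=None)


def test_identical_neighbor_messages_aggregate_to_expected_stats():
    g = star_graph(3)
    src, dst = directed_edges(g)
    msgs = np.where(dst[:, None] == 0, 2.5, 7.0)  # center receives 2.5s
    out = aggregate(g, Tensor(np.broadcast_to(msgs, (len(dst), 1)).copy()), delta=1.0).data
    # identity-scaled blocks: [mu, sigma, max, min]
    assert out[0, 0] == pytest.approx(2.5)       # mean
    assert out[0, 1] == pytest.approx(0.0, abs=1e-5)  # std of identical values
    assert out[0, 2] == pytest.approx(2.5) and out[0, 3] == pytest.approx(2.5)


def test_star_graph_matches_per_node_brute_force(rng):
    g = star_graph(4, feat_dim=3)
    src, dst = directed_edges(g)
    msgs = rng.normal(size=(len(dst), 3))
    out = aggregate(g, Tensor(msgs.copy()), delta=0.9).data
    scalers = degree_scalers(g.degrees, 0.9)
    for v in range(g.n_nodes):
        incoming = msgs[dst == v]
        if len(incoming) == 0:
            assert np.allclose(out[v], 0.0)
            continue
        stats = [incoming.mean(0), incoming.std(0), incoming.max(0), incoming.min(0)]
        expected = np.concatenate([scalers[v, a] * s for a in range(3) for s in stats])
        assert np.allclose(out[v], expected, atol=1e-5)


def test_identity_scaler_block_equals_plain_statistics(rng):
    g = star_graph(4, feat_dim=2)
    src, dst = directed_edges(g)
    msgs = rng.normal(size=(len(dst), 2))
    out = aggregate(g, Tensor(msgs.copy()), delta=2.0).data
    plain = aggregate(g, Tensor(msgs.copy()), delta=1.0).data
    # alpha = 0 block (first 4*f columns) is independent of delta
    assert np.allclose(out[:, : 4 * 2], plain[:, : 4 * 2])


# ----------------------------------------------------------------- network

def test_gnn_logits_invariant_to_node_permutation(rng):
    pts = rng.uniform(0, 80, size=(15, 2))
    feats = rng.normal(size=(15, 16))
    perm = rng.permutation(15)
    g1 = build_knn_graph(pts, feats, k=4, dmin=40)
    g2 = build_knn_graph(pts[perm], feats[perm], k=4, dmin=40)
    gnn = NucleiGNN(rng=np.random.default_rng(0))
    _, logits1, _ = gnn(g1, delta=1.0)
    _, logits2, _ = gnn(g2, delta=1.0)
    assert np.array_equal(logits1.data, logits2.data)  # bit-exact


def test_isomorphic_translated_graphs_give_identical_logits(rng):
    pts = rng.uniform(0, 80, size=(10, 2))
    feats = rng.normal(size=(10, 16))
    g1 = build_knn_graph(pts, feats, k=3, dmin=40)
    g2 = build_knn_graph(pts + 1000.0, feats, k=3, dmin=40)
    gnn = NucleiGNN(rng=np.random.default_rng(1))
    assert np.allclose(gnn(g1, 1.0)[1].data, gnn(g2, 1.0)[1].data)


def test_empty_graph_uses_flagged_null_embedding():
    g = NucleiGraph(np.zeros((0, 2)), np.zeros((0, 16)), np.zeros((0, 2), dtype=int), order=None)
    gnn = NucleiGNN(rng=np.random.default_rng(2))
    _, logits, empty = gnn(g, delta=1.0)
    assert empty and logits.shape == (1, 2)


def test_gradient_flows_and_loss_decreases_on_toy_fit(rng):
    feats0 = rng.normal(loc=-1.0, size=(8, 16))
    feats1 = rng.normal(loc=+1.0, size=(8, 16))
    pts = rng.uniform(0, 50, size=(8, 2))
    g0 = build_knn_graph(pts, feats0, k=3, dmin=60)
    g1 = build_knn_graph(pts, feats1, k=3, dmin=60)
    gnn = NucleiGNN(rng=np.random.default_rng(3))
    delta = fit_degree_normalizer([g0, g1])
    opt = Adam(gnn.parameters(), lr=1e-2)

    def total():
        loss = Tensor(0.0)
        for g, lbl in ((g0, 0), (g1, 1)):
            _, logits, _ = gnn(g, delta)
            p = logits.reshape(-1).softmax(axis=0)
            loss = loss + apl_loss(p, one_hot(lbl))
        return loss

    first = total().item()
    for _ in range(10):
        loss = total()
        opt.zero_grad()
        loss.backward()
        assert any(p.grad is not None and np.any(p.grad != 0) for p in gnn.parameters())
        opt.step()
    assert total().item() < first


def test_graph_json_roundtrip(rng):
    pts = rng.uniform(0, 60, size=(6, 2))
    feats = rng.normal(size=(6, 16))
    g = build_knn_graph(pts, feats, k=2, dmin=50)
    d = g.to_json_dict()
    assert len(d["nodes"]) == 6
    assert all(len(n["features"]) == 16 for n in d["nodes"])
    assert d["k"] == 2 and d["dmin"] == 50
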