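"""K-NN nucleus topology and degree-scaled multi-aggregator message passing.

Nuclei within one selected patch become graph nodes carrying the
16-dimensional handcrafted feature vector.  An undirected edge joins two
nuclei when either is among the other's K nearest neighbors (Euclidean
distance) AND their distance is below ``dmin`` — nearby nuclei interact,
distant ones do not.  Defaults K = 5 and dmin = 50 px.

Message passing follows the principal-neighbourhood-aggregation recipe:
per-edge messages are reduced per node by four statistics (mean, std,
max, min), each modulated by three degree scalers
``(log(d + 1) / delta)^alpha`` for alpha in {0, +1, -1}, where ``delta``
is the mean of log(degree + 1) over training nodes.  The 12 resulting
blocks are concatenated and fed with the node state to an update MLP;
global mean pooling and a linear head produce per-graph class logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Linear, Module, Parameter, Tensor, concat, segment_extreme

__all__ = [
    "NucleiGraph",
    "build_knn_graph",
    "fit_degree_normalizer",
    "degree_scalers",
    "aggregate",
    "NucleiGNN",
]


@dataclass
class NucleiGraph:
    """Undirected nucleus graph of one patch.

    Nodes are stored in canonical order (lexicographic by centroid, ties
    by input index) so that every downstream computation is invariant to
    the order nuclei were supplied in — bit-exactly, not just up to
    floating-point reordering.
    """

    positions: np.ndarray                 # r x 2 (x, y) px
    features: np.ndarray                  # r x 16 handcrafted vectors
    edges: np.ndarray                     # e x 2, i < j, unique
    k: int = 5
    dmin: float = 50.0
    order: np.ndarray = field(default=None)  # canonical -> input index map

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.intp)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def neighbors(self) -> list[np.ndarray]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [np.array(sorted(a), dtype=np.intp) for a in adj]

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {"x": float(x), "y": float(y), "features": f.tolist()}
                for (x, y), f in zip(self.positions, self.features)
            ],
            "edges": [[int(i), int(j)] for i, j in self.edges],
            "k": self.k,
            "dmin": self.dmin,
        }


def build_knn_graph(
    centroids,
    features=None,
    k: int = 5,
    dmin: float = 50.0,
    symmetrize: str = "union",
) -> NucleiGraph:
    """Build the K-NN-within-dmin nucleus graph.

    Each node selects its ``k`` nearest neighbors (ties at the k-th
    distance broken by lower index) that are strictly closer than
    ``dmin``; the directed relation is symmetrized by union (default) or
    intersection.  Isolated nodes are allowed.
    """
    if k < 1 or dmin <= 0:
        raise ValueError("k must be >= 1 and dmin > 0")
    if symmetrize not in ("union", "intersection"):
        raise ValueError("symmetrize must be 'union' or 'intersection'")
    pos = np.asarray(centroids, dtype=np.float64).reshape(-1, 2)
    if len(pos) == 0:
        raise ValueError("need at least one centroid")
    feats = (
        np.zeros((len(pos), 0)) if features is None else np.asarray(features, dtype=np.float64)
    )
    order = np.lexsort((np.arange(len(pos)), pos[:, 1], pos[:, 0]))
    pos = pos[order]
    feats = feats[order]
    n = len(pos)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    selected = np.zeros((n, n), dtype=bool)
    for i in range(n):
        candidates = [(dist[i, j], j) for j in range(n) if j != i and dist[i, j] < dmin]
        candidates.sort()
        for _, j in candidates[:k]:
            selected[i, j] = True
    adj = (selected | selected.T) if symmetrize == "union" else (selected & selected.T)
    ii, jj = np.nonzero(np.triu(adj, 1))
    edges = np.column_stack([ii, jj]).astype(np.intp)
    return NucleiGraph(positions=pos, features=feats, edges=edges, k=k, dmin=dmin, order=order)


def fit_degree_normalizer(training_graphs: list[NucleiGraph]) -> float:
    """delta = mean of log(degree + 1) over all training nodes."""
    logs = [np.log(g.degrees + 1.0) for g in training_graphs if g.n_nodes > 0]
    if not logs:
        raise ValueError("no nodes in training graphs")
    return float(np.concatenate(logs).mean())


def degree_scalers(degrees: np.ndarray, delta: float) -> np.ndarray:
    """Per-node scalers ``(log(d+1)/delta)^alpha`` for alpha = 0, +1, -1.

    Returns an (r, 3) array; isolated nodes (d = 0) get zeros in the
    amplify and attenuate columns — their aggregation is zero anyway.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    logd = np.log(np.asarray(degrees, dtype=np.float64) + 1.0)
    s1 = logd / delta
    with np.errstate(divide="ignore"):
        s_neg = np.where(s1 > 0, 1.0 / np.where(s1 > 0, s1, 1.0), 0.0)
    return np.column_stack([np.ones_like(s1), s1, s_neg])


def aggregate(graph: NucleiGraph, messages: Tensor, delta: float) -> Tensor:
    """Degree-scaled multi-statistic neighborhood aggregation.

    ``messages`` holds one row per directed edge (source -> target,
    both directions of every undirected edge).  For each node the mean,
    std, max and min of incoming messages are computed and each
    multiplied by the three degree scalers, giving a fixed block order
    [id*mu, id*sigma, id*max, id*min, amp*mu, ..., att*min] of width
    12 * f.  Nodes without neighbors aggregate to zeros.
    """
    n = graph.n_nodes
    f = messages.shape[1]
    src, dst = directed_edges(graph)
    if len(dst) == 0:
        return Tensor(np.zeros((n, 12 * f)))
    deg = np.bincount(dst, minlength=n).astype(np.float64)
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1.0), 0.0)
    # incidence matrix averaging incoming messages per node
    mean_mat = np.zeros((n, len(dst)))
    mean_mat[dst, np.arange(len(dst))] = inv[dst]
    mean_op = Tensor(mean_mat)
    mu = mean_op @ messages
    ex2 = mean_op @ (messages * messages)
    var = (ex2 - mu * mu).clip_min(0.0)
    sigma = (var + 1e-12) ** 0.5
    mx = segment_extreme(messages, dst, n, "max")
    mn = segment_extreme(messages, dst, n, "min")
    scalers = degree_scalers(graph.degrees, delta)
    blocks = []
    for a in range(3):
        col = Tensor(scalers[:, a : a + 1])
        for stat in (mu, sigma, mx, mn):
            blocks.append(stat * col)
    return concat(blocks, axis=1)


def directed_edges(graph: NucleiGraph) -> tuple[np.ndarray, np.ndarray]:
    """Both directions of every undirected edge as (src, dst) arrays."""
    if len(graph.edges) == 0:
        e = np.zeros(0, dtype=np.intp)
        return e, e
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    return np.concatenate([i, j]), np.concatenate([j, i])


class NucleiGNN(Module):
    """Two-layer message-passing network with a linear class head.

    Each layer computes per-edge messages M([h_src, h_dst]), aggregates
    them with :func:`aggregate`, and updates node states with
    U([h, agg]) followed by ReLU.  Graph logits come from global mean
    pooling; an empty graph falls back to a learned null embedding.
    """

    def __init__(
        self,
        in_dim: int = 16,
        hidden: int = 64,
        msg_dim: int = 32,
        n_layers: int = 2,
        n_classes: int = 2,
        rng: np.random.Generator | None = None,
    ):
        rng = np.random.default_rng() if rng is None else rng
        self.n_layers = n_layers
        dims = [in_dim] + [hidden] * n_layers
        self.msg = [Linear(2 * dims[t], msg_dim, rng) for t in range(n_layers)]
        self.upd = [Linear(dims[t] + 12 * msg_dim, hidden, rng) for t in range(n_layers)]
        self.head = Linear(hidden, n_classes, rng)
        self.null_embedding = Parameter(np.zeros(hidden))

    def forward(self, graph: NucleiGraph, delta: float):
        """Returns (node_embeddings, graph_logits, empty_flag)."""
        if graph.n_nodes == 0:
            pooled = self.null_embedding.reshape(1, -1)
            return pooled, self.head(pooled), True
        h = Tensor(graph.features)
        src, dst = directed_edges(graph)
        for t in range(self.n_layers):
            if len(src) > 0:
                pair = concat([h.rows(src), h.rows(dst)], axis=1)
                msg = self.msg[t](pair).relu()
            else:
                msg = Tensor(np.zeros((0, self.msg[t].weight.shape[1])))
            agg = aggregate(graph, msg, delta)
            h = self.upd[t](concat([h, agg], axis=1)).relu()
        pooled = h.mean(axis=0, keepdims=True)
        return h, self.head(pooled), False

    __call__ = forward
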