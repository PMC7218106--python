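"""Node representation learning by biased second-order random walks plus
skip-gram with negative sampling.

The walk process is the classic two-parameter biased walk: standing at
``v`` having arrived from ``t``, the unnormalized probability of moving
to a neighbor ``x`` is ``alpha_pq(t, x) * w_vx`` where ``alpha`` depends
on the graph distance ``d_tx`` between ``t`` and ``x``::

    alpha = 1/p  if d_tx = 0   (return to t)
            1    if d_tx = 1   (stay near t)
            1/q  if d_tx = 2   (move away)

The skip-gram objective over the sampled walk neighborhoods is
maximized with negative sampling (k draws from the unigram^0.75 noise
distribution per positive pair), the standard tractable surrogate for
the full softmax partition function.  Training is single-threaded and
deterministic for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _kernels
from .graph import Network

logger = logging.getLogger(__name__)

__all__ = [
    "WalkParams",
    "EmbedParams",
    "WalkCorpus",
    "Embedding",
    "alpha",
    "transition_distribution",
    "simulate_walks",
    "train_skipgram",
    "embed_network",
]


@dataclass(frozen=True)
class WalkParams:
    """Biased-walk hyperparameters.

    ``p`` (return) and ``q`` (in-out) bias the walk between breadth- and
    depth-first exploration; ``p = q = 1`` degenerates to a first-order
    weight-proportional walk.
    """

    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")


@dataclass(frozen=True)
class EmbedParams:
    dimension: int = 128
    window: int = 10
    epochs: int = 5
    negative_samples: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.dimension < 1 or self.window < 1:
            raise ValueError("dimension and window must be >= 1")
        if self.epochs < 1 or self.negative_samples < 1:
            raise ValueError("epochs and negative_samples must be >= 1")


class _CSR:
    """Compact adjacency with per-node sorted neighbor ids."""

    def __init__(self, net: Network):
        self.ids: list[str] = sorted(net.nodes())
        self.index = {n: i for i, n in enumerate(self.ids)}
        n = len(self.ids)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for u, v, w in net.edges():
            iu, iv = self.index[u], self.index[v]
            adj[iu].append((iv, w))
            if not net.directed:
                adj[iv].append((iu, w))
        indptr = np.zeros(n + 1, dtype=np.int64)
        indices: list[int] = []
        weights: list[float] = []
        for i, nbrs in enumerate(adj):
            nbrs.sort()
            indptr[i + 1] = indptr[i] + len(nbrs)
            indices.extend(x for x, _ in nbrs)
            weights.extend(w for _, w in nbrs)
        self.indptr = indptr
        self.indices = np.asarray(indices, dtype=np.int64)
        self.weights = np.asarray(weights, dtype=np.float64)
        self.cumw = np.cumsum(self.weights)
        # symmetrized adjacency for the d_tx test on directed graphs
        if net.directed:
            uadj: list[set[int]] = [set() for _ in range(n)]
            for u, v, _w in net.edges():
                iu, iv = self.index[u], self.index[v]
                uadj[iu].add(iv)
                uadj[iv].add(iu)
            und_indptr = np.zeros(n + 1, dtype=np.int64)
            und_indices: list[int] = []
            for i, s in enumerate(uadj):
                srt = sorted(s)
                und_indptr[i + 1] = und_indptr[i] + len(srt)
                und_indices.extend(srt)
            self.und_indptr = und_indptr
            self.und_indices = np.asarray(und_indices, dtype=np.int64)
        else:
            self.und_indptr = self.indptr
            self.und_indices = self.indices


@dataclass
class WalkCorpus:
    """Sampled walk neighborhoods: int32 rows over node indices, -1-padded."""

    walks: np.ndarray
    ids: list[str]

    def __len__(self) -> int:
        return self.walks.shape[0]

    def to_lists(self) -> list[list[str]]:
        out = []
        for row in self.walks:
            out.append([self.ids[i] for i in row if i >= 0])
        return out


class Embedding:
    """Per-node d-dimensional feature vectors (the learned f(u))."""

    def __init__(self, ids: list[str], matrix: np.ndarray):
        if len(ids) != matrix.shape[0]:
            raise ValueError("one vector per node required")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("non-finite embedding entries")
        self.ids = list(ids)
        self.index = {n: i for i, n in enumerate(self.ids)}
        self.matrix = np.asarray(matrix, dtype=np.float64)

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def vector(self, node: str) -> np.ndarray:
        return self.matrix[self.index[node]]

    def subset(self, nodes: list[str]) -> "Embedding":
        rows = [self.index[n] for n in nodes]
        return Embedding(list(nodes), self.matrix[rows])

    def save(self, path: str | Path) -> None:
        """word2vec text format: header "n d", then "node v1 ... vd"."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)} {self.dimension}\n")
            for n, row in zip(self.ids, self.matrix):
                fh.write(n + " " + " ".join(f"{x:.8g}" for x in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Embedding":
        with open(path) as fh:
            n, d = map(int, fh.readline().split())
            ids, rows = [], []
            for line in fh:
                parts = line.split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        mat = np.asarray(rows, dtype=np.float64)
        if mat.shape != (n, d):
            raise ValueError(f"{path}: header {(n, d)} does not match body {mat.shape}")
        return cls(ids, mat)


def alpha(p: float, q: float, d_tx: int) -> float:
    """Search bias alpha_pq as a function of the t-to-x distance."""
    if d_tx == 0:
        return 1.0 / p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / q
    raise ValueError(f"d_tx must be 0, 1 or 2, got {d_tx}")


def transition_distribution(net: Network, t: str | None, v: str,
                            params: WalkParams) -> dict[str, float]:
    """Exact next-step distribution over out-neighbors of ``v``.

    ``t`` is the previous node; ``None`` means the walk's first step,
    which samples proportionally to edge weight (alpha = 1).  An empty
    dict signals a sink node (walk truncates).
    """
    g = net.g
    nbrs = {x: d.get("weight", 1.0) for x, d in g[v].items()}
    if not nbrs:
        return {}
    if t is not None and not g.has_edge(t, v):
        raise ValueError(f"({t!r}, {v!r}) is not an edge")
    pi: dict[str, float] = {}
    for x, w in nbrs.items():
        if t is None:
            a = 1.0
        elif x == t:
            a = alpha(params.p, params.q, 0)
        elif g.has_edge(t, x) or (net.directed and g.has_edge(x, t)):
            a = alpha(params.p, params.q, 1)
        else:
            a = alpha(params.p, params.q, 2)
        pi[x] = a * w
    z = sum(pi.values())
    return {x: val / z for x, val in pi.items()}


def simulate_walks(net: Network, params: WalkParams) -> WalkCorpus:
    """``walks_per_node`` truncated walks from every node, shuffled start
    order per pass, each step drawn from the biased transition rule."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    csr = _CSR(net)
    state = _kernels.seed_state(params.seed)
    walks = _kernels.simulate_walks_kernel(
        csr.indptr, csr.indices, csr.weights, csr.cumw,
        csr.und_indptr, csr.und_indices,
        params.walks_per_node, params.walk_length,
        float(params.p), float(params.q), state)
    return WalkCorpus(walks=walks, ids=csr.ids)


def _negative_table(walks: np.ndarray, n_nodes: int,
                    table_size: int = 1 << 18) -> np.ndarray:
    """Unigram^0.75 noise table used for negative draws."""
    flat = walks[walks >= 0]
    counts = np.bincount(flat, minlength=n_nodes).astype(np.float64)
    counts = np.maximum(counts, 1.0) ** 0.75
    cum = np.cumsum(counts)
    cum /= cum[-1]
    ticks = (np.arange(table_size) + 0.5) / table_size
    return np.searchsorted(cum, ticks).astype(np.int64)


def train_skipgram(corpus: WalkCorpus, params: EmbedParams) -> Embedding:
    """Fit skip-gram embeddings to the walk corpus by negative sampling."""
    if len(corpus) == 0:
        raise ValueError("empty walk corpus")
    n = len(corpus.ids)
    visited = np.zeros(n, dtype=bool)
    flat = corpus.walks[corpus.walks >= 0]
    visited[flat] = True
    if not visited.all():
        logger.warning("%d nodes never visited by any walk; their vectors "
                       "stay at random initialization", int((~visited).sum()))
    table = _negative_table(corpus.walks, n)
    state = _kernels.seed_state(params.seed + 0x5EED)
    syn0, syn1 = _kernels.train_sgns_kernel(
        corpus.walks, n, params.dimension, params.window, params.epochs,
        params.negative_samples, float(params.learning_rate), table, state)
    emb = Embedding(corpus.ids, syn0.astype(np.float64))
    emb.context_matrix = syn1.astype(np.float64)  # output-side vectors
    return emb


def embed_network(net: Network, walk_params: WalkParams | None = None,
                  embed_params: EmbedParams | None = None) -> Embedding:
    """simulate_walks followed by train_skipgram."""
    walk_params = walk_params or WalkParams()
    embed_params = embed_params or EmbedParams()
    corpus = simulate_walks(net, walk_params)
    return train_skipgram(corpus, embed_params)
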