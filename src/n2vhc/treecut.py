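"""Average-linkage hierarchical clustering of embedding vectors and a
"Dynamic Hybrid"-style tree cut with outlier re-assignment.

Stage 1 walks the dendrogram bottom-up and emits every branch that
simultaneously satisfies four conditions:

1. size ``N > N0`` (the minimum module size),
2. branch height below the maximum tree height ``h_max``,
3. core scatter ``dbar < d_max`` — the mean pairwise dissimilarity of
   the ``Nc`` lowest-merging leaves of the branch (the branch *core*),
4. cluster gap ``g = height - dbar > g_min``.

Leaves not covered by any qualifying branch are *outliers* (label 0);
stage 2 assigns each outlier to the cluster with the smallest average
dissimilarity to its members.  ``deepSplit`` presets trade conservative
for aggressive splitting by scaling ``d_max``/``g_min`` along the
dendrogram height range, and additionally decide whether nested
qualifying branches resolve to the higher (deepSplit <= 2) or the more
specific lower branch (deepSplit >= 3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .embed import Embedding

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "CutParams",
    "ModulePartition",
    "build_dendrogram",
    "core_size",
    "cluster_stats",
    "dynamic_hybrid_cut",
    "assign_outliers",
    "cut_tree",
]


class Dendrogram:
    """Binary merge tree over ``n`` leaves (scipy linkage encoding).

    Leaves are 0..n-1; internal nodes n..2n-2 correspond to linkage
    rows in merge order.  ``ids[i]`` is the node id of leaf ``i``.
    """

    def __init__(self, Z: np.ndarray, ids: Sequence[str]):
        self.Z = np.asarray(Z, dtype=float)
        self.ids = list(ids)
        n = len(self.ids)
        if self.Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape does not match leaf count")
        self.n_leaves = n
        # leaf lists and parent pointers per tree node
        self._leaves: list[list[int]] = [[i] for i in range(n)]
        self.parent = np.full(2 * n - 1, -1, dtype=np.int64)
        for row in range(n - 1):
            a, b = int(self.Z[row, 0]), int(self.Z[row, 1])
            self._leaves.append(self._leaves[a] + self._leaves[b])
            self.parent[a] = n + row
            self.parent[b] = n + row

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.Z[node - n, 2])

    def children(self, node: int) -> tuple[int, int]:
        row = node - self.n_leaves
        return int(self.Z[row, 0]), int(self.Z[row, 1])

    def leaves(self, node: int) -> list[int]:
        return self._leaves[node]

    def branch_size(self, node: int) -> int:
        return len(self._leaves[node])

    def leaf_join_height(self, leaf: int) -> float:
        """Height of the merge that first absorbs this leaf."""
        return self.height(self.parent[leaf]) if self.parent[leaf] >= 0 else 0.0

    def to_newick(self) -> str:
        def rec(node: int, parent_h: float) -> str:
            h = self.height(node)
            bl = max(parent_h - h, 0.0)
            if node < self.n_leaves:
                return f"{self.ids[node]}:{bl:.6g}"
            a, b = self.children(node)
            return f"({rec(a, h)},{rec(b, h)}):{bl:.6g}"

        root = 2 * self.n_leaves - 2
        h = self.height(root)
        a, b = self.children(root)
        return f"({rec(a, h)},{rec(b, h)});"


@dataclass(frozen=True)
class CutParams:
    """Tree-cut parameters; unset ``h_max``/``d_max``/``g_min`` are filled
    from the ``deep_split`` preset relative to the merge-height range."""

    min_module_size: int = 20
    deep_split: int = 2
    h_max: float | None = None        # absolute; default 99th height percentile
    h_max_quantile: float = 0.99
    d_max: float | None = None        # absolute core-scatter cap
    g_min: float | None = None        # absolute minimum cluster gap

    def __post_init__(self):
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")

    def resolve(self, heights: np.ndarray) -> "CutParams":
        """Fill unset thresholds from the dendrogram's height scale.

        The deepSplit preset interpolates the core-scatter cap from 0.64
        (conservative) to 0.95 (aggressive) of the height range above its
        5th-percentile base, with ``g_min = 0.75 * (1 - frac) * range``.
        """
        h_max = self.h_max
        if h_max is None:
            h_max = float(np.quantile(heights, self.h_max_quantile))
        base = float(np.quantile(heights, 0.05))
        span = max(h_max - base, 0.0)
        frac = 0.64 + self.deep_split * (0.95 - 0.64) / 4.0
        d_max = self.d_max if self.d_max is not None else base + frac * span
        g_min = self.g_min if self.g_min is not None else 0.75 * (1.0 - frac) * span
        return replace(self, h_max=h_max, d_max=d_max, g_min=g_min)


class ModulePartition:
    """node id -> module id; 0 marks unassigned/outlier nodes."""

    def __init__(self, labels: Mapping[str, int]):
        self.labels: dict[str, int] = {str(k): int(v) for k, v in labels.items()}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, node: str) -> int:
        return self.labels[node]

    @property
    def module_ids(self) -> list[int]:
        return sorted({m for m in self.labels.values() if m > 0})

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    def members(self, module: int) -> set[str]:
        return {n for n, m in self.labels.items() if m == module}

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, m in self.labels.items():
            if m > 0:
                out.setdefault(m, set()).add(n)
        return out

    def outliers(self) -> set[str]:
        return {n for n, m in self.labels.items() if m == 0}

    def member_sets(self) -> frozenset[frozenset[str]]:
        """Labelling-independent view for stability comparison."""
        return frozenset(frozenset(v) for v in self.modules().values())

    def relabeled(self) -> "ModulePartition":
        """Contiguous 1..K ids ordered by smallest member id."""
        mods = sorted(self.modules().items(), key=lambda kv: min(kv[1]))
        remap = {old: i + 1 for i, (old, _) in enumerate(mods)}
        return ModulePartition({n: remap.get(m, 0) for n, m in self.labels.items()})


def build_dendrogram(embeddings: Embedding, metric: str = "euclidean",
                     method: str = "average") -> tuple[Dendrogram, np.ndarray]:
    """Agglomerative tree over embedding vectors.

    Returns the dendrogram and the square dissimilarity matrix in leaf
    order (needed by the cut).  Euclidean distance with average linkage
    by default; ties resolve to scipy's deterministic merge order.
    """
    if len(embeddings.ids) < 2:
        raise ValueError("need at least 2 nodes to cluster")
    if not np.all(np.isfinite(embeddings.matrix)):
        raise ValueError("non-finite embedding vectors")
    condensed = pdist(embeddings.matrix, metric=metric)
    Z = linkage(condensed, method=method)
    return Dendrogram(Z, embeddings.ids), squareform(condensed)


def core_size(N: int, N0: int) -> int:
    """Size Nc of the branch core over which core scatter is measured."""
    if N < 1 or N0 < 1:
        raise ValueError("N and N0 must be >= 1")
    inner = max(N - N0 / 2.0, 0.0)
    nc = min(int(math.floor(N0 / 2.0 + math.sqrt(inner))), N)
    return max(nc, 1)


def _core_leaves(dend: Dendrogram, node: int, n0: int) -> list[int]:
    leaves = dend.leaves(node)
    nc = core_size(len(leaves), n0)
    ranked = sorted(leaves, key=lambda lf: (dend.leaf_join_height(lf), lf))
    return ranked[:nc]


def cluster_stats(dend: Dendrogram, node: int, distances: np.ndarray,
                  n0: int) -> tuple[int, float, float, float]:
    """(N, height, core scatter dbar, gap g) for a dendrogram branch.

    ``height`` is the branch's own top merge height.  The gap measures
    how far the branch sits below the height at which it merges into
    the rest of the tree: ``g = attach_height - dbar`` where the attach
    height is the parent merge height (for the tree root, its own
    height).  A tight, well-separated cluster has small ``dbar`` and
    large ``g``.
    """
    leaves = dend.leaves(node)
    N = len(leaves)
    height = dend.height(node)
    parent = dend.parent[node]
    attach = dend.height(parent) if parent >= 0 else height
    core = _core_leaves(dend, node, n0)
    if len(core) < 2:
        dbar = 0.0
    else:
        idx = np.asarray(core)
        sub = distances[np.ix_(idx, idx)]
        m = len(core)
        dbar = float(sub.sum() / (m * (m - 1)))
    return N, height, dbar, attach - dbar


def _qualifies(dend: Dendrogram, node: int, distances: np.ndarray,
               p: CutParams) -> bool:
    N, height, dbar, g = cluster_stats(dend, node, distances, p.min_module_size)
    return (N > p.min_module_size and height < p.h_max
            and dbar < p.d_max and g > p.g_min)


def dynamic_hybrid_cut(dend: Dendrogram, distances: np.ndarray,
                       params: CutParams) -> ModulePartition:
    """Stage-1 cut: bottom-up merging locks qualifying branches.

    Merges at or above ``h_max`` are not performed.  Walking the
    remaining merges bottom-up, when two branches join and *both*
    qualify they are locked as separate clusters (their union becomes a
    composite that is never itself emitted); when a branch joins an
    already-composite partner it is locked iff it qualifies.  Branches
    still alive after the last sub-``h_max`` merge are locked iff they
    qualify.  Leaves of no locked branch are outliers (label 0).
    """
    n = dend.n_leaves
    if distances.shape != (n, n):
        raise ValueError("distance matrix does not match dendrogram leaves")
    p = params.resolve(dend.heights)

    composite = np.zeros(2 * n - 1, dtype=bool)
    alive = set(range(n))  # current forest roots among processed merges
    selected: list[int] = []

    def maybe_lock(node: int) -> None:
        if node >= n and not composite[node] and \
                _qualifies(dend, node, distances, p):
            selected.append(node)
            composite[node] = True

    for row in range(n - 1):
        if dend.Z[row, 2] >= p.h_max:
            continue  # merge suppressed by the height cap
        a, b = int(dend.Z[row, 0]), int(dend.Z[row, 1])
        parent = n + row
        alive.discard(a)
        alive.discard(b)
        alive.add(parent)
        qa = a >= n and not composite[a] and _qualifies(dend, a, distances, p)
        qb = b >= n and not composite[b] and _qualifies(dend, b, distances, p)
        if composite[a] or composite[b]:
            if qa:
                selected.append(a)
            if qb:
                selected.append(b)
            composite[parent] = True
        elif qa and qb:
            selected.extend((a, b))
            composite[parent] = True
        # else: the smaller/failing side is absorbed; parent stays ordinary

    for node in alive:
        maybe_lock(node)
    selected.sort(key=lambda s: (dend.height(s), min(dend.leaves(s))))

    labels = {node_id: 0 for node_id in dend.ids}
    for mid, branch in enumerate(selected, start=1):
        for lf in dend.leaves(branch):
            labels[dend.ids[lf]] = mid
    if not selected:
        logger.warning("no dendrogram branch satisfies the cut conditions; "
                       "all %d leaves marked outliers", n)
    return ModulePartition(labels)


def assign_outliers(partition: ModulePartition, distances: np.ndarray,
                    ids: Sequence[str]) -> ModulePartition:
    """Stage 2: attach each outlier to its most similar cluster.

    Similarity is average linkage to the stage-1 members (fixed during
    the sweep, so the result is order-independent); ties resolve to the
    lower module id.  Existing non-zero labels never change.
    """
    mods = partition.modules()
    if not mods:
        logger.warning("no clusters to absorb outliers into; partition unchanged")
        return partition
    index = {node_id: i for i, node_id in enumerate(ids)}
    member_idx = {m: np.asarray([index[x] for x in sorted(v)])
                  for m, v in mods.items()}
    labels = dict(partition.labels)
    for node in sorted(partition.outliers()):
        i = index[node]
        best_id, best_d = None, np.inf
        for m in sorted(member_idx):
            d = float(distances[i, member_idx[m]].mean())
            if d < best_d:
                best_id, best_d = m, d
        labels[node] = best_id
    return ModulePartition(labels)


def cut_tree(embeddings: Embedding, params: CutParams,
             metric: str = "euclidean", method: str = "average"
             ) -> ModulePartition:
    """build_dendrogram -> dynamic_hybrid_cut -> assign_outliers."""
    dend, distances = build_dendrogram(embeddings, metric=metric, method=method)
    part = dynamic_hybrid_cut(dend, distances, params)
    part = assign_outliers(part, distances, dend.ids)
    return part.relabeled()
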