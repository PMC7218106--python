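import numpy as np
import pytest

from n2vhc.embed import Embedding
from n2vhc.evaluate import micro_f1
from n2vhc.treecut import (CutParams, Dendrogram, ModulePartition,
                           assign_outliers, build_dendrogram, cluster_stats,
                           core_size, cut_tree, dynamic_hybrid_cut)


def _emb(points, prefix="n"):
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    ids = [f"{prefix}{i:03d}" for i in range(X.shape[0])]
    return Embedding(ids, X)


# -- dendrogram construction ------------------------------------------

def test_two_points_single_merge():
    dend, dist = build_dendrogram(_emb([[0.0], [1.0]]))
    assert dend.Z.shape == (1, 4)
    assert dend.heights[0] == pytest.approx(1.0)


def test_three_collinear_points_average_linkage():
    dend, _ = build_dendrogram(_emb([[0.0], [1.0], [10.0]]))
    # first merge (0,1) at height 1; then average of d(0,10)=10, d(1,10)=9
    assert dend.heights[0] == pytest.approx(1.0)
    assert dend.heights[1] == pytest.approx(9.5)


def test_duplicated_points_merge_at_zero():
    dend, _ = build_dendrogram(_emb([[1.0], [1.0], [5.0]]))
    assert dend.heights[0] == pytest.approx(0.0)


def test_non_finite_vectors_rejected():
    with pytest.raises(ValueError):
        build_dendrogram(Embedding(["a", "b"], np.array([[np.nan], [1.0]])))


def test_newick_export_parses():
    import io
    from Bio import Phylo
    dend, _ = build_dendrogram(_emb([[0.0], [1.0], [10.0]]))
    tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == \
        ["n000", "n001", "n002"]


# -- core size ---------------------------------------------------------

@pytest.mark.parametrize("N,N0,expected", [
    (50, 20, 16),   # floor(10 + sqrt(40)) = 16
    (5, 20, 5),     # N <= N0/2: clipped to N
    (1, 20, 1),
    (100, 2, 10),   # floor(1 + sqrt(99)) = 10
])
def test_core_size(N, N0, expected):
    assert core_size(N, N0) == expected


# -- branch statistics -------------------------------------------------

def test_cluster_stats_two_leaf_root():
    dend, dist = build_dendrogram(_emb([[0.0], [3.0]]))
    N, height, dbar, g = cluster_stats(dend, 2, dist, n0=2)
    assert (N, height) == (2, pytest.approx(3.0))
    assert dbar == pytest.approx(3.0)
    assert g == pytest.approx(0.0)  # root: attach height = own height


def test_cluster_stats_tight_pair_plus_far_leaf():
    dend, dist = build_dendrogram(_emb([[0.0], [0.1], [5.0]]))
    root = 2 * 3 - 2
    N, height, dbar, g = cluster_stats(dend, root, dist, n0=2)
    assert N == 3
    assert height == pytest.approx((5.0 + 4.9) / 2)
    assert dbar == pytest.approx(0.1)  # core = the tight pair
    assert g == pytest.approx(height - 0.1)


def test_cluster_stats_equidistant_points_zero_gap():
    # equilateral triangle: every pairwise distance 1, all merges at 1
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    dend, dist = build_dendrogram(Embedding(["a", "b", "c"], X))
    root = 4
    _, _, dbar, g = cluster_stats(dend, root, dist, n0=2)
    assert g == pytest.approx(0.0, abs=1e-9)


def test_gap_uses_attach_height_for_inner_branch():
    # tight pair attaching to a far leaf: pair branch gap = attach - scatter
    dend, dist = build_dendrogram(_emb([[0.0], [0.1], [5.0]]))
    pair = 3  # first merge
    N, height, dbar, g = cluster_stats(dend, pair, dist, n0=2)
    assert (N, height) == (2, pytest.approx(0.1))
    assert g == pytest.approx(dend.height(4) - 0.1)


# -- the dynamic hybrid cut -------------------------------------------

def bottom_up_oracle(dend, dist, params):
    """Recursive restatement of the bottom-up locking semantics."""
    p = params.resolve(dend.heights)
    n = dend.n_leaves

    def qualifies(node):
        if node < n:
            return False
        N, height, dbar, g = cluster_stats(dend, node, dist,
                                           p.min_module_size)
        return (N > p.min_module_size and height < p.h_max
                and dbar < p.d_max and g > p.g_min)

    def collect(node):
        """Returns (locked branch list, is_composite)."""
        if node < n or dend.height(node) >= p.h_max:
            # suppressed merges split the subtree into forest roots
            if node < n:
                return [], False
            out = []
            for c in dend.children(node):
                sub, comp = collect(c)
                if sub:
                    out.extend(sub)
                elif not comp and qualifies(c):
                    out.append(c)
            return out, True
        a, b = dend.children(node)
        La, ca = collect(a)
        Lb, cb = collect(b)
        qa = (not ca) and qualifies(a)
        qb = (not cb) and qualifies(b)
        if ca or cb:
            locked = La + Lb + ([a] if qa else []) + ([b] if qb else [])
            return locked, True
        if qa and qb:
            return [a, b], True
        return [], False

    root = 2 * n - 2
    locked, comp = collect(root)
    if not locked and not comp and qualifies(root):
        locked = [root]
    return {frozenset(dend.ids[lf] for lf in dend.leaves(b)) for b in locked}


@pytest.mark.parametrize("seed", range(8))
def test_stage1_matches_recursive_oracle_small(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 13))
    X = rng.normal(size=(n, 3)) * rng.choice([1.0, 4.0], size=(n, 1))
    emb = Embedding([f"l{i:02d}" for i in range(n)], X)
    dend, dist = build_dendrogram(emb)
    params = CutParams(min_module_size=2, deep_split=int(rng.integers(0, 5)))
    part = dynamic_hybrid_cut(dend, dist, params)
    got = {frozenset(v) for v in part.modules().values()}
    assert got == bottom_up_oracle(dend, dist, params)


def test_stage1_clusters_satisfy_all_conditions(blob_embedding):
    emb, _ = blob_embedding
    params = CutParams(min_module_size=5, deep_split=2)
    dend, dist = build_dendrogram(emb)
    part = dynamic_hybrid_cut(dend, dist, params)
    p = params.resolve(dend.heights)
    leaf_of = {node_id: i for i, node_id in enumerate(dend.ids)}
    for members in part.modules().values():
        leaves = {leaf_of[m] for m in members}
        node = next(b for b in range(2 * dend.n_leaves - 1)
                    if set(dend.leaves(b)) == leaves)
        N, height, dbar, g = cluster_stats(dend, node, dist,
                                           p.min_module_size)
        assert N > p.min_module_size
        assert height < p.h_max
        assert dbar < p.d_max
        assert g > p.g_min


def test_two_blobs_split_and_infeasible_params(blob_embedding):
    emb, truth = blob_embedding
    part = cut_tree(emb, CutParams(min_module_size=10, deep_split=2))
    assert part.n_modules == 4
    assert micro_f1(part.labels, truth)[2] == 1.0
    # min size condition unsatisfiable
    dend, dist = build_dendrogram(emb)
    part = dynamic_hybrid_cut(dend, dist, CutParams(min_module_size=40))
    assert part.n_modules == 0 and len(part.outliers()) == 60
    # h_max below the first merge height
    part = dynamic_hybrid_cut(dend, dist,
                              CutParams(min_module_size=5,
                                        h_max=float(dend.heights[0]) / 2))
    assert part.n_modules == 0


def test_single_blob_collapses_to_one_module():
    rng = np.random.default_rng(2)
    emb = Embedding([f"n{i:02d}" for i in range(20)],
                    rng.normal(size=(20, 6)))
    part = cut_tree(emb, CutParams(min_module_size=5, deep_split=2))
    assert part.n_modules == 1
    assert not part.outliers()


# -- outlier assignment -----------------------------------------------

def test_assign_outliers_rules():
    ids = ["a", "b", "c", "d", "o"]
    #         a    b    c    d    o
    dist = np.array([
        [0.0, 1.0, 9.0, 9.0, 2.0],
        [1.0, 0.0, 9.0, 9.0, 2.0],
        [9.0, 9.0, 0.0, 1.0, 2.0],
        [9.0, 9.0, 1.0, 0.0, 2.0],
        [2.0, 2.0, 2.0, 2.0, 0.0],
    ])
    part = ModulePartition({"a": 1, "b": 1, "c": 2, "d": 2, "o": 0})
    out = assign_outliers(part, dist, ids)
    assert out["o"] == 1  # equidistant tie goes to the lower module id
    # dominance: distance 0 to a member of module 2
    dist2 = dist.copy()
    dist2[4, 2] = dist2[2, 4] = 0.0
    out = assign_outliers(part, dist2, ids)
    assert out["o"] == 2
    # identity when no outliers; labels never change
    full = ModulePartition({"a": 1, "b": 1, "c": 2, "d": 2, "o": 2})
    assert assign_outliers(full, dist, ids).labels == full.labels
    # no clusters at all: unchanged
    empty = ModulePartition({k: 0 for k in ids})
    assert assign_outliers(empty, dist, ids).labels == empty.labels


def test_cut_tree_invariant_to_leaf_order(blob_embedding):
    emb, truth = blob_embedding
    params = CutParams(min_module_size=10, deep_split=2)
    base = cut_tree(emb, params)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(emb.ids))
    emb2 = Embedding([emb.ids[i] for i in perm], emb.matrix[perm])
    permuted = cut_tree(emb2, params)
    assert base.member_sets() == permuted.member_sets()
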