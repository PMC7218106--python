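"""Numba kernels for biased random walks and skip-gram negative sampling.

Both kernels are single-threaded and drive all randomness from an
explicit xorshift64* state so that a given seed reproduces walks and
embeddings bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- deterministic PRNG (xorshift64*) ---------------------------------


@njit(cache=True, inline="always")
def _next_u64(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    state[0] = x
    return (x * np.uint64(2685821657736338717)) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _rand_f64(state):
    return (_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _rand_below(state, n):
    return np.int64(_next_u64(state) % np.uint64(n))


def seed_state(seed: int) -> np.ndarray:
    """SplitMix64-scrambled non-zero initial state from a small seed."""
    mask = (1 << 64) - 1
    z = (int(seed) + 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    if z == 0:
        z = 0x2545F4914F6CDD1D
    return np.array([z], dtype=np.uint64)


# -- biased second-order random walks ---------------------------------


@njit(cache=True, inline="always")
def _binary_search(cumw, lo, hi, r):
    # first index i in [lo, hi) with cumw[i] > r
    while lo < hi:
        mid = (lo + hi) // 2
        if cumw[mid] > r:
            hi = mid
        else:
            lo = mid + 1
    return lo


@njit(cache=True, inline="always")
def _is_neighbor(indices, indptr, t, x):
    lo, hi = indptr[t], indptr[t + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        if indices[mid] == x:
            return True
        elif indices[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return False


@njit(cache=True)
def simulate_walks_kernel(indptr, indices, weights, cumw,
                          und_indptr, und_indices, n_walks,
                          walk_length, p, q, state):
    """All walks, ``n_walks`` passes over a shuffled node order.

    ``und_indptr``/``und_indices`` hold the symmetrized adjacency used
    for the d_tx distance test (identical to ``indptr``/``indices`` on
    undirected graphs).  Returns an int32 matrix
    (n_walks * n, walk_length) padded with -1 after early truncation at
    sink nodes.
    """
    n = indptr.shape[0] - 1
    walks = np.full((n_walks * n, walk_length), -1, dtype=np.int32)
    order = np.arange(n, dtype=np.int64)
    first_order = (p == 1.0) and (q == 1.0)
    probs = np.empty(0, dtype=np.float64)
    if not first_order:
        max_deg = 0
        for v in range(n):
            d = indptr[v + 1] - indptr[v]
            if d > max_deg:
                max_deg = d
        probs = np.empty(max_deg, dtype=np.float64)
    row = 0
    for _pass in range(n_walks):
        # Fisher-Yates shuffle of start order
        for i in range(n - 1, 0, -1):
            j = _rand_below(state, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for s in range(n):
            u = order[s]
            walks[row, 0] = u
            prev = -1
            cur = u
            for step in range(1, walk_length):
                lo, hi = indptr[cur], indptr[cur + 1]
                deg = hi - lo
                if deg == 0:
                    break  # sink: truncate
                if first_order or prev < 0:
                    # weight-proportional draw via per-node cumulative weights
                    total = cumw[hi - 1] - (cumw[lo - 1] if lo > 0 else 0.0)
                    r = _rand_f64(state) * total + (cumw[lo - 1] if lo > 0 else 0.0)
                    idx = _binary_search(cumw, lo, hi, r)
                    nxt = indices[idx]
                else:
                    total = 0.0
                    for k in range(deg):
                        x = indices[lo + k]
                        w = weights[lo + k]
                        if x == prev:
                            a = 1.0 / p
                        elif _is_neighbor(und_indices, und_indptr, prev, x):
                            a = 1.0
                        else:
                            a = 1.0 / q
                        total += a * w
                        probs[k] = total
                    r = _rand_f64(state) * total
                    k = 0
                    while k < deg - 1 and probs[k] <= r:
                        k += 1
                    nxt = indices[lo + k]
                walks[row, step] = nxt
                prev = cur
                cur = nxt
            row += 1
    return walks


# -- skip-gram with negative sampling ---------------------------------


@njit(cache=True, fastmath=True)
def train_sgns_kernel(walks, n_nodes, dim, window, epochs, negative,
                      alpha0, neg_table, state):
    """word2vec-style SGNS over padded walk rows (-1 = padding).

    Input vectors syn0 are the embeddings; syn1 holds the output
    (context) representations trained against ``negative`` draws from
    ``neg_table`` per positive pair.  Learning rate decays linearly.
    """
    syn0 = np.empty((n_nodes, dim), dtype=np.float32)
    for i in range(n_nodes):
        for j in range(dim):
            syn0[i, j] = np.float32((_rand_f64(state) - 0.5) / dim)
    syn1 = np.zeros((n_nodes, dim), dtype=np.float32)
    table_size = neg_table.shape[0]
    n_rows = walks.shape[0]
    max_len = walks.shape[1]

    # total token budget for the linear learning-rate schedule
    total_tokens = 0
    for r in range(n_rows):
        for c in range(max_len):
            if walks[r, c] < 0:
                break
            total_tokens += 1
    total_tokens *= epochs
    if total_tokens == 0:
        return syn0, syn1

    grad = np.empty(dim, dtype=np.float32)
    processed = 0
    lr = np.float32(alpha0)
    min_lr = np.float32(alpha0 * 1.0e-4)
    for _epoch in range(epochs):
        for r in range(n_rows):
            # walk length of this row
            wl = 0
            for c in range(max_len):
                if walks[r, c] < 0:
                    break
                wl += 1
            for j in range(wl):
                processed += 1
                if processed % 10000 == 0:
                    frac = processed / total_tokens
                    lr = np.float32(alpha0 * (1.0 - frac))
                    if lr < min_lr:
                        lr = min_lr
                center = walks[r, j]
                b = 1 + np.int64(_rand_below(state, window))  # reduced window
                lo = j - b if j - b > 0 else 0
                hi = j + b + 1 if j + b + 1 < wl else wl
                for k in range(lo, hi):
                    if k == j:
                        continue
                    ctx = walks[r, k]
                    row0 = syn0[ctx]
                    # positive pair + `negative` sampled negatives
                    for g in range(dim):
                        grad[g] = 0.0
                    for neg in range(negative + 1):
                        if neg == 0:
                            target = center
                            label = np.float32(1.0)
                        else:
                            target = neg_table[_rand_below(state, table_size)]
                            if target == center:
                                continue
                            label = np.float32(0.0)
                        row1 = syn1[target]
                        dot = np.float32(0.0)
                        for g in range(dim):
                            dot += row0[g] * row1[g]
                        if dot > 6.0:
                            f = np.float32(1.0)
                        elif dot < -6.0:
                            f = np.float32(0.0)
                        else:
                            f = np.float32(1.0 / (1.0 + np.exp(-dot)))
                        gcoef = (label - f) * lr
                        for g in range(dim):
                            grad[g] += gcoef * row1[g]
                            row1[g] += gcoef * row0[g]
                    for g in range(dim):
                        row0[g] += grad[g]
    return syn0, syn1


@njit(cache=True)
def sgns_loss_kernel(walks, syn0, syn1, window, negative, neg_table, state):
    """Mean negative-sampling objective (positive-pair part uses the
    full fixed window; negatives are re-sampled).  Diagnostic only."""
    n_rows = walks.shape[0]
    max_len = walks.shape[1]
    table_size = neg_table.shape[0]
    dim = syn0.shape[1]
    loss = 0.0
    count = 0
    for r in range(n_rows):
        wl = 0
        for c in range(max_len):
            if walks[r, c] < 0:
                break
            wl += 1
        for j in range(wl):
            center = walks[r, j]
            lo = j - window if j - window > 0 else 0
            hi = j + window + 1 if j + window + 1 < wl else wl
            for k in range(lo, hi):
                if k == j:
                    continue
                ctx = walks[r, k]
                dot = 0.0
                for g in range(dim):
                    dot += syn0[ctx, g] * syn1[center, g]
                loss += np.log(1.0 + np.exp(-dot))
                for neg in range(negative):
                    target = neg_table[_rand_below(state, table_size)]
                    if target == center:
                        continue
                    dot = 0.0
                    for g in range(dim):
                        dot += syn0[ctx, g] * syn1[target, g]
                    loss += np.log(1.0 + np.exp(dot))
                count += 1
    if count == 0:
        return 0.0
    return loss / count
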