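"""Synthetic-data generators.

Two families: (1) LFR-style weighted benchmark networks with planted
communities — power-law degree and community-size distributions, a
topological mixing parameter controlling the fraction of inter-community
edges per node, and a weight mixing parameter ``muw`` controlling the
fraction of each node's *weighted* degree that crosses community
borders; (2) synthetic GWAS/eQTL/interactome triplets with planted
disease modules for end-to-end pipeline tests.

The LFR-style generator is a native reimplementation (configuration
model within and between communities plus weight assignment targeting
``muw`` in expectation); it approximates, rather than bit-replicates,
the reference benchmark tool's iterative rewiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import Network

__all__ = ["LFRParams", "PlantedDiseaseConfig", "PlantedDiseaseData",
           "generate_lfr_like", "generate_planted_disease_data"]


@dataclass(frozen=True)
class LFRParams:
    """LFR-style benchmark parameters.

    ``t1``/``t2`` are the (minus) exponents of the degree and
    community-size power laws; ``muw`` the weight mixing parameter; the
    topological mixing ``mut`` defaults to ``muw``.
    """

    n: int
    k: float
    maxk: int
    muw: float = 0.5
    t1: float = 2.0
    t2: float = 1.0
    mut: float | None = None
    directed: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.k <= self.maxk < self.n):
            raise ValueError("need 1 <= k <= maxk < n")
        if not 0.0 <= self.muw <= 1.0:
            raise ValueError("muw must be in [0, 1]")
        if self.mut is not None and not 0.0 <= self.mut <= 1.0:
            raise ValueError("mut must be in [0, 1]")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("t1 and t2 must be positive")


def _truncated_powerlaw_pmf(kmin: int, kmax: int, exponent: float) -> np.ndarray:
    ks = np.arange(kmin, kmax + 1, dtype=float)
    w = ks ** (-exponent)
    return w / w.sum()


def _solve_kmin(mean_target: float, kmax: int, exponent: float) -> int:
    """Smallest-degree cutoff whose truncated power law matches the mean."""
    best, best_err = 1, np.inf
    for kmin in range(1, kmax + 1):
        pmf = _truncated_powerlaw_pmf(kmin, kmax, exponent)
        mean = float(np.arange(kmin, kmax + 1) @ pmf)
        err = abs(mean - mean_target)
        if err < best_err:
            best, best_err = kmin, err
        if mean > mean_target:
            break
    return best


def _sample_community_sizes(n: int, minc: int, maxc: int, t2: float,
                            rng: np.random.Generator) -> list[int]:
    pmf = _truncated_powerlaw_pmf(minc, maxc, t2)
    support = np.arange(minc, maxc + 1)
    sizes: list[int] = []
    total = 0
    while total < n:
        s = int(rng.choice(support, p=pmf))
        sizes.append(s)
        total += s
    excess = total - n
    # shave the excess off the largest communities, respecting minc
    while excess > 0:
        i = int(np.argmax(sizes))
        cut = min(excess, sizes[i] - minc)
        if cut == 0:
            # everything at minc: drop one community, enlarge another
            sizes.sort()
            excess -= sizes.pop(0)
            if excess < 0:
                sizes[-1] += -excess
                excess = 0
            continue
        sizes[i] -= cut
        excess -= cut
    return sorted(sizes, reverse=True)


def _pair_stubs(stubs: np.ndarray, rng: np.random.Generator,
                forbidden_same: np.ndarray | None, existing: set[tuple[int, int]],
                max_sweeps: int = 10) -> list[tuple[int, int]]:
    """Randomly pair stubs into simple edges; unmatched leftovers are dropped.

    ``forbidden_same``: per-node community labels; stub pairs inside the
    same community are rejected (used for the inter-community pass).
    """
    edges: list[tuple[int, int]] = []
    pool = stubs.copy()
    for _ in range(max_sweeps):
        if pool.size < 2:
            break
        rng.shuffle(pool)
        leftovers: list[int] = []
        m = pool.size - pool.size % 2
        for idx in range(0, m, 2):
            u, v = int(pool[idx]), int(pool[idx + 1])
            if u == v:
                leftovers.extend((u, v))
                continue
            if forbidden_same is not None and forbidden_same[u] == forbidden_same[v]:
                leftovers.extend((u, v))
                continue
            key = (u, v) if u < v else (v, u)
            if key in existing:
                leftovers.extend((u, v))
                continue
            existing.add(key)
            edges.append(key)
        if pool.size % 2:
            leftovers.append(int(pool[-1]))
        pool = np.asarray(leftovers, dtype=np.int64)
    return edges


def generate_lfr_like(params: LFRParams) -> tuple[Network, dict[str, int]]:
    """Weighted benchmark network with planted communities.

    Returns the network and the ground-truth labels (node id ->
    community id, 1-based).  The graph is connected after a post-hoc
    repair step that bridges stray components to the giant one.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    mut = params.muw if params.mut is None else params.mut

    # -- degree sequence ----------------------------------------------
    kmin = _solve_kmin(params.k, params.maxk, params.t1)
    pmf = _truncated_powerlaw_pmf(kmin, params.maxk, params.t1)
    degrees = rng.choice(np.arange(kmin, params.maxk + 1), size=n, p=pmf)

    # -- community sizes and assignment -------------------------------
    minc = max(kmin, 2)
    maxc = min(params.maxk, n)
    sizes = _sample_community_sizes(n, minc, maxc, params.t2, rng)
    n_comm = len(sizes)
    d_int = np.minimum(np.rint((1.0 - mut) * degrees).astype(np.int64),
                       degrees)
    comm = np.full(n, -1, dtype=np.int64)
    capacity = np.asarray(sizes, dtype=np.int64).copy()
    order = np.argsort(-d_int, kind="stable")
    for node in order:
        ok = np.flatnonzero((capacity > 0)
                            & (np.asarray(sizes) - 1 >= d_int[node]))
        if ok.size == 0:
            ok = np.flatnonzero(capacity > 0)
            d_int[node] = min(d_int[node], sizes[int(ok[0])] - 1)
        probs = capacity[ok] / capacity[ok].sum()
        c = int(rng.choice(ok, p=probs))
        comm[node] = c
        capacity[c] -= 1
        d_int[node] = min(d_int[node], sizes[c] - 1)
    d_ext = degrees - d_int

    # -- intra-community edges (per-community configuration model) ----
    existing: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    internal: set[tuple[int, int]] = set()
    for c in range(n_comm):
        members = np.flatnonzero(comm == c)
        stubs = np.repeat(members, d_int[members])
        if stubs.size % 2:  # make the stub count even
            heavy = members[int(np.argmax(d_int[members]))]
            stubs = np.append(stubs, heavy)
        new = _pair_stubs(stubs, rng, None, existing)
        edges.extend(new)
        internal.update(new)

    # -- inter-community edges -----------------------------------------
    ext_stubs = np.repeat(np.arange(n), d_ext)
    if ext_stubs.size % 2:
        ext_stubs = ext_stubs[:-1]
    edges.extend(_pair_stubs(ext_stubs, rng, comm, existing))

    # -- weights targeting the muw weighted-degree mixing --------------
    deg_int = np.zeros(n, dtype=np.int64)
    deg_ext = np.zeros(n, dtype=np.int64)
    for u, v in edges:
        if (u, v) in internal:
            deg_int[u] += 1
            deg_int[v] += 1
        else:
            deg_ext[u] += 1
            deg_ext[v] += 1
    strength = degrees.astype(float)
    w_int_node = (1.0 - params.muw) * strength / np.maximum(deg_int, 1)
    w_ext_node = params.muw * strength / np.maximum(deg_ext, 1)

    width = len(str(n))
    ids = [f"v{i:0{width}d}" for i in range(n)]
    net = Network(directed=False)
    for i in ids:
        net.add_node(i)
    for u, v in edges:
        if (u, v) in internal:
            w = 0.5 * (w_int_node[u] + w_int_node[v])
        else:
            w = 0.5 * (w_ext_node[u] + w_ext_node[v])
        net.add_edge(ids[u], ids[v], weight=max(w, 1e-12))

    # -- connectivity repair -------------------------------------------
    import networkx as nx
    comps = sorted(nx.connected_components(net.g), key=len, reverse=True)
    if len(comps) > 1:
        giant = sorted(comps[0])
        mean_w = float(np.mean([w for *_, w in net.edges()])) or 1.0
        for comp in comps[1:]:
            u = sorted(comp)[rng.integers(len(comp))]
            v = giant[rng.integers(len(giant))]
            net.add_edge(u, v, weight=mean_w)

    labels = {ids[i]: int(comm[i]) + 1 for i in range(n)}

    if params.directed:
        # randomize edge orientation (the benchmark's directed flavor)
        dnet = Network(directed=True)
        for i in ids:
            dnet.add_node(i)
        for u, v, w in net.edges():
            if rng.random() < 0.5:
                u, v = v, u
            dnet.add_edge(u, v, weight=w)
        net = dnet
    return net, labels


# ---------------------------------------------------------------------
# planted disease data
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedDiseaseConfig:
    """Stochastic-block-model interactome plus synthetic GWAS/eQTL tables.

    ``module_sizes`` define the planted gene modules; the first
    ``n_disease_modules`` of them receive egenes wired to synthetic SNPs
    with small eQTL p-values, everything else only sees uniform-noise
    eQTL records (which a Benjamini-Hochberg filter should reject).
    """

    module_sizes: tuple[int, ...] = (25,) * 8
    n_disease_modules: int = 3
    egenes_per_module: int = 10
    esnps_per_egene: int = 2
    p_within: float = 0.30
    p_between: float = 0.01
    signal_p_max: float = 1e-8
    n_noise_records: int = 200
    low_expression_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_disease_modules > len(self.module_sizes):
            raise ValueError("more disease modules than modules")
        for p in (self.p_within, self.p_between, self.low_expression_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class PlantedDiseaseData:
    interactome: Network
    eqtl: pd.DataFrame                    # snp, gene, pvalue (proxy-level)
    proxy_map: dict[str, str]
    expression: dict[str, float]
    truth_modules: dict[int, set[str]]    # all planted modules
    disease_modules: dict[int, set[str]]  # the egene-carrying subset
    egenes: set[str] = field(default_factory=set)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .graph import write_edge_list
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactome": outdir / "interactome.tsv",
            "eqtl": outdir / "eqtl.tsv",
            "proxies": outdir / "proxies.tsv",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth_modules.tsv",
        }
        write_edge_list(self.interactome, paths["interactome"])
        self.eqtl.to_csv(paths["eqtl"], sep="\t", header=False, index=False)
        with open(paths["proxies"], "w") as fh:
            for proxy, index in sorted(self.proxy_map.items()):
                fh.write(f"{proxy}\t{index}\n")
        with open(paths["expression"], "w") as fh:
            for g, x in sorted(self.expression.items()):
                fh.write(f"{g}\t{x}\n")
        with open(paths["truth"], "w") as fh:
            for m, genes in sorted(self.truth_modules.items()):
                for g in sorted(genes):
                    fh.write(f"{g}\t{m}\n")
        return paths


def generate_planted_disease_data(cfg: PlantedDiseaseConfig) -> PlantedDiseaseData:
    """Synthetic triplet exercising the full integration pipeline."""
    rng = np.random.default_rng(cfg.seed)
    n_genes = sum(cfg.module_sizes)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]

    # block membership
    truth: dict[int, set[str]] = {}
    block = np.empty(n_genes, dtype=np.int64)
    start = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        idx = np.arange(start, start + size)
        block[idx] = m
        truth[m] = {genes[i] for i in idx}
        start += size

    net = Network(directed=False)
    for g in genes:
        net.add_node(g)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            p = cfg.p_within if block[i] == block[j] else cfg.p_between
            if rng.random() < p:
                net.add_edge(genes[i], genes[j])

    # eQTL signal: proxy SNPs per egene, all tagging one index SNP per module
    records: list[tuple[str, str, float]] = []
    proxy_map: dict[str, str] = {}
    egenes: set[str] = set()
    disease = {m: truth[m] for m in range(1, cfg.n_disease_modules + 1)}
    snp_serial = 0
    for m, members in disease.items():
        index_snp = f"rsI{m:03d}"
        proxy_map[index_snp] = index_snp
        chosen = rng.choice(sorted(members), size=min(cfg.egenes_per_module,
                                                     len(members)),
                            replace=False)
        for g in chosen:
            egenes.add(str(g))
            for _ in range(cfg.esnps_per_egene):
                proxy = f"rsP{snp_serial:05d}"
                snp_serial += 1
                proxy_map[proxy] = index_snp
                records.append((proxy, str(g), float(rng.uniform(0.0, cfg.signal_p_max))))

    # noise: uniform p-values on random (snp, gene) pairs
    for _ in range(cfg.n_noise_records):
        proxy = f"rsN{snp_serial:05d}"
        snp_serial += 1
        proxy_map[proxy] = proxy
        g = genes[int(rng.integers(n_genes))]
        records.append((proxy, g, float(rng.uniform())))

    eqtl = pd.DataFrame(records, columns=["snp", "gene", "pvalue"])

    expression = {g: 1.0 for g in genes}
    if cfg.low_expression_fraction > 0:
        non_disease = sorted(set(genes) - set().union(*disease.values()))
        n_low = int(round(cfg.low_expression_fraction * len(non_disease)))
        for g in rng.choice(non_disease, size=n_low, replace=False):
            expression[str(g)] = 0.0

    return PlantedDiseaseData(interactome=net, eqtl=eqtl, proxy_map=proxy_map,
                              expression=expression, truth_modules=truth,
                              disease_modules=disease, egenes=egenes)
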