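"""The iterative disease-module loop and module prioritization.

After the whole integrated network is embedded and cut into modules,
modules containing no egene are discarded, the surviving genes (and the
SNPs still attached to them) are extracted as a subnetwork, and the
clustering/cut repeats until the partition is stable.  Every surviving
module is then scored by a one-sided Fisher exact test for egene
over-representation against the gene-only background, with
Benjamini-Hochberg FDR across modules.  Module eigen-features (first
principal component of a module's embedding rows) support a
module-level dendrogram under the 1 - Pearson correlation distance, and
gene-set over-representation annotates modules against GMT collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .embed import EmbedParams, Embedding, WalkParams, embed_network
from .graph import GeneSetCollection, Network
from .integrate import IntegratedNetwork, bh_fdr
from .treecut import CutParams, Dendrogram, ModulePartition, cut_tree

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "ModuleReport",
    "fisher_point_probability",
    "fisher_enrichment_p",
    "score_modules",
    "iterate_module_selection",
    "module_eigen_features",
    "module_dendrogram",
    "geneset_overrepresentation",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 egene-by-module table over a gene-only background of size n.

    a: in-module egenes; b: egenes outside the module; c: in-module
    non-egenes; d: non-egenes outside.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_sets(cls, module: set[str], egenes: set[str],
                  background: set[str]) -> "ContingencyTable":
        module = module & background
        egenes = egenes & background
        a = len(module & egenes)
        return cls(a=a, b=len(egenes) - a, c=len(module) - a,
                   d=len(background) - len(module) - len(egenes) + a)


def fisher_point_probability(t: ContingencyTable) -> float:
    """Hypergeometric point probability of the observed table,
    C(a+b, a) * C(c+d, c) / C(n, a+c), computed in log space."""
    return float(np.exp(hypergeom.logpmf(t.a, t.n, t.a + t.b, t.a + t.c)))


def fisher_enrichment_p(t: ContingencyTable) -> float:
    """One-sided over-representation tail P(X >= a) with margins fixed."""
    p = float(hypergeom.sf(t.a - 1, t.n, t.a + t.b, t.a + t.c))
    return min(max(p, 0.0), 1.0)


@dataclass
class ModuleReport:
    module: int
    genes: set[str]
    egenes: set[str]
    pvalue: float
    fdr: float
    rank: int

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_egenes(self) -> int:
        return len(self.egenes)


def score_modules(partition: ModulePartition, egenes: set[str],
                  background: set[str],
                  point_probability: bool = False) -> list[ModuleReport]:
    """Per-module egene enrichment over the gene-only background.

    ``point_probability`` swaps the one-sided tail for the hypergeometric
    point mass (a reporting variant, not a test).  Reports come back
    sorted by ascending p with BH FDR across modules.
    """
    mods = partition.modules()
    if not mods:
        return []
    if not egenes <= background:
        raise ValueError("egenes must be a subset of the background")
    stat = fisher_point_probability if point_probability else fisher_enrichment_p
    rows = []
    for m in sorted(mods):
        genes = mods[m] & background
        t = ContingencyTable.from_sets(genes, egenes, background)
        rows.append((m, genes, genes & egenes, stat(t)))
    fdrs = bh_fdr([r[3] for r in rows])
    reports = [ModuleReport(module=m, genes=g, egenes=e, pvalue=p,
                            fdr=float(f), rank=0)
               for (m, g, e, p), f in zip(rows, fdrs)]
    reports.sort(key=lambda r: (r.pvalue, r.module))
    for i, r in enumerate(reports, start=1):
        r.rank = i
    return reports


def _surviving_nodes(net: Network, kept_members: set[str]) -> set[str]:
    """Genes in kept modules plus SNPs that still touch a kept gene."""
    genes = {n for n in kept_members if net.role(n) == "gene"}
    snps = set()
    for s in (n for n in kept_members if net.role(n) == "snp"):
        if any(nb in genes for nb in net.g[s]):
            snps.add(s)
    return genes | snps


def iterate_module_selection(inet: IntegratedNetwork,
                             walk_params: WalkParams | None = None,
                             embed_params: EmbedParams | None = None,
                             cut_params: CutParams | None = None,
                             max_iter: int = 20,
                             reembed_each_iter: bool = False
                             ) -> tuple[ModulePartition, list[dict], Embedding]:
    """Egene-filtered clustering loop.

    Embed once and re-cut restricted embeddings by default;
    ``reembed_each_iter`` recomputes walks and embeddings on each induced
    subnetwork.  Stops when no module is egene-free (stability) or at
    ``max_iter``.  Returns the final partition over surviving nodes, the
    per-iteration trace, and the embedding of the final node set.
    """
    walk_params = walk_params or WalkParams()
    embed_params = embed_params or EmbedParams()
    cut_params = cut_params or CutParams()
    if not inet.egenes:
        raise ValueError("integrated network has no egenes to select on")

    full_emb = embed_network(inet.network, walk_params, embed_params)
    nodes = sorted(inet.network.nodes())
    emb = full_emb
    trace: list[dict] = []
    partition = ModulePartition({})
    for iteration in range(1, max_iter + 1):
        part = cut_tree(emb, cut_params)
        mods = part.modules()
        kept = {m: v for m, v in mods.items()
                if v & inet.egenes}
        trace_row = {
            "iteration": iteration,
            "n_nodes": len(nodes),
            "n_modules": len(mods),
            "n_modules_kept": len(kept),
        }
        if not kept:
            trace_row["n_surviving_nodes"] = 0
            trace.append(trace_row)
            logger.warning("all modules egene-free at iteration %d", iteration)
            return ModulePartition({}), trace, emb
        sub = inet.network if len(nodes) == inet.network.n_nodes else None
        net_now = sub or _induced(inet.network, set(nodes))
        surviving = _surviving_nodes(net_now, set().union(*kept.values()))
        trace_row["n_surviving_nodes"] = len(surviving)
        trace_row["n_dropped_nodes"] = len(nodes) - len(surviving)
        trace.append(trace_row)
        partition = ModulePartition(
            {n: m for n, m in part.labels.items() if n in surviving and
             part.labels[n] in kept}).relabeled()
        if len(surviving) == len(nodes):
            break  # nothing filtered: the next pass would be identical
        nodes = sorted(surviving)
        if reembed_each_iter:
            emb = embed_network(_induced(inet.network, set(nodes)),
                                walk_params, embed_params)
        else:
            emb = full_emb.subset(nodes)
    else:
        logger.warning("module selection hit max_iter=%d without stability",
                       max_iter)
    return partition, trace, emb


def _induced(net: Network, keep: set[str]) -> Network:
    from .graph import induced_subgraph
    return induced_subgraph(net, keep)


def module_eigen_features(partition: ModulePartition,
                          embeddings: Embedding) -> dict[int, np.ndarray]:
    """First principal component of each module's member-feature matrix.

    Unit norm with the first non-zero loading made positive; a singleton
    module contributes its own normalized vector.
    """
    out: dict[int, np.ndarray] = {}
    for m, members in sorted(partition.modules().items()):
        rows = [embeddings.index[n] for n in sorted(members)]
        X = embeddings.matrix[rows]
        if X.shape[0] == 1:
            v = X[0].copy()
        else:
            Xc = X - X.mean(axis=0, keepdims=True)
            _, _, vt = np.linalg.svd(Xc, full_matrices=False)
            v = vt[0]
        norm = np.linalg.norm(v)
        if norm == 0:
            v = np.zeros_like(v)
        else:
            v = v / norm
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size and v[nz[0]] < 0:
                v = -v
        out[m] = v
    return out


def module_dendrogram(eigen: dict[int, np.ndarray]) -> Dendrogram:
    """Average-linkage tree over modules, distance 1 - Pearson(rho)."""
    if len(eigen) < 2:
        raise ValueError("need at least 2 modules")
    ids = sorted(eigen)
    X = np.vstack([eigen[m] for m in ids])
    sd = X.std(axis=1)
    for m, s in zip(ids, sd):
        if s == 0:
            raise ValueError(f"module {m} has a zero-variance eigen feature")
    corr = np.corrcoef(X)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(Z, [str(m) for m in ids])


def geneset_overrepresentation(module_genes: set[str],
                               collection: GeneSetCollection,
                               background: set[str],
                               top_k: int = 50) -> pd.DataFrame:
    """Fisher over-representation of a module against GMT gene sets.

    Returns the ``top_k`` terms by ascending p with BH FDR computed over
    the full collection.
    """
    module = module_genes & background
    if not module_genes <= background:
        raise ValueError("module genes must lie inside the background")
    if len(collection) == 0:
        return pd.DataFrame(columns=["term", "overlap", "set_size",
                                     "pvalue", "fdr"])
    rows = []
    for gs in collection:
        members = gs.members & background
        t = ContingencyTable.from_sets(module, set(members), background)
        # here the "egene" margin plays the gene-set role
        rows.append((gs.name, t.a, len(members), fisher_enrichment_p(t)))
    df = pd.DataFrame(rows, columns=["term", "overlap", "set_size", "pvalue"])
    df["fdr"] = bh_fdr(df["pvalue"].to_numpy())
    df = df.sort_values(["pvalue", "term"], kind="stable").reset_index(drop=True)
    return df.head(top_k)
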