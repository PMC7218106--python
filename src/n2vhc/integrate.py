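"""Build the integrated disease network from GWAS-derived SNPs, eQTL
summaries, an expression filter, and the interactome.

The construction mirrors the standard post-GWAS workflow: proxy SNPs in
linkage disequilibrium with GWAS index SNPs are collapsed onto their
index SNP; SNP-gene eQTL associations are FDR-filtered
(Benjamini-Hochberg) at a nominal cutoff; genes silent in the target
tissue are removed; and the surviving SNP-egene pairs are projected onto
the gene-gene interactome as extra bipartite edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .graph import GENE, SNP, Network, induced_subgraph

__all__ = [
    "IntegratedNetwork",
    "bh_fdr",
    "read_eqtl_table",
    "read_proxy_map",
    "read_expression_table",
    "filter_significant_eqtl",
    "replace_proxies",
    "filter_expressed_genes",
    "build_integrated_network",
]

#: column names of the canonical eQTL record frame
EQTL_COLUMNS = ("snp", "gene", "pvalue")


@dataclass
class IntegratedNetwork:
    """Interactome augmented with significant SNP-egene edges.

    ``egenes`` are the genes with at least one retained eQTL edge (the
    potential disease genes); ``esnps`` the SNP side of those edges.
    """

    network: Network
    egenes: set[str] = field(default_factory=set)
    esnps: set[str] = field(default_factory=set)
    dropped_records: int = 0  # eQTL records whose gene is absent from interactome

    def induced(self, keep: set[str]) -> "IntegratedNetwork":
        sub = induced_subgraph(self.network, keep)
        return IntegratedNetwork(
            network=sub,
            egenes=self.egenes & set(sub.nodes()),
            esnps=self.esnps & set(sub.nodes()),
            dropped_records=self.dropped_records,
        )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """Read SNP-gene eQTL associations (TSV: snp, gene, pvalue[, tissue])."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need >=3 columns (snp, gene, pvalue)")
    df = df.iloc[:, :3].copy()
    df.columns = list(EQTL_COLUMNS)
    df["pvalue"] = df["pvalue"].astype(float)
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise ValueError(f"{path}: p-values outside [0, 1]")
    # duplicate (snp, gene) pairs keep the strongest evidence
    df = df.sort_values("pvalue", kind="stable")
    df = df.drop_duplicates(subset=["snp", "gene"], keep="first")
    return df.reset_index(drop=True)


def read_proxy_map(path: str | Path) -> dict[str, str]:
    """Read proxy-SNP -> index-SNP mapping (TSV: proxy, index).

    Index SNPs are added as self-mapping fixed points, and chained
    mappings are rejected: the image of the map must map to itself.
    """
    mapping: dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (proxy, index)")
    for proxy, index in zip(df.iloc[:, 0], df.iloc[:, 1]):
        proxy, index = proxy.strip(), index.strip()
        if proxy in mapping and mapping[proxy] != index:
            raise ValueError(f"proxy SNP {proxy!r} maps to two index SNPs")
        mapping[proxy] = index
    for index in list(mapping.values()):
        prior = mapping.setdefault(index, index)
        if prior != index:
            raise ValueError(f"chained proxy mapping through {index!r}")
    return mapping


def read_expression_table(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (gene, expression)")
    return {g.strip(): float(x) for g, x in zip(df.iloc[:, 0], df.iloc[:, 1])}


def filter_significant_eqtl(records: pd.DataFrame, fdr_cutoff: float = 0.05
                            ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep associations with BH-adjusted p <= ``fdr_cutoff``.

    Returns the surviving records plus summary counts (associations,
    distinct egenes, distinct eSNPs).
    """
    if records.empty:
        raise ValueError("empty eQTL record table")
    adj = bh_fdr(records["pvalue"].to_numpy())
    kept = records.loc[adj <= fdr_cutoff].reset_index(drop=True)
    counts = {
        "associations": int(len(kept)),
        "egenes": int(kept["gene"].nunique()),
        "esnps": int(kept["snp"].nunique()),
    }
    return kept, counts


def replace_proxies(records: pd.DataFrame, proxy_map: Mapping[str, str],
                    strict: bool = True) -> pd.DataFrame:
    """Replace each record's SNP by its index SNP.

    Duplicate (index, gene) pairs arising from several proxies of one
    index SNP hitting the same gene collapse to the minimum nominal p.
    Unmapped SNPs raise when ``strict``, else pass through unchanged.
    """
    unmapped = sorted(set(records["snp"]) - set(proxy_map))
    if unmapped and strict:
        raise KeyError(f"SNPs missing from proxy map: {unmapped[:10]}")
    out = records.copy()
    out["snp"] = out["snp"].map(lambda s: proxy_map.get(s, s))
    out = out.sort_values("pvalue", kind="stable")
    out = out.drop_duplicates(subset=["snp", "gene"], keep="first")
    return out.reset_index(drop=True)


def filter_expressed_genes(net: Network, expression: Mapping[str, float],
                           threshold: float = 0.1) -> Network:
    """Drop gene nodes expressed below ``threshold`` (absent genes count as 0).

    SNP nodes are always retained.
    """
    keep = set(net.snp_nodes)
    keep.update(g for g in net.gene_nodes
                if expression.get(g, 0.0) >= threshold)
    return induced_subgraph(net, keep)


def build_integrated_network(interactome: Network, records: pd.DataFrame,
                             eqtl_edge_weight: float = 1.0) -> IntegratedNetwork:
    """Project significant (already proxy-replaced) eQTL pairs onto the interactome.

    Records whose gene is not an interactome node are dropped and
    counted.  SNP-gene edges get weight ``eqtl_edge_weight`` and
    multi-evidence duplicates sum.
    """
    if interactome.n_nodes == 0:
        raise ValueError("empty interactome")
    net = interactome.copy()
    genes = set(net.gene_nodes)
    egenes: set[str] = set()
    esnps: set[str] = set()
    dropped = 0
    for snp, gene in zip(records["snp"], records["gene"]):
        if gene not in genes:
            dropped += 1
            continue
        if snp not in net:
            net.add_node(snp, role=SNP)
        net.add_edge(snp, gene, weight=eqtl_edge_weight, collapse="sum")
        egenes.add(gene)
        esnps.add(snp)
    return IntegratedNetwork(network=net, egenes=egenes, esnps=esnps,
                             dropped_records=dropped)
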