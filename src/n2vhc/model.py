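"""Model/Results surface over the disease-module pipeline.

``DiseaseModuleModel`` holds the integrated network and all
hyperparameters; ``fit()`` runs embedding, the iterative egene-filtered
clustering loop, and Fisher scoring, returning a
``DiseaseModuleResults`` with the module table, iteration trace,
eigen-features and a ``summary()``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .embed import EmbedParams, Embedding, WalkParams
from .graph import GeneSetCollection, Network
from .integrate import (IntegratedNetwork, build_integrated_network,
                        filter_expressed_genes, filter_significant_eqtl,
                        replace_proxies)
from .pipeline import (ModuleReport, geneset_overrepresentation,
                       iterate_module_selection, module_dendrogram,
                       module_eigen_features, score_modules)
from .treecut import CutParams, Dendrogram, ModulePartition

__all__ = ["DiseaseModuleModel", "DiseaseModuleResults"]


class DiseaseModuleModel:
    """Disease-module discovery on an egene-annotated network.

    Parameters
    ----------
    network:
        An :class:`IntegratedNetwork`, or a plain :class:`Network`
        together with an explicit ``egenes`` set.
    """

    def __init__(self, network: IntegratedNetwork | Network,
                 egenes: set[str] | None = None,
                 walk_params: WalkParams | None = None,
                 embed_params: EmbedParams | None = None,
                 cut_params: CutParams | None = None,
                 fdr_threshold: float = 0.05,
                 max_iter: int = 20,
                 reembed_each_iter: bool = False):
        if isinstance(network, IntegratedNetwork):
            self.data = network
        else:
            if egenes is None:
                raise ValueError("a plain Network needs an explicit egene set")
            self.data = IntegratedNetwork(network=network,
                                          egenes=set(egenes),
                                          esnps=network.snp_nodes)
        self.walk_params = walk_params or WalkParams()
        self.embed_params = embed_params or EmbedParams()
        self.cut_params = cut_params or CutParams()
        self.fdr_threshold = fdr_threshold
        self.max_iter = max_iter
        self.reembed_each_iter = reembed_each_iter

    @classmethod
    def from_summaries(cls, interactome: Network, eqtl: pd.DataFrame,
                       proxy_map: dict[str, str] | None = None,
                       expression: dict[str, float] | None = None,
                       expression_threshold: float = 0.1,
                       fdr_cutoff: float = 0.05,
                       eqtl_edge_weight: float = 1.0,
                       strict_proxies: bool = False,
                       **kwargs) -> "DiseaseModuleModel":
        """Build the model straight from the raw summary tables:
        proxy replacement -> BH filter -> expression filter -> projection."""
        records = eqtl
        if proxy_map is not None:
            records = replace_proxies(records, proxy_map, strict=strict_proxies)
        records, counts = filter_significant_eqtl(records, fdr_cutoff)
        net = interactome
        if expression is not None:
            net = filter_expressed_genes(net, expression, expression_threshold)
        inet = build_integrated_network(net, records,
                                        eqtl_edge_weight=eqtl_edge_weight)
        model = cls(inet, **kwargs)
        model.integration_counts = counts
        return model

    def fit(self, seed: int | None = None) -> "DiseaseModuleResults":
        """Run the full loop; ``seed`` overrides the walk/embed seeds."""
        wp, ep = self.walk_params, self.embed_params
        if seed is not None:
            from dataclasses import replace
            wp = replace(wp, seed=seed)
            ep = replace(ep, seed=seed)
        partition, trace, embedding = iterate_module_selection(
            self.data, wp, ep, self.cut_params,
            max_iter=self.max_iter, reembed_each_iter=self.reembed_each_iter)
        background = {n for n in self.data.network.gene_nodes}
        reports = score_modules(partition, self.data.egenes & background,
                                background) if len(partition) else []
        return DiseaseModuleResults(model=self, partition=partition,
                                    reports=reports, trace=trace,
                                    embedding=embedding)


class DiseaseModuleResults:
    """Fitted disease modules with enrichment statistics."""

    def __init__(self, model: DiseaseModuleModel, partition: ModulePartition,
                 reports: list[ModuleReport], trace: list[dict],
                 embedding: Embedding):
        self.model = model
        self.partition = partition
        self.reports = reports
        self.trace = trace
        self.embedding = embedding

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    @property
    def module_table(self) -> pd.DataFrame:
        rows = [{"module": r.module, "n_genes": r.n_genes,
                 "n_egenes": r.n_egenes, "pvalue": r.pvalue, "fdr": r.fdr}
                for r in self.reports]
        return pd.DataFrame(rows, columns=["module", "n_genes", "n_egenes",
                                           "pvalue", "fdr"])

    def significant_modules(self, fdr: float | None = None) -> list[ModuleReport]:
        cut = self.model.fdr_threshold if fdr is None else fdr
        return [r for r in self.reports if r.fdr <= cut]

    def module_eigen_features(self) -> dict[int, np.ndarray]:
        return module_eigen_features(self.partition, self.embedding)

    def module_dendrogram(self) -> Dendrogram:
        return module_dendrogram(self.module_eigen_features())

    def plot_module_dendrogram(self, ax=None):
        """Render the module-level tree (1 - Pearson distance)."""
        from .plotting import plot_dendrogram
        return plot_dendrogram(self.module_dendrogram(), ax=ax)

    def annotate(self, module: int, collection: GeneSetCollection,
                 top_k: int = 50) -> pd.DataFrame:
        background = set(self.model.data.network.gene_nodes)
        genes = {n for n in self.partition.members(module)
                 if n in background}
        return geneset_overrepresentation(genes, collection, background, top_k)

    def summary(self) -> str:
        lines = ["Disease module discovery results",
                 "=" * 34,
                 f"iterations to convergence: {self.n_iterations}",
                 f"candidate modules (>=1 egene): {self.partition.n_modules}",
                 f"significant modules (FDR <= {self.model.fdr_threshold:g}): "
                 f"{len(self.significant_modules())}",
                 "",
                 f"{'module':>6} {'#gene':>6} {'#egene':>7} "
                 f"{'p-value':>10} {'FDR':>10}"]
        for r in self.reports:
            lines.append(f"{r.module:>6} {r.n_genes:>6} {r.n_egenes:>7} "
                         f"{r.pvalue:>10.3g} {r.fdr:>10.3g}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.module_table.to_csv(outdir / "modules.tsv", sep="\t", index=False)
        with open(outdir / "partition.tsv", "w") as fh:
            for node in sorted(self.partition.labels):
                fh.write(f"{node}\t{self.partition.labels[node]}\n")
        with open(outdir / "trace.json", "w") as fh:
            json.dump(self.trace, fh, indent=2)
        if self.partition.n_modules >= 2:
            with open(outdir / "module_dendrogram.nwk", "w") as fh:
                fh.write(self.module_dendrogram().to_newick() + "\n")
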