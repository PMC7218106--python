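"""Graph data model and file I/O shared by the whole pipeline.

Nodes are opaque string ids tagged with a *role*: ``"gene"`` (default) or
``"snp"``.  Role tags let downstream enrichment restrict backgrounds to
genes while SNP nodes still participate in walks and clustering.  Storage
is a thin wrapper over :mod:`networkx`; edges carry a positive ``weight``
(default 1.0), duplicate edges are collapsed at construction time and
self-loops are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

GENE = "gene"
SNP = "snp"

__all__ = [
    "Network",
    "GeneSet",
    "GeneSetCollection",
    "read_edge_list",
    "write_edge_list",
    "read_node_labels",
    "write_node_labels",
    "read_gmt",
    "induced_subgraph",
]


class Network:
    """A node-labeled, optionally weighted/directed graph.

    Parameters
    ----------
    directed:
        Store edges as arcs.  Undirected by default; benchmarks that ship
        directed edges may opt in.
    """

    def __init__(self, directed: bool = False):
        self.g: nx.Graph = nx.DiGraph() if directed else nx.Graph()

    # -- construction -------------------------------------------------
    def add_node(self, node: str, role: str = GENE) -> None:
        if role not in (GENE, SNP):
            raise ValueError(f"unknown node role {role!r}")
        self.g.add_node(str(node), role=role)

    def add_edge(self, u: str, v: str, weight: float = 1.0,
                 collapse: str = "max") -> None:
        """Add an edge, collapsing duplicates.

        ``collapse`` is ``"max"`` (replicated interactome lines are
        redundant evidence) or ``"sum"`` (multi-evidence accumulation,
        used for eQTL edges).
        """
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        w = float(weight)
        if w <= 0:
            raise ValueError(f"non-positive edge weight {w} on ({u}, {v})")
        for n in (u, v):
            if n not in self.g:
                self.g.add_node(n, role=GENE)
        if self.g.has_edge(u, v):
            old = self.g[u][v]["weight"]
            self.g[u][v]["weight"] = old + w if collapse == "sum" else max(old, w)
        else:
            self.g.add_edge(u, v, weight=w)

    # -- queries -------------------------------------------------------
    @property
    def directed(self) -> bool:
        return self.g.is_directed()

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self) -> list[str]:
        return list(self.g.nodes)

    def role(self, node: str) -> str:
        return self.g.nodes[node].get("role", GENE)

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.g.nodes(data=True)
                if d.get("role", GENE) == role}

    @property
    def gene_nodes(self) -> set[str]:
        return self.nodes_with_role(GENE)

    @property
    def snp_nodes(self) -> set[str]:
        return self.nodes_with_role(SNP)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, d in self.g.edges(data=True):
            yield u, v, d.get("weight", 1.0)

    def density(self) -> float:
        return nx.density(self.g)

    def degree(self, node: str) -> int:
        return self.g.degree(node)

    def __contains__(self, node: str) -> bool:
        return node in self.g

    def __repr__(self) -> str:  # pragma: no cover
        kind = "directed" if self.directed else "undirected"
        return f"<Network {kind}: {self.n_nodes} nodes, {self.n_edges} edges>"

    def copy(self) -> "Network":
        out = Network(directed=self.directed)
        out.g = self.g.copy()
        return out

    @classmethod
    def from_networkx(cls, g: nx.Graph, role: str = GENE) -> "Network":
        """Wrap an existing networkx graph; missing weights become 1.0."""
        net = cls(directed=g.is_directed())
        for n, d in g.nodes(data=True):
            net.add_node(str(n), role=d.get("role", role))
        for u, v, d in g.edges(data=True):
            net.add_edge(str(u), str(v), weight=float(d.get("weight", 1.0)))
        return net


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets parsed from a GMT file (MSigDB dialect)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping blanks and '#' comments."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def read_edge_list(path: str | Path, directed: bool = False,
                   weighted: bool = False, collapse: str = "max") -> Network:
    """Read a TSV/whitespace edge list ``u v [w]`` into a :class:`Network`.

    A missing weight column defaults to 1.0; when ``weighted`` the third
    column must parse as a positive number.  Malformed lines raise with
    the offending line number.
    """
    net = Network(directed=directed)
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns, "
                             f"got {len(parts)}")
        u, v = parts[0].strip(), parts[1].strip()
        w = 1.0
        if weighted and len(parts) >= 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: weight {parts[2]!r} is not numeric") from exc
        if w <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
        net.add_edge(u, v, weight=w, collapse=collapse)
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a canonicalized (sorted) tab-separated edge list with weights."""
    rows = sorted((u, v, w) if net.directed or u <= v else (v, u, w)
                  for u, v, w in net.edges())
    with open(path, "w") as fh:
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.17g}\n")
        # isolated nodes survive the round trip as degenerate comment records
        isolated = sorted(n for n in net.nodes() if net.g.degree(n) == 0)
        for n in isolated:
            fh.write(f"# node\t{n}\n")


def read_node_labels(path: str | Path) -> dict[str, int]:
    """Read ground-truth community labels (TSV: node, community id).

    Community ids are normalized to a contiguous 1..K range preserving
    the order of first appearance.
    """
    raw: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        node = parts[0].strip()
        if node in raw:
            raise ValueError(f"{path}:{lineno}: duplicate node {node!r}")
        raw[node] = int(parts[1])
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for node, c in raw.items():
        if c not in remap:
            remap[c] = len(remap) + 1
        out[node] = remap[c]
    return out


def write_node_labels(labels: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for node in sorted(labels):
            fh.write(f"{node}\t{labels[node]}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
        name, desc = parts[0].strip(), parts[1].strip()
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        seen.add(name)
        members = frozenset(m.strip() for m in parts[2:] if m.strip())
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets.append(GeneSet(name, desc, members))
    return GeneSetCollection(sets)


def induced_subgraph(net: Network, keep: Iterable[str]) -> Network:
    """Subgraph on ``keep``: exactly those nodes plus edges internal to them."""
    keep = set(keep)
    unknown = keep - set(net.g.nodes)
    if unknown:
        raise KeyError(f"unknown node ids in keep set: {sorted(unknown)[:5]}")
    out = Network(directed=net.directed)
    for n in keep:
        out.add_node(n, role=net.role(n))
    for u, v, w in net.edges():
        if u in keep and v in keep:
            out.add_edge(u, v, weight=w)
    return out
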