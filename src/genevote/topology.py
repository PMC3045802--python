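"""The 12 per-gene network topological features.

Feature semantics on the integrated network:

* ``ppi``, ``metin``, ``metout``, ``regin``, ``regout`` — per-layer degree
  centralities (distinct partners; in/out split for the directed layers).
* ``c`` — clustering coefficient on the undirected projection of all layers.
* ``identicalness`` — number of genes (including the gene itself) whose
  other 11 feature values are identical after rounding reals to 9 decimals.
* ``cent`` — closeness, measured as the mean shortest-path length from the
  gene to every gene reachable from it on the combined graph (ppi edges
  traversable both ways, metabolic/regulatory direction-respecting); 0 when
  nothing is reachable.
* ``inbet``, ``inbetppi``, ``inbetmet``, ``inbetreg`` — unnormalized
  betweenness on the combined graph and on each single layer.  Source-target
  pairs are ordered when any directed edge participates and unordered on a
  pure-undirected graph.

Shortest-path centralities run on python-igraph (C core); everything else
is computed directly from the edge sets (clustering through networkx on the
undirected projection).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import igraph as ig
import networkx as nx
import numpy as np

from .network import IntegratedNetwork

#: canonical feature column order, used everywhere downstream
TOPOLOGY_COLUMNS = (
    "ppi",
    "metin",
    "metout",
    "regin",
    "regout",
    "c",
    "identicalness",
    "cent",
    "inbet",
    "inbetppi",
    "inbetmet",
    "inbetreg",
)

#: decimals kept when comparing feature vectors for identicalness
IDENTICALNESS_DECIMALS = 9

BETWEENNESS_SCOPES = ("all", "ppi", "metabolic", "regulatory")


@dataclass(frozen=True)
class TopologyFeatures:
    gene: str
    ppi: int = 0
    metin: int = 0
    metout: int = 0
    regin: int = 0
    regout: int = 0
    c: float = 0.0
    identicalness: int = 1
    cent: float = 0.0
    inbet: float = 0.0
    inbetppi: float = 0.0
    inbetmet: float = 0.0
    inbetreg: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TOPOLOGY_COLUMNS}


def _check_gene(net: IntegratedNetwork, gene: str) -> None:
    if gene not in net.genes:
        raise KeyError(f"gene {gene!r} not in network")


def degree_features(net: IntegratedNetwork, gene: str) -> tuple[int, int, int, int, int]:
    """(ppi, metin, metout, regin, regout) — distinct-partner counts per layer."""
    _check_gene(net, gene)
    ppi_partners: set[str] = set()
    met_in: set[str] = set()
    met_out: set[str] = set()
    reg_in: set[str] = set()
    reg_out: set[str] = set()
    for e in net.edges:
        if e.layer == "ppi":
            if e.source == gene:
                ppi_partners.add(e.target)
            elif e.target == gene:
                ppi_partners.add(e.source)
        elif e.layer == "metabolic":
            if e.target == gene:
                met_in.add(e.source)
            if e.source == gene:
                met_out.add(e.target)
        else:
            if e.target == gene:
                reg_in.add(e.source)
            if e.source == gene:
                reg_out.add(e.target)
    return len(ppi_partners), len(met_in), len(met_out), len(reg_in), len(reg_out)


def _undirected_projection(net: IntegratedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.genes)
    g.add_edges_from((e.source, e.target) for e in net.edges)
    return g


def clustering_coefficient(net: IntegratedNetwork, gene: str) -> float:
    """Neighbor-pair link density on the undirected projection; 0 if < 2 neighbors."""
    _check_gene(net, gene)
    return float(nx.clustering(_undirected_projection(net), gene))


def _combined_directed_edges(net: IntegratedNetwork) -> set[tuple[str, str]]:
    edges: set[tuple[str, str]] = set()
    for e in net.edges:
        edges.add((e.source, e.target))
        if e.layer == "ppi":
            edges.add((e.target, e.source))
    return edges


def _igraph(
    genes: Sequence[str], edges: Iterable[tuple[str, str]], directed: bool
) -> ig.Graph:
    index = {g: i for i, g in enumerate(genes)}
    if not directed:
        edges = {tuple(sorted(e)) for e in edges}
    g = ig.Graph(directed=directed)
    g.add_vertices(len(genes))
    g.add_edges([(index[u], index[v]) for u, v in sorted(edges)])
    return g


def _scope_graph(net: IntegratedNetwork, scope: str) -> tuple[list[str], ig.Graph]:
    """Graph for a betweenness scope, over all network genes."""
    genes = sorted(net.genes)
    if scope == "all":
        directed_part = [e for e in net.edges if e.layer != "ppi"]
        if directed_part:
            return genes, _igraph(genes, _combined_directed_edges(net), directed=True)
        ppi = [(e.source, e.target) for e in net.edges]
        return genes, _igraph(genes, ppi, directed=False)
    if scope == "ppi":
        ppi = [(e.source, e.target) for e in net.layer_edges("ppi")]
        return genes, _igraph(genes, ppi, directed=False)
    if scope in ("metabolic", "regulatory"):
        layer = [(e.source, e.target) for e in net.layer_edges(scope)]
        return genes, _igraph(genes, layer, directed=True)
    raise ValueError(f"unknown scope {scope!r}")


def betweenness_centrality(net: IntegratedNetwork, scope: str = "all") -> dict[str, float]:
    """Unnormalized betweenness per gene for one scope (see module docstring)."""
    genes, graph = _scope_graph(net, scope)
    values = graph.betweenness(directed=graph.is_directed())
    return {g: float(v) for g, v in zip(genes, values)}


def _combined_graph(net: IntegratedNetwork) -> tuple[list[str], ig.Graph]:
    genes = sorted(net.genes)
    return genes, _igraph(genes, _combined_directed_edges(net), directed=True)


def closeness_centrality(net: IntegratedNetwork, gene: str) -> float:
    """Mean shortest-path length to reachable genes; 0 when none is reachable."""
    _check_gene(net, gene)
    genes, graph = _combined_graph(net)
    dist = np.asarray(graph.distances(source=[genes.index(gene)], mode="out")[0], dtype=float)
    dist[genes.index(gene)] = np.inf
    reachable = np.isfinite(dist)
    if not reachable.any():
        return 0.0
    return float(dist[reachable].mean())


def _closeness_all(net: IntegratedNetwork, block: int = 512) -> dict[str, float]:
    genes, graph = _combined_graph(net)
    out: dict[str, float] = {}
    for start in range(0, len(genes), block):
        rows = list(range(start, min(start + block, len(genes))))
        dist = np.asarray(graph.distances(source=rows, mode="out"), dtype=float)
        for local, idx in enumerate(rows):
            d = dist[local]
            d[idx] = np.inf
            reachable = np.isfinite(d)
            out[genes[idx]] = float(d[reachable].mean()) if reachable.any() else 0.0
    return out


def identicalness(features: Sequence[TopologyFeatures]) -> dict[str, int]:
    """Count, per gene, the genes sharing its 11-value topology vector.

    The gene itself counts, so every value is >= 1; real-valued features are
    rounded to :data:`IDENTICALNESS_DECIMALS` decimals before comparison.
    """
    keys: dict[str, tuple] = {}
    counts: dict[tuple, int] = {}
    for f in features:
        key = tuple(
            round(float(getattr(f, name)), IDENTICALNESS_DECIMALS)
            for name in TOPOLOGY_COLUMNS
            if name != "identicalness"
        )
        keys[f.gene] = key
        counts[key] = counts.get(key, 0) + 1
    return {gene: counts[key] for gene, key in keys.items()}


def compute_topology_table(net: IntegratedNetwork) -> list[TopologyFeatures]:
    """All 12 features for every gene of the network, sorted by gene id."""
    genes = sorted(net.genes)

    adjacency: dict[str, dict[str, set[str]]] = {
        k: {g: set() for g in genes}
        for k in ("ppi", "metin", "metout", "regin", "regout")
    }
    for e in net.edges:
        if e.layer == "ppi":
            adjacency["ppi"][e.source].add(e.target)
            adjacency["ppi"][e.target].add(e.source)
        elif e.layer == "metabolic":
            adjacency["metout"][e.source].add(e.target)
            adjacency["metin"][e.target].add(e.source)
        else:
            adjacency["regout"][e.source].add(e.target)
            adjacency["regin"][e.target].add(e.source)

    clustering = nx.clustering(_undirected_projection(net))
    closeness = _closeness_all(net)
    betweenness = {scope: betweenness_centrality(net, scope) for scope in BETWEENNESS_SCOPES}

    rows = [
        TopologyFeatures(
            gene=g,
            ppi=len(adjacency["ppi"][g]),
            metin=len(adjacency["metin"][g]),
            metout=len(adjacency["metout"][g]),
            regin=len(adjacency["regin"][g]),
            regout=len(adjacency["regout"][g]),
            c=float(clustering[g]),
            cent=closeness[g],
            inbet=betweenness["all"][g],
            inbetppi=betweenness["ppi"][g],
            inbetmet=betweenness["metabolic"][g],
            inbetreg=betweenness["regulatory"][g],
        )
        for g in genes
    ]
    ident = identicalness(rows)
    return [replace(r, identicalness=ident[r.gene]) for r in rows]


def write_topology_table(rows: Sequence[TopologyFeatures], path) -> None:
    """TSV with columns gene + the 12 features in canonical order."""
    from pathlib import Path

    lines = ["gene\t" + "\t".join(TOPOLOGY_COLUMNS)]
    for r in rows:
        lines.append(
            r.gene + "\t" + "\t".join(repr(float(v)) for v in r.as_dict().values())
        )
    Path(path).write_text("\n".join(lines) + "\n")
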