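"""Construction of the integrated gene-interaction network.

The network is the union of three interaction layers over a shared gene-id
space: an undirected protein-physical layer (ppi), a directed metabolic
layer (enzyme g1 -> enzyme g2 whenever a product of a reaction catalyzed by
g1 is a reactant of a reaction catalyzed by g2, after removing currency
metabolites), and a directed transcriptional-regulation layer (TF ->
regulated gene).  Self-loops are excluded in every layer and within a layer
each ordered (or, for ppi, unordered) gene pair appears at most once.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import InteractionRecord, ReactionRecord

#: the eight most connected metabolites of the human metabolic reconstruction,
#: removed by default before deriving enzyme-enzyme interactions
DEFAULT_CURRENCY_METABOLITES = (
    "ADP",
    "ATP",
    "H+",
    "H2O",
    "NADP+",
    "NADPH",
    "orthophosphate",
    "pyrophosphate",
)


@dataclass
class IntegratedNetwork:
    """Multi-layer gene graph: ppi undirected, metabolic/regulatory directed."""

    genes: set[str] = field(default_factory=set)
    edges: set[InteractionRecord] = field(default_factory=set)

    def layer_edges(self, layer: str) -> set[InteractionRecord]:
        return {e for e in self.edges if e.layer == layer}

    def validate(self) -> None:
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-loop on {e.source!r}")
            if e.source not in self.genes or e.target not in self.genes:
                raise ValueError(f"edge endpoint outside gene set: {e}")
            if e.layer == "ppi" and e.source > e.target:
                raise ValueError(f"non-canonical ppi edge {e}")


@dataclass
class BuildSummary:
    """Bookkeeping emitted alongside an assembled network."""

    layer_counts: dict[str, int] = field(default_factory=dict)
    dropped_unmapped: int = 0
    dropped_self_loops: int = 0
    collapsed_duplicates: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def normalize_ids(
    records: Sequence[InteractionRecord],
    idmap: Mapping[str, str],
    summary: BuildSummary | None = None,
) -> list[InteractionRecord]:
    """Map gene names/synonyms to canonical ids, dropping what cannot map.

    Records with an unmapped endpoint are dropped (and counted), records that
    become self-loops after mapping are dropped, and duplicates arising from
    many-to-one synonym collapse are re-collapsed.
    """
    summary = summary if summary is not None else BuildSummary()
    out: list[InteractionRecord] = []
    seen: set[InteractionRecord] = set()
    for rec in records:
        src = idmap.get(rec.source)
        tgt = idmap.get(rec.target)
        if src is None or tgt is None:
            summary.dropped_unmapped += 1
            continue
        if src == tgt:
            summary.dropped_self_loops += 1
            continue
        mapped = InteractionRecord.create(src, tgt, rec.layer)
        if mapped in seen:
            summary.collapsed_duplicates += 1
            continue
        seen.add(mapped)
        out.append(mapped)
    return out


def select_currency_metabolites(
    reactions: Sequence[ReactionRecord], k: int
) -> list[str]:
    """The k metabolites taking part (as reactant or product) in the most reactions.

    Ties break lexicographically.  The pipeline default is the fixed
    :data:`DEFAULT_CURRENCY_METABOLITES` list; this data-driven alternative
    exists because "most connected" is how that list was originally chosen.
    """
    counts: Counter[str] = Counter()
    for r in reactions:
        for m in r.reactants | r.products:
            counts[m] += 1
    if k > len(counts):
        raise ValueError(f"k={k} exceeds {len(counts)} distinct metabolites")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [m for m, _ in ranked[:k]]


def derive_metabolic_interactions(
    reactions: Sequence[ReactionRecord],
    currency: Iterable[str] = DEFAULT_CURRENCY_METABOLITES,
) -> list[InteractionRecord]:
    """Directed enzyme-enzyme edges from shared non-currency metabolites.

    Edge g1 -> g2 whenever some reaction catalyzed by g1 produces metabolite
    m, some reaction catalyzed by g2 consumes m, and m is not a currency
    metabolite.  Self-edges are excluded, duplicates collapsed.
    """
    currency = set(currency)
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for r in reactions:
        if not r.genes:
            continue
        for m in r.products - currency:
            producers.setdefault(m, set()).update(r.genes)
        for m in r.reactants - currency:
            consumers.setdefault(m, set()).update(r.genes)
    edges: set[tuple[str, str]] = set()
    for m, prods in producers.items():
        cons = consumers.get(m)
        if not cons:
            continue
        for g1 in prods:
            for g2 in cons:
                if g1 != g2:
                    edges.add((g1, g2))
    return [
        InteractionRecord(src, tgt, "metabolic") for src, tgt in sorted(edges)
    ]


def assemble_network(
    ppi: Sequence[InteractionRecord],
    metabolic: Sequence[InteractionRecord],
    regulatory: Sequence[InteractionRecord],
) -> IntegratedNetwork:
    """Union of the three layers over the union of their genes.

    Layer tags are preserved, so the same gene pair may carry one edge per
    layer.  Self-loops are dropped; within a layer duplicates collapse.
    """
    net = IntegratedNetwork()
    for records, layer in ((ppi, "ppi"), (metabolic, "metabolic"), (regulatory, "regulatory")):
        for rec in records:
            if rec.layer != layer:
                raise ValueError(f"record {rec} passed as {layer} layer")
            if rec.source == rec.target:
                continue
            canon = InteractionRecord.create(rec.source, rec.target, layer)
            net.edges.add(canon)
            net.genes.add(canon.source)
            net.genes.add(canon.target)
    net.validate()
    return net


def write_edge_list(net: IntegratedNetwork, path: str | Path) -> None:
    """Emit the assembled network as a sorted (source, target, layer) TSV."""
    lines = ["source\ttarget\tlayer"]
    lines += [
        f"{e.source}\t{e.target}\t{e.layer}"
        for e in sorted(net.edges, key=lambda e: (e.layer, e.source, e.target))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def build_summary(net: IntegratedNetwork, base: BuildSummary | None = None) -> BuildSummary:
    """Fill per-layer edge counts into a build summary."""
    summary = base if base is not None else BuildSummary()
    summary.layer_counts = {
        layer: len(net.layer_edges(layer)) for layer in ("ppi", "metabolic", "regulatory")
    }
    return summary
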