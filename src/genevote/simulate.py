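"""Synthetic multi-layer networks, annotations, expression, and planted labels.

The generator emulates the statistical shape of the data the method was
designed for: a heavy-tailed undirected protein-interaction layer
(preferential attachment), a directed regulatory layer radiating from a
small set of transcription-factor hubs, a metabolic layer realized as
reaction chains (so enzyme-enzyme edges arise through the same
product-to-reactant derivation the real pipeline uses, currency metabolites
included), multi-hot subcellular localization draws, and 32-tissue
log-normal tpm expression with per-gene tissue-breadth control.

Class labels are planted on the extracted feature columns through a
logistic model: after within-column standardization,
P(positive) = sigmoid(beta0 + beta . x), with beta0 auto-calibrated so the
expected prevalence matches the target.  Planting on post-extraction
columns makes ground-truth signal and rule recovery exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .features import (
    LOCALIZATION_CATEGORIES,
    UNKNOWN_CATEGORY,
    assemble_feature_matrix,
    expression_features,
    localization_features,
)
from .io import AnnotationRecord, ExpressionProfile, InteractionRecord, ReactionRecord
from .network import (
    DEFAULT_CURRENCY_METABOLITES,
    IntegratedNetwork,
    assemble_network,
    derive_metabolic_interactions,
)
from .topology import compute_topology_table

#: rough per-compartment annotation frequencies (multi-hot, independent draws)
DEFAULT_LOCALIZATION_PROBS = {
    "Cytoplasm": 0.40,
    "Nucleus": 0.33,
    "Plasma membrane": 0.26,
    "Mitochondrion": 0.12,
    "Endoplasmic reticulum": 0.08,
    "Extracellular space": 0.10,
    "Golgi apparatus": 0.06,
    "Cellular component": 0.08,
    "Other localization": 0.10,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study (network, annotations, label model)."""

    n_genes: int = 2000
    seed: int = 0
    # ppi layer: preferential attachment with this many edges per new gene
    ppi_attachment: int = 4
    # regulatory layer: TF hubs with 1 + Poisson(tf_out_mean - 1) targets each
    n_tf: int = 60
    tf_out_mean: float = 10.0
    # metabolic layer: reaction chains over a shared metabolite pool
    n_reactions: int = 600
    chain_length_mean: float = 5.0
    enzyme_fraction: float = 0.3
    currency_probability: float = 0.3
    # localization and expression
    localization_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCALIZATION_PROBS)
    )
    unannotated_probability: float = 0.15
    n_tissues: int = 32
    breadth_alpha: float = 0.6
    breadth_beta: float = 0.9
    expressed_log_mean: float = 3.0
    expressed_log_sd: float = 1.0
    background_log_mean: float = 0.0
    background_log_sd: float = 0.7
    # label model
    beta: Mapping[str, float] = field(default_factory=dict)
    beta0: float | None = None  # auto-calibrated when None
    prevalence: float = 0.14

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 0.5:
            raise ValueError("prevalence must lie in (0, 0.5]")
        if self.n_tf > self.n_genes:
            raise ValueError("n_tf cannot exceed n_genes")
        for name, p in self.localization_probs.items():
            if name not in LOCALIZATION_CATEGORIES or name == UNKNOWN_CATEGORY:
                raise ValueError(f"bad localization category {name!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of range for {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def morbidity_like(**overrides) -> SyntheticSpec:
    """Morbidity-flavored study: effects on regin, inbetmet, extracellular space."""
    defaults = dict(
        beta={"regin": 3.0, "inbetmet": 1.0, "Extracellular space": 1.0},
        prevalence=0.14,
        seed=11,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def druggability_like(**overrides) -> SyntheticSpec:
    """Druggability-flavored study: effects on plasma membrane, inbetreg, metin."""
    defaults = dict(
        beta={"Plasma membrane": 3.0, "inbetreg": 1.0, "metin": 1.0},
        prevalence=0.05,
        seed=13,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_network(
    spec: SyntheticSpec,
) -> tuple[IntegratedNetwork, list[ReactionRecord]]:
    """Three-layer network plus the reaction table its metabolic layer came from."""
    rng = np.random.default_rng([spec.seed, 1])
    genes = _gene_ids(spec.n_genes)

    ba = nx.barabasi_albert_graph(
        spec.n_genes, spec.ppi_attachment, seed=int(rng.integers(2**31))
    )
    ppi = [
        InteractionRecord.create(genes[u], genes[v], "ppi") for u, v in ba.edges()
    ]

    regulatory: list[InteractionRecord] = []
    if spec.n_tf > 0:
        tfs = rng.choice(spec.n_genes, size=spec.n_tf, replace=False)
        for tf in tfs:
            k = 1 + rng.poisson(max(spec.tf_out_mean - 1, 0))
            targets = rng.choice(spec.n_genes, size=min(k, spec.n_genes - 1), replace=False)
            for t in targets:
                if t != tf:
                    regulatory.append(
                        InteractionRecord(genes[tf], genes[t], "regulatory")
                    )

    reactions = _generate_reactions(spec, genes, rng)
    metabolic = derive_metabolic_interactions(reactions, DEFAULT_CURRENCY_METABOLITES)

    net = assemble_network(ppi, metabolic, regulatory)
    # genes untouched by any layer still belong to the study
    net.genes.update(genes)
    return net, reactions


def _generate_reactions(
    spec: SyntheticSpec, genes: Sequence[str], rng: np.random.Generator
) -> list[ReactionRecord]:
    """Reaction chains: each reaction consumes its predecessor's product."""
    n_enzymes = max(int(spec.enzyme_fraction * spec.n_genes), 1)
    enzymes = rng.choice(spec.n_genes, size=n_enzymes, replace=False)
    reactions: list[ReactionRecord] = []
    metabolite_counter = 0
    r = 0
    while r < spec.n_reactions:
        length = 1 + rng.geometric(1.0 / max(spec.chain_length_mean, 1.0))
        substrate = f"M{metabolite_counter:05d}"
        metabolite_counter += 1
        for _ in range(min(length, spec.n_reactions - r)):
            product = f"M{metabolite_counter:05d}"
            metabolite_counter += 1
            gene = genes[int(rng.choice(enzymes))]
            reactants, products = {substrate}, {product}
            if rng.random() < spec.currency_probability:
                pair = rng.integers(len(DEFAULT_CURRENCY_METABOLITES) // 2)
                reactants.add(DEFAULT_CURRENCY_METABOLITES[2 * pair])
                products.add(DEFAULT_CURRENCY_METABOLITES[2 * pair + 1])
            reactions.append(
                ReactionRecord(
                    reaction_id=f"R{r:05d}",
                    genes=frozenset({gene}),
                    reactants=frozenset(reactants),
                    products=frozenset(products),
                )
            )
            substrate = product
            r += 1
    return reactions


def generate_annotations_expression(
    spec: SyntheticSpec, genes: Sequence[str]
) -> tuple[list[AnnotationRecord], list[ExpressionProfile]]:
    """Localization draws and 32-tissue log-normal tpm profiles per gene."""
    rng = np.random.default_rng([spec.seed, 2])
    genes = sorted(genes)
    categories = list(spec.localization_probs)
    probs = np.array([spec.localization_probs[c] for c in categories])

    annotations: list[AnnotationRecord] = []
    for gene in genes:
        if rng.random() < spec.unannotated_probability:
            continue  # stays "Unknown"
        flags = rng.random(len(categories)) < probs
        if not flags.any():
            flags[rng.choice(len(categories), p=probs / probs.sum())] = True
        for c, on in zip(categories, flags):
            if on:
                annotations.append(AnnotationRecord(gene, c))

    profiles: list[ExpressionProfile] = []
    for gene in genes:
        breadth = rng.beta(spec.breadth_alpha, spec.breadth_beta)
        expressed = rng.random(spec.n_tissues) < breadth
        tpm = rng.lognormal(spec.background_log_mean, spec.background_log_sd, spec.n_tissues)
        tpm[expressed] = rng.lognormal(
            spec.expressed_log_mean, spec.expressed_log_sd, int(expressed.sum())
        )
        profiles.append(ExpressionProfile(gene, tuple(float(v) for v in tpm)))
    return annotations, profiles


def generate_feature_matrix(spec: SyntheticSpec) -> pd.DataFrame:
    """Full pipeline run on one synthetic study: network -> topology -> matrix."""
    net, _ = generate_network(spec)
    annotations, profiles = generate_annotations_expression(spec, net.genes)
    topo = compute_topology_table(net)
    loc = localization_features(annotations, genes=net.genes)
    expr = [expression_features(p) for p in profiles]
    return assemble_feature_matrix(topo, loc, expr, genes=net.genes)


def _standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def plant_labels(matrix: pd.DataFrame, spec: SyntheticSpec) -> list[str]:
    """Bernoulli labels from a logistic model on standardized feature columns.

    Returns the positive gene list; the intercept is bisected so the model's
    expected prevalence equals the target (unless ``spec.beta0`` is set).
    """
    missing = [name for name in spec.beta if name not in matrix.columns]
    if missing:
        raise KeyError(f"label-model features absent from matrix: {missing}")
    z = _standardize(matrix)
    linear = np.zeros(len(matrix))
    for name, coef in spec.beta.items():
        linear += coef * z[name].to_numpy()

    if spec.beta0 is not None:
        beta0 = spec.beta0
    else:
        lo, hi = -30.0, 30.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if _sigmoid(mid + linear).mean() < spec.prevalence:
                lo = mid
            else:
                hi = mid
        beta0 = (lo + hi) / 2

    rng = np.random.default_rng([spec.seed, 3])
    draws = rng.random(len(matrix)) < _sigmoid(beta0 + linear)
    return [g for g, positive in zip(matrix.index, draws) if positive]


def generate_study(spec: SyntheticSpec) -> tuple[pd.DataFrame, list[str]]:
    """Feature matrix plus planted positive list for one synthetic study."""
    matrix = generate_feature_matrix(spec)
    return matrix, plant_labels(matrix, spec)


def write_study_tables(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write every pipeline input table for one synthetic study to a directory."""
    from .io import SET_DELIMITER

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, reactions = generate_network(spec)
    annotations, profiles = generate_annotations_expression(spec, net.genes)

    paths = {}
    paths["interactions"] = out / "interactions.tsv"
    lines = ["source\ttarget\tlayer"]
    lines += [
        f"{e.source}\t{e.target}\t{e.layer}"
        for e in sorted(net.edges, key=lambda e: (e.layer, e.source, e.target))
    ]
    paths["interactions"].write_text("\n".join(lines) + "\n")

    paths["reactions"] = out / "reactions.tsv"
    lines = ["reaction_id\tgenes\treactants\tproducts"]
    for r in reactions:
        lines.append(
            "\t".join(
                [
                    r.reaction_id,
                    SET_DELIMITER.join(sorted(r.genes)),
                    SET_DELIMITER.join(sorted(r.reactants)),
                    SET_DELIMITER.join(sorted(r.products)),
                ]
            )
        )
    paths["reactions"].write_text("\n".join(lines) + "\n")

    paths["annotations"] = out / "annotations.tsv"
    lines = ["gene\tterm"]
    lines += [f"{a.gene}\t{a.term}" for a in annotations]
    paths["annotations"].write_text("\n".join(lines) + "\n")

    paths["expression"] = out / "expression.tsv"
    header = "gene\t" + "\t".join(f"t{i + 1}" for i in range(spec.n_tissues))
    lines = [header]
    lines += [
        p.gene + "\t" + "\t".join(repr(v) for v in p.tpm) for p in profiles
    ]
    paths["expression"].write_text("\n".join(lines) + "\n")

    matrix, positives = generate_study(replace(spec, seed=spec.seed))
    paths["labels"] = out / "labels.txt"
    paths["labels"].write_text("\n".join(positives) + "\n")
    return paths
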