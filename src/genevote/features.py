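"""Localization and expression learning attributes, and the full feature matrix.

The matrix holds, per gene, 24 attributes in a fixed order: the 12 network
topological features, two tissue-expression summaries (``numtissuesexp``,
``avegexptec``), and ten binary subcellular-localization flags derived from
GO-slim cellular-component terms.  A gene with no localization annotation
carries ``Unknown``; terms outside the eight named compartments map to
``Other localization`` through a remap table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationRecord, ExpressionProfile, FormatError
from .topology import TOPOLOGY_COLUMNS, TopologyFeatures

#: the ten localization categories, in column order
LOCALIZATION_CATEGORIES = (
    "Cytoplasm",
    "Endoplasmic reticulum",
    "Mitochondrion",
    "Nucleus",
    "Extracellular space",
    "Golgi apparatus",
    "Plasma membrane",
    "Cellular component",
    "Other localization",
    "Unknown",
)

#: fallback category for terms a remap table does not cover
OTHER_CATEGORY = "Other localization"
UNKNOWN_CATEGORY = "Unknown"

#: expression "expressed in a tissue" cutoff, transcripts per million
TPM_THRESHOLD = 5.0

EXPRESSION_COLUMNS = ("numtissuesexp", "avegexptec")

#: all 24 learning attributes, in canonical order
FEATURE_COLUMNS = TOPOLOGY_COLUMNS + EXPRESSION_COLUMNS + LOCALIZATION_CATEGORIES

#: identity remap for annotations already expressed as category names
IDENTITY_REMAP: dict[str, str] = {
    c.lower(): c for c in LOCALIZATION_CATEGORIES if c != UNKNOWN_CATEGORY
}


@dataclass(frozen=True)
class LocalizationFeatures:
    """Multi-hot localization flags; ``Unknown`` excludes all other flags."""

    gene: str
    flags: tuple[int, ...]  # aligned with LOCALIZATION_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.flags) != len(LOCALIZATION_CATEGORIES) or any(
            f not in (0, 1) for f in self.flags
        ):
            raise ValueError("flags must be one binary value per category")
        unknown = self.flags[LOCALIZATION_CATEGORIES.index(UNKNOWN_CATEGORY)]
        if unknown and sum(self.flags) != 1:
            raise ValueError("Unknown flag excludes all other categories")
        if sum(self.flags) == 0:
            raise ValueError("at least one localization flag must be set")


@dataclass(frozen=True)
class ExpressionFeatures:
    gene: str
    numtissuesexp: int
    avegexptec: float

    def __post_init__(self) -> None:
        if self.numtissuesexp == 0 and self.avegexptec != 0:
            raise ValueError("a gene expressed in no tissue has zero average tpm")


def read_remap(path: str | Path) -> dict[str, str]:
    """term -> category table (TSV with columns term, category)."""
    remap = {}
    with Path(path).open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if not reader.fieldnames or not {"term", "category"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns term, category")
        for row in reader:
            if row["category"] not in LOCALIZATION_CATEGORIES:
                raise FormatError(f"{path}: unknown category {row['category']!r}")
            remap[row["term"]] = row["category"]
    return remap


def localization_features(
    annotations: Sequence[AnnotationRecord],
    remap: Mapping[str, str] | None = None,
    genes: Iterable[str] | None = None,
) -> list[LocalizationFeatures]:
    """Multi-hot flags per gene; unannotated genes get ``Unknown``.

    ``remap`` routes raw terms to categories; uncovered terms fall back to
    ``Other localization``.  When ``genes`` is given, a row is produced for
    every listed gene (annotation-free genes included); otherwise only for
    annotated genes.
    """
    remap = dict(remap) if remap is not None else {}
    per_gene: dict[str, set[str]] = {}
    for rec in annotations:
        category = remap.get(rec.term)
        if category is None:
            category = IDENTITY_REMAP.get(rec.term.lower(), OTHER_CATEGORY)
        per_gene.setdefault(rec.gene, set()).add(category)
    targets = sorted(set(genes)) if genes is not None else sorted(per_gene)
    rows = []
    for gene in targets:
        categories = per_gene.get(gene, set()) - {UNKNOWN_CATEGORY}
        if not categories:
            categories = {UNKNOWN_CATEGORY}
        flags = tuple(int(c in categories) for c in LOCALIZATION_CATEGORIES)
        rows.append(LocalizationFeatures(gene, flags))
    return rows


def expression_features(
    profile: ExpressionProfile, threshold: float = TPM_THRESHOLD
) -> ExpressionFeatures:
    """(numtissuesexp, avegexptec): tissues at/above threshold and their mean tpm."""
    values = np.asarray(profile.tpm, dtype=float)
    expressed = values >= threshold
    n = int(expressed.sum())
    avg = float(values[expressed].mean()) if n else 0.0
    return ExpressionFeatures(profile.gene, n, avg)


def assemble_feature_matrix(
    topology: Sequence[TopologyFeatures],
    localization: Sequence[LocalizationFeatures],
    expression: Sequence[ExpressionFeatures],
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Genes x 24 attribute DataFrame (index: gene id, fixed column order).

    Topology is mandatory for every gene; genes missing expression data get
    (0, 0) and genes missing localization get ``Unknown``.
    """
    topo = {t.gene: t for t in topology}
    genes = sorted(set(genes)) if genes is not None else sorted(topo)
    missing = [g for g in genes if g not in topo]
    if missing:
        raise KeyError(f"genes without topology features: {missing[:5]}")

    loc = {l.gene: l.flags for l in localization}
    unknown_flags = tuple(
        int(c == UNKNOWN_CATEGORY) for c in LOCALIZATION_CATEGORIES
    )
    expr = {e.gene: (e.numtissuesexp, e.avegexptec) for e in expression}

    rows = []
    for g in genes:
        t = topo[g].as_dict()
        n_exp, avg = expr.get(g, (0, 0.0))
        flags = loc.get(g, unknown_flags)
        rows.append([t[c] for c in TOPOLOGY_COLUMNS] + [n_exp, avg] + list(flags))
    matrix = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=list(FEATURE_COLUMNS))
    assert not matrix.isna().any().any()
    return matrix


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path, labels=None) -> None:
    """features.tsv: gene + 24 columns, plus an optional label column."""
    out = matrix.copy()
    if labels is not None:
        out["label"] = pd.Series(labels).reindex(out.index)
    out.to_csv(path, sep="\t")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="gene")
    missing = [c for c in FEATURE_COLUMNS if c not in matrix.columns]
    if missing:
        raise FormatError(f"{path}: missing feature column(s) {missing}")
    return matrix
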