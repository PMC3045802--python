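"""Balanced training datasets: normal, label-shuffled, and feature-ablated.

Positives are the known morbid (or druggable) genes; because no curated
negative class exists, every other network gene is treated as a provisional
negative (positive-unlabeled framing) and each replicate draws an
equal-sized uniform sample of them without replacement.  Label shuffling
produces the paired null condition; feature ablation removes one attribute
column at a time.

Per-replicate randomness derives from a master seed as
``numpy.random.default_rng([master_seed, replicate_index])``, so any single
replicate can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class Provenance:
    task: str = "morbidity"
    variant: str = "normal"  # "normal" | "shuffled"
    replicate: int = 0
    seed: int = 0
    ablated_feature: str | None = None


@dataclass
class LabeledDataset:
    """Feature rows plus binary labels, balanced by construction."""

    features: pd.DataFrame
    labels: pd.Series  # aligned with features.index; values in {1, 0}
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share an index")
        if self.features.index.has_duplicates:
            raise ValueError("duplicate genes within a dataset")
        counts = self.labels.value_counts()
        if counts.get(POSITIVE, 0) != counts.get(NEGATIVE, 0):
            raise ValueError("dataset is not balanced")

    def __len__(self) -> int:
        return len(self.features)


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """The documented master-seed -> replicate-seed derivation."""
    return np.random.default_rng([master_seed, replicate])


def build_balanced_datasets(
    matrix: pd.DataFrame,
    positives: Sequence[str],
    n_replicates: int = 10,
    seed: int = 0,
    task: str = "morbidity",
) -> list[LabeledDataset]:
    """All positives plus an equal-size random negative sample, per replicate.

    Negative samples are drawn uniformly without replacement from the
    non-positive genes, independently for each replicate (replicates may
    overlap in their negatives).
    """
    positives = list(dict.fromkeys(positives))
    missing = set(positives) - set(matrix.index)
    if missing:
        raise KeyError(f"positives absent from matrix: {sorted(missing)[:5]}")
    pool = matrix.index.difference(positives).to_numpy()
    if len(pool) < len(positives):
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than positive set ({len(positives)})"
        )
    out = []
    for r in range(n_replicates):
        rng = replicate_rng(seed, r)
        negatives = rng.choice(pool, size=len(positives), replace=False)
        genes = list(positives) + list(negatives)
        labels = pd.Series(
            [POSITIVE] * len(positives) + [NEGATIVE] * len(negatives),
            index=pd.Index(genes, name="gene"),
            name="label",
        )
        out.append(
            LabeledDataset(
                features=matrix.loc[genes],
                labels=labels,
                provenance=Provenance(task=task, variant="normal", replicate=r, seed=seed),
            )
        )
    return out


def shuffle_dataset_labels(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Permute class labels uniformly over the same rows (the null condition)."""
    rng = np.random.default_rng(seed)
    permuted = rng.permutation(dataset.labels.to_numpy())
    return LabeledDataset(
        features=dataset.features,
        labels=pd.Series(permuted, index=dataset.labels.index, name="label"),
        provenance=replace(dataset.provenance, variant="shuffled", seed=seed),
    )


def ablate_feature(
    datasets: Sequence[LabeledDataset], feature: str
) -> list[LabeledDataset]:
    """Drop one attribute column from every dataset (without-one-feature family)."""
    out = []
    for d in datasets:
        if feature not in d.features.columns:
            raise KeyError(f"unknown feature column {feature!r}")
        out.append(
            LabeledDataset(
                features=d.features.drop(columns=[feature]),
                labels=d.labels,
                provenance=replace(d.provenance, ablated_feature=feature),
            )
        )
    return out
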