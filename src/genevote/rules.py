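"""Interpretable decision trees and root-to-leaf cellular rules.

A single gain-ratio (C4.5-style) decision tree is trained per normal
dataset replicate; walking root-to-leaf paths yields human-readable rules
such as "regin > 1 -> positive".  Numeric attributes split binarily at
midpoints between observed values; binary localization flags split as
flag = 0 / flag = 1.  Trees are simplified by error-based pruning: a
subtree collapses to a leaf when the leaf's pessimistic error estimate
(binomial upper confidence limit at the given confidence) does not exceed
the subtree's.  Leaves carry "(n/e)" annotations — n training instances
reached the leaf, e of them are misclassified.

The representative tree among the 10 replicates is chosen by modal root
feature, then highest cross-validated AUC, then smaller tree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import LabeledDataset, Provenance
from .learning import EvalResult

CLASS_NAMES = {1: "positive", 0: "negative"}


@dataclass
class Node:
    """Internal split node or leaf of a decision tree."""

    support: int
    errors: int
    predicted: int
    feature: str | None = None
    threshold: float | None = None
    binary: bool = False
    left: "Node | None" = None  # feature <= threshold (or flag = 0)
    right: "Node | None" = None  # feature > threshold (or flag = 1)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class DecisionTree:
    root: Node
    columns: list[str]
    n_training: int
    provenance: Provenance | None = None

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def root_feature(self) -> str | None:
        return self.root.feature

    def classify(self, X: pd.DataFrame) -> np.ndarray:
        values = X[self.columns].to_numpy(dtype=float)
        out = np.empty(len(values), dtype=int)
        for i, row in enumerate(values):
            node = self.root
            while not node.is_leaf:
                j = self.columns.index(node.feature)
                node = node.left if row[j] <= node.threshold else node.right
            out[i] = node.predicted
        return out


@dataclass(frozen=True)
class DecisionRule:
    """One root-to-leaf path: ordered conditions, prediction, leaf counts."""

    conditions: tuple[tuple[str, str, float], ...]
    predicted: int
    support: int
    errors: int

    def __post_init__(self) -> None:
        if self.errors > self.support:
            raise ValueError("leaf errors exceed leaf support")

    def __str__(self) -> str:
        if self.conditions:
            parts = " and ".join(
                f"{f} {op} {v:g}" for f, op, v in self.conditions
            )
        else:
            parts = "always"
        return f"{parts} -> {CLASS_NAMES[self.predicted]} ({self.support}/{self.errors})"


def _entropy(pos: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Binary class entropy in bits, elementwise; 0 on empty partitions."""
    total = np.asarray(total, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, pos / np.maximum(total, 1), 0.0)
        h = -np.where((p > 0) & (p < 1), p * np.log2(p) + (1 - p) * np.log2(1 - p), 0.0)
    return h


def _best_split(values: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (gain_ratio, gain, threshold) for one numeric column, or None."""
    order = np.argsort(values, kind="mergesort")
    v, yy = values[order], y[order]
    n = len(v)
    cut = np.nonzero(v[1:] > v[:-1])[0] + 1  # left side sizes at value changes
    cut = cut[(cut >= min_leaf) & (n - cut >= min_leaf)]
    if len(cut) == 0:
        return None
    cum_pos = np.cumsum(yy == 1)
    total_pos = cum_pos[-1]
    left_n, right_n = cut, n - cut
    left_pos = cum_pos[cut - 1]
    right_pos = total_pos - left_pos
    parent_h = _entropy(np.array([total_pos]), np.array([n]))[0]
    child_h = (left_n * _entropy(left_pos, left_n) + right_n * _entropy(right_pos, right_n)) / n
    gain = parent_h - child_h
    frac = left_n / n
    split_info = -(frac * np.log2(frac) + (1 - frac) * np.log2(1 - frac))
    ratio = np.where(split_info > 0, gain / split_info, 0.0)
    usable = gain > 1e-12
    if not usable.any():
        return None
    best = int(np.flatnonzero(usable)[np.argmax(ratio[usable])])
    i = cut[best]
    return float(ratio[best]), float(gain[best]), float((v[i - 1] + v[i]) / 2)


def _leaf(y: np.ndarray) -> Node:
    pos = int((y == 1).sum())
    predicted = 1 if pos * 2 >= len(y) else 0
    errors = len(y) - pos if predicted == 1 else pos
    return Node(support=len(y), errors=errors, predicted=predicted)


def _grow(X: np.ndarray, y: np.ndarray, columns, binary_mask, min_leaf: int) -> Node:
    leaf = _leaf(y)
    if leaf.errors == 0 or len(y) < 2 * min_leaf:
        return leaf
    best = None
    for j, name in enumerate(columns):
        found = _best_split(X[:, j], y, min_leaf)
        if found is None:
            continue
        ratio, gain, threshold = found
        if best is None or ratio > best[0] + 1e-12:
            best = (ratio, j, threshold)
    if best is None:
        return leaf
    _, j, threshold = best
    mask = X[:, j] <= threshold
    node = Node(
        support=leaf.support,
        errors=leaf.errors,
        predicted=leaf.predicted,
        feature=columns[j],
        threshold=threshold,
        binary=bool(binary_mask[j]),
        left=_grow(X[mask], y[mask], columns, binary_mask, min_leaf),
        right=_grow(X[~mask], y[~mask], columns, binary_mask, min_leaf),
    )
    return node


def _pessimistic_errors(errors: int, n: int, confidence: float) -> float:
    """n times the binomial upper confidence limit of the leaf error rate."""
    if n == 0:
        return 0.0
    upper = stats.beta.ppf(1 - confidence, errors + 1, n - errors) if errors < n else 1.0
    return float(n * upper)


def _prune(node: Node, confidence: float) -> Node:
    if node.is_leaf:
        return node
    node.left = _prune(node.left, confidence)
    node.right = _prune(node.right, confidence)
    subtree_est = sum(
        _pessimistic_errors(l.errors, l.support, confidence) for l in node.leaves()
    )
    leaf_est = _pessimistic_errors(node.errors, node.support, confidence)
    if leaf_est <= subtree_est:
        return Node(support=node.support, errors=node.errors, predicted=node.predicted)
    return node


def induce_tree(
    dataset: LabeledDataset, min_leaf: int = 2, confidence: float = 0.25
) -> DecisionTree:
    """Gain-ratio tree with error-based pruning on one balanced dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    columns = list(dataset.features.columns)
    X = dataset.features.to_numpy(dtype=float)
    y = dataset.labels.to_numpy()
    binary_mask = [set(np.unique(X[:, j])) <= {0.0, 1.0} for j in range(X.shape[1])]
    root = _prune(_grow(X, y, columns, binary_mask, min_leaf), confidence)
    return DecisionTree(
        root=root, columns=columns, n_training=len(y), provenance=dataset.provenance
    )


def extract_rules(tree: DecisionTree) -> list[DecisionRule]:
    """One rule per leaf; conditions in path order; supports sum to |dataset|."""
    rules: list[DecisionRule] = []

    def walk(node: Node, conditions: tuple) -> None:
        if node.is_leaf:
            rules.append(
                DecisionRule(
                    conditions=conditions,
                    predicted=node.predicted,
                    support=node.support,
                    errors=node.errors,
                )
            )
            return
        if node.binary:
            left_cond = (node.feature, "=", 0.0)
            right_cond = (node.feature, "=", 1.0)
        else:
            left_cond = (node.feature, "<=", node.threshold)
            right_cond = (node.feature, ">", node.threshold)
        walk(node.left, conditions + (left_cond,))
        walk(node.right, conditions + (right_cond,))

    walk(tree.root, ())
    return rules


def select_representative_tree(
    trees: Sequence[DecisionTree], evals: Sequence[EvalResult]
) -> DecisionTree:
    """Modal-root tree with the highest paired CV AUC.

    Ties break toward the smaller tree (fewer leaves), then the earlier
    replicate.
    """
    if not trees:
        raise ValueError("no trees to select from")
    if len(trees) != len(evals):
        raise ValueError("trees and evaluations must pair one-to-one")
    roots = [t.root_feature() for t in trees]
    modal_root = Counter(roots).most_common(1)[0][0]
    candidates = [
        (evals[i].auc, -trees[i].n_leaves(), -i, trees[i])
        for i in range(len(trees))
        if roots[i] == modal_root
    ]
    return max(candidates, key=lambda c: c[:3])[3]


def render_tree(tree: DecisionTree) -> str:
    """Indented text rendering with '(n/e)' leaf annotations."""
    lines: list[str] = []

    def walk(node: Node, prefix: str, label: str) -> None:
        if node.is_leaf:
            lines.append(
                f"{prefix}{label}: {CLASS_NAMES[node.predicted]} ({node.support}/{node.errors})"
            )
            return
        lines.append(f"{prefix}{label}[{node.feature}]")
        if node.binary:
            walk(node.left, prefix + "  ", f"{node.feature} = 0 ")
            walk(node.right, prefix + "  ", f"{node.feature} = 1 ")
        else:
            walk(node.left, prefix + "  ", f"{node.feature} <= {node.threshold:g} ")
            walk(node.right, prefix + "  ", f"{node.feature} > {node.threshold:g} ")

    walk(tree.root, "", "")
    return "\n".join(lines) + "\n"


def rules_to_json(rules: Sequence[DecisionRule]) -> list[dict]:
    return [
        {
            "conditions": [
                {"feature": f, "comparator": op, "value": v} for f, op, v in r.conditions
            ],
            "predicted": CLASS_NAMES[r.predicted],
            "support": r.support,
            "errors": r.errors,
        }
        for r in rules
    ]
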