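"""Voting ensemble, cross-validated evaluation, Wilcoxon tests, genome scoring.

The classifier is a voting meta-classifier over seven tree-family learners,
each wrapped in bootstrap aggregating; its positive-class probability is
the arithmetic mean of the bagged members' probabilities.  Performance is
measured by recall, precision (threshold 0.5) and AUC under stratified
10-fold cross-validation, summarized as median [min, max] over the 10
dataset replicates, and compared across conditions with the exact Wilcoxon
signed-rank test: a difference is significant when W <= W_c, the two-tailed
p = 0.05 critical value obtained by exhaustive sign-pattern enumeration.

Genome-wide scoring applies the 10 normal-condition and 10 label-shuffled
models to every gene (labels withheld); a gene's morbidity or druggability
score is the median of its 10 normal probabilities, and the per-gene
normal-versus-shuffled Wilcoxon test flags genes whose scores exceed the
null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import OneHotEncoder
from sklearn.tree import DecisionTreeClassifier

from .datasets import LabeledDataset, Provenance

# --------------------------------------------------------------------------
# ensemble members
# --------------------------------------------------------------------------


class LeafLogisticTree(BaseEstimator, ClassifierMixin):
    """Depth-limited decision tree with a logistic model over leaf membership.

    Serves the logistic-model-tree role in the ensemble: the tree carves the
    feature space, and a logistic regression fitted on one-hot leaf
    indicators provides smoothed class probabilities.
    """

    def __init__(self, max_depth: int = 5, min_samples_leaf: int = 8, random_state=None):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.tree_ = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y)
        if len(self.classes_) < 2:
            self.logistic_ = None
            return self
        leaves = self.tree_.apply(X).reshape(-1, 1)
        self.encoder_ = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        self.logistic_ = LogisticRegression(max_iter=500).fit(
            self.encoder_.fit_transform(leaves), y
        )
        return self

    def predict_proba(self, X):
        if self.logistic_ is None:
            return np.ones((len(np.asarray(X)), 1))
        leaves = self.tree_.apply(X).reshape(-1, 1)
        return self.logistic_.predict_proba(self.encoder_.transform(leaves))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def default_members() -> tuple[tuple[str, BaseEstimator], ...]:
    """The seven tree-family learners of the voting ensemble.

    Functional stand-ins, in order: a reduced-error-style pruned tree, a
    randomized tree, a random forest, a C4.5-style tree with >= 32 instances
    per leaf, a best-first-expanded tree with >= 32 instances per terminal
    node, a logistic-model tree, and 25 rounds of boosted decision stumps in
    the alternating-decision-tree role.
    """
    return (
        ("rep_tree", DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2, ccp_alpha=1e-3)),
        ("random_tree", DecisionTreeClassifier(splitter="random", max_features="sqrt", min_samples_leaf=2)),
        ("random_forest", RandomForestClassifier(n_estimators=10)),
        ("c45_tree", DecisionTreeClassifier(criterion="entropy", min_samples_leaf=32)),
        ("best_first_tree", DecisionTreeClassifier(min_samples_leaf=32, max_leaf_nodes=32)),
        ("logistic_model_tree", LeafLogisticTree(max_depth=5)),
        ("boosted_stumps", AdaBoostClassifier(estimator=DecisionTreeClassifier(max_depth=1), n_estimators=25)),
    )


@dataclass
class EnsembleConfig:
    members: tuple[tuple[str, BaseEstimator], ...] = field(default_factory=default_members)
    bags_per_member: int = 10
    seed: int = 0
    stratify: bool = True


class ConfigError(ValueError):
    pass


@dataclass
class EnsembleModel:
    """Bagged voting ensemble; probability = mean of member probabilities."""

    config: EnsembleConfig
    members_: list = field(default_factory=list)  # fitted BaggingClassifiers
    columns_: list[str] = field(default_factory=list)
    provenance: Provenance | None = None

    @property
    def fitted(self) -> bool:
        return bool(self.members_)

    def _check_columns(self, X: pd.DataFrame) -> None:
        if list(X.columns) != self.columns_:
            raise ValueError("feature columns do not match the training columns")

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Positive-class probability per row: the average rule over members."""
        if not self.fitted:
            raise RuntimeError("model is not fitted")
        self._check_columns(X)
        values = X.to_numpy(dtype=float)
        probs = np.zeros(len(X))
        for member in self.members_:
            # boosted members hit log(0) on perfectly separable bootstraps
            with np.errstate(divide="ignore", invalid="ignore"):
                p = member.predict_proba(values)
            idx = list(member.classes_).index(1) if 1 in member.classes_ else None
            probs += p[:, idx] if idx is not None else np.zeros(len(X))
        return probs / len(self.members_)


def build_meta_classifier(config: EnsembleConfig) -> EnsembleModel:
    """Validate the member roster and return an untrained ensemble."""
    if not config.members:
        raise ConfigError("ensemble needs at least one member")
    for name, proto in config.members:
        if not hasattr(proto, "predict_proba"):
            raise ConfigError(f"member {name!r} lacks probability output")
    if config.bags_per_member < 1:
        raise ConfigError("bags_per_member must be positive")
    return EnsembleModel(config=config)


def _member_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def train(model: EnsembleModel, dataset: LabeledDataset) -> EnsembleModel:
    """Fit every member on bootstrap resamples; deterministic under the seed."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = model.config
    X = dataset.features.to_numpy(dtype=float)
    y = dataset.labels.to_numpy()
    seeds = _member_seeds(config.seed, len(config.members))
    members = []
    for (name, proto), member_seed in zip(config.members, seeds):
        base = clone(proto)
        if "random_state" in base.get_params():
            base.set_params(random_state=member_seed)
        bagged = BaggingClassifier(
            estimator=base,
            n_estimators=config.bags_per_member,
            random_state=member_seed,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            members.append(bagged.fit(X, y))
    return EnsembleModel(
        config=config,
        members_=members,
        columns_=list(dataset.features.columns),
        provenance=dataset.provenance,
    )


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


@dataclass
class EvalResult:
    recall: float
    precision: float
    auc: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    provenance: Provenance | None = None

    MEASURES = ("recall", "precision", "auc")


def mann_whitney_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic over positive/negative score pairs,
    with half credit for ties."""
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class label vector")
    ranks = stats.rankdata(probabilities)  # mid-ranks on ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_predictions(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> EvalResult:
    """Recall and precision at the threshold plus rank-based AUC."""
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=float)
    if len(labels) != len(probabilities):
        raise ValueError("labels and probabilities differ in length")
    predicted = probabilities >= threshold
    tp = int(((labels == 1) & predicted).sum())
    fp = int(((labels == 0) & predicted).sum())
    fn = int(((labels == 1) & ~predicted).sum())
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return EvalResult(
        recall=recall,
        precision=precision,
        auc=mann_whitney_auc(labels, probabilities),
        tp=tp,
        fp=fp,
        fn=fn,
    )


def cross_validate(
    dataset: LabeledDataset,
    config: EnsembleConfig,
    folds: int = 10,
    seed: int | None = None,
) -> EvalResult:
    """k-fold cross-validation; per-fold measures averaged into one result.

    Folds are stratified by default (``config.stratify``); ``seed`` defaults
    to the ensemble seed.
    """
    if folds > len(dataset):
        raise ValueError(f"folds={folds} exceeds dataset size {len(dataset)}")
    seed = config.seed if seed is None else seed
    splitter_cls = StratifiedKFold if config.stratify else KFold
    splitter = splitter_cls(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    y = dataset.labels.to_numpy()
    fold_results = []
    for train_idx, test_idx in splitter.split(dataset.features, y):
        # training folds of a balanced dataset are only near-balanced, so the
        # balance invariant is not enforced on them
        train_set = _unchecked_dataset(dataset, train_idx)
        model = train(build_meta_classifier(config), train_set)
        probs = model.predict_proba(dataset.features.iloc[test_idx])
        fold_results.append(evaluate_predictions(y[test_idx], probs))
    return EvalResult(
        recall=float(np.mean([r.recall for r in fold_results])),
        precision=float(np.mean([r.precision for r in fold_results])),
        auc=float(np.mean([r.auc for r in fold_results])),
        tp=sum(r.tp for r in fold_results),
        fp=sum(r.fp for r in fold_results),
        fn=sum(r.fn for r in fold_results),
        provenance=dataset.provenance,
    )


def _unchecked_dataset(dataset: LabeledDataset, idx) -> LabeledDataset:
    # CV training folds need not be exactly balanced; bypass the invariant.
    d = object.__new__(LabeledDataset)
    d.features = dataset.features.iloc[idx]
    d.labels = dataset.labels.iloc[idx]
    d.provenance = dataset.provenance
    return d


def summarize(results: Sequence[EvalResult]) -> dict[str, dict[str, float]]:
    """Per-measure median, min, max over dataset replicates."""
    if not results:
        raise ValueError("no results to summarize")
    out = {}
    for measure in EvalResult.MEASURES:
        values = np.array([getattr(r, measure) for r in results], dtype=float)
        out[measure] = {
            "median": float(np.median(values)),
            "min": float(values.min()),
            "max": float(values.max()),
        }
    return out


# --------------------------------------------------------------------------
# Wilcoxon signed-rank test (exact for small N)
# --------------------------------------------------------------------------

EXACT_WILCOXON_LIMIT = 25
ALPHA_TWO_TAILED = 0.05


@dataclass(frozen=True)
class WilcoxonResult:
    W: float | None
    N: int
    W_c: float | None
    significant: bool
    exact_p: float | None


def _null_counts(scaled_ranks: tuple[int, ...]) -> np.ndarray:
    """counts[s] = number of sign patterns whose positive-rank sum (x2) is s."""
    total = sum(scaled_ranks)
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in scaled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


@lru_cache(maxsize=None)
def wilcoxon_critical_value(n: int, alpha: float = ALPHA_TWO_TAILED) -> float | None:
    """Largest c with two-tailed exact P(W <= c) <= alpha for untied ranks 1..n.

    None when no value of W reaches significance at that N (small samples).
    Exact enumeration over the 2^n sign patterns via the rank-sum
    distribution; matches published critical-value tables built the same way
    (e.g., 8 at N = 10).
    """
    if n < 1:
        return None
    if n > EXACT_WILCOXON_LIMIT:
        # normal approximation, continuity corrected
        mu = n * (n + 1) / 4
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        c = math.floor(mu - 0.5 + sigma * stats.norm.ppf(alpha / 2))
        return float(max(c, 0)) if c >= 0 else None
    scaled = tuple(2 * r for r in range(1, n + 1))
    counts = _null_counts(scaled)
    cdf = np.cumsum(counts) / counts.sum()
    # W takes integer values here; scaled axis s corresponds to W = s / 2
    critical = None
    for w in range(0, sum(range(1, n + 1)) + 1):
        if 2 * cdf[2 * w] <= alpha:
            critical = float(w)
        else:
            break
    return critical


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test of paired samples a vs b.

    Zero differences are discarded (N reduced), absolute differences ranked
    with mid-ranks on ties, W = min(positive-rank sum, negative-rank sum).
    Exact two-tailed p by enumeration for N <= 25, normal approximation with
    tie correction above.  ``significant`` is the critical-value rule
    W <= W_c at two-tailed p = 0.05.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(W=None, N=0, W_c=None, significant=False, exact_p=None)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    w_c = wilcoxon_critical_value(n)
    if n <= EXACT_WILCOXON_LIMIT:
        scaled = tuple(int(round(2 * r)) for r in ranks)
        counts = _null_counts(scaled)
        cdf = np.cumsum(counts) / counts.sum()
        p = min(1.0, 2 * float(cdf[int(round(2 * w))]))
    else:
        mu = n * (n + 1) / 4
        _, tie_counts = np.unique(ranks, return_counts=True)
        correction = float(((tie_counts**3 - tie_counts) / 48).sum())
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24 - correction)
        z = (w - mu + 0.5) / sigma
        p = min(1.0, 2 * float(stats.norm.cdf(z)))
    significant = w_c is not None and w <= w_c
    return WilcoxonResult(W=w, N=n, W_c=w_c, significant=significant, exact_p=p)


def compare_conditions(
    normal: Sequence[EvalResult], other: Sequence[EvalResult], measure: str
) -> WilcoxonResult:
    """Paired Wilcoxon test of one measure between two condition result lists.

    Pairing respects replicate index, not list order.
    """
    if measure not in EvalResult.MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if len(normal) != len(other):
        raise ValueError("conditions have different replicate counts")

    def by_replicate(results):
        if all(r.provenance is not None for r in results):
            return sorted(results, key=lambda r: r.provenance.replicate)
        return list(results)

    a = [getattr(r, measure) for r in by_replicate(normal)]
    b = [getattr(r, measure) for r in by_replicate(other)]
    return wilcoxon_signed_rank(a, b)


# --------------------------------------------------------------------------
# genome-wide scoring
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneScore:
    gene: str
    normal_scores: tuple[float, ...]
    shuffled_scores: tuple[float, ...]
    normal_median: float
    normal_min: float
    normal_max: float
    shuffled_median: float
    shuffled_min: float
    shuffled_max: float
    wilcoxon: WilcoxonResult


@dataclass
class GeneScoreTable:
    """Per-gene normal/shuffled score summaries, sorted by normal median desc."""

    rows: list[GeneScore] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: (-r.normal_median, r.gene))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.rows],
                "normal_median": [r.normal_median for r in self.rows],
                "shuffled_median": [r.shuffled_median for r in self.rows],
                "significant": [r.wilcoxon.significant for r in self.rows],
            }
        ).set_index("gene")


def score_genome_wide(
    models_normal: Sequence[EnsembleModel],
    models_shuffled: Sequence[EnsembleModel],
    matrix: pd.DataFrame,
) -> GeneScoreTable:
    """Median-of-10 scores per gene under both conditions plus per-gene test.

    Applies each fitted model to the whole (unlabeled) feature matrix; the
    per-gene Wilcoxon test pairs the replicate scores of the two conditions.
    """
    if len(models_normal) != len(models_shuffled) or not models_normal:
        raise ValueError("need equally many fitted models per condition")
    normal = np.stack([m.predict_proba(matrix) for m in models_normal])
    shuffled = np.stack([m.predict_proba(matrix) for m in models_shuffled])
    rows = []
    for j, gene in enumerate(matrix.index):
        ns, ss = normal[:, j], shuffled[:, j]
        rows.append(
            GeneScore(
                gene=str(gene),
                normal_scores=tuple(ns),
                shuffled_scores=tuple(ss),
                normal_median=float(np.median(ns)),
                normal_min=float(ns.min()),
                normal_max=float(ns.max()),
                shuffled_median=float(np.median(ss)),
                shuffled_min=float(ss.min()),
                shuffled_max=float(ss.max()),
                wilcoxon=wilcoxon_signed_rank(ns, ss),
            )
        )
    return GeneScoreTable(rows=rows)


def score_histogram(
    scores: GeneScoreTable, known_positives: Sequence[str], bin_width: float = 0.2
) -> list[float]:
    """Percentage of known positives per score bin of the normal medians.

    Bins partition [0, 1] ([0, w), [w, 2w), ..., last bin closed at 1);
    fractions sum to 100 when any known positive is scored.
    """
    n_bins = int(round(1.0 / bin_width))
    if not math.isclose(n_bins * bin_width, 1.0):
        raise ValueError("bin_width must evenly partition [0, 1]")
    known = set(known_positives)
    values = [r.normal_median for r in scores.rows if r.gene in known]
    if not values:
        return [0.0] * n_bins
    counts = np.histogram(values, bins=n_bins, range=(0.0, 1.0))[0]
    return list(100.0 * counts / counts.sum())
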