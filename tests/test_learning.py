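import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

import genevote as gv
from genevote.learning import ConfigError, mann_whitney_auc

from conftest import random_matrix
from oracles import brute_auc, brute_wilcoxon


class ConstantClassifier(BaseEstimator, ClassifierMixin):
    """Predicts a fixed positive-class probability regardless of input."""

    def __init__(self, p=0.5):
        self.p = p

    def fit(self, X, y):
        self.classes_ = np.array(sorted(set(np.asarray(y))))
        return self

    def predict_proba(self, X):
        n = len(np.asarray(X))
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])

    def predict(self, X):
        return np.full(len(np.asarray(X)), int(self.p >= 0.5))


def balanced_dataset(seed=0, n=40):
    matrix = random_matrix(np.random.default_rng(seed), n=n)
    positives = list(matrix.index[: n // 4])
    return gv.build_balanced_datasets(matrix, positives, 1, seed=seed)[0]


def separable_dataset(seed=0, n=60):
    """Labels perfectly determined by one feature."""
    matrix = random_matrix(np.random.default_rng(seed), n=n)
    order = matrix["cent"].sort_values()
    positives = list(order.index[: n // 2])
    d = gv.build_balanced_datasets(matrix, positives, 1, seed=seed)[0]
    return d


class TestMetaClassifier:
    def test_default_roster_has_seven_bagged_members(self):
        config = gv.EnsembleConfig()
        assert len(config.members) == 7
        model = gv.train(gv.build_meta_classifier(config), balanced_dataset())
        assert len(model.members_) == 7
        assert all(len(m.estimators_) == config.bags_per_member for m in model.members_)

    def test_prediction_is_member_average(self):
        config = gv.EnsembleConfig(
            members=(("a", ConstantClassifier(0.2)), ("b", ConstantClassifier(0.4))),
            bags_per_member=3,
        )
        d = balanced_dataset()
        model = gv.train(gv.build_meta_classifier(config), d)
        probs = model.predict_proba(d.features)
        assert np.allclose(probs, 0.3)

    def test_three_member_roster_allowed(self):
        config = gv.EnsembleConfig(
            members=tuple(("m%d" % i, ConstantClassifier(0.5)) for i in range(3))
        )
        assert len(gv.build_meta_classifier(config).config.members) == 3

    def test_member_without_probabilities_rejected(self):
        from sklearn.svm import LinearSVC

        config = gv.EnsembleConfig(members=(("svc", LinearSVC()),))
        with pytest.raises(ConfigError):
            gv.build_meta_classifier(config)

    def test_training_is_deterministic_under_seed(self, fast_config):
        d = balanced_dataset(seed=3)
        probe = d.features.iloc[:5]
        p1 = gv.train(gv.build_meta_classifier(fast_config), d).predict_proba(probe)
        p2 = gv.train(gv.build_meta_classifier(fast_config), d).predict_proba(probe)
        assert np.array_equal(p1, p2)

    def test_separable_data_gets_perfect_training_auc(self, fast_config):
        d = separable_dataset()
        model = gv.train(gv.build_meta_classifier(fast_config), d)
        result = gv.evaluate_predictions(d.labels, model.predict_proba(d.features))
        assert result.auc == 1.0

    def test_column_mismatch_at_predict_time(self, fast_config):
        d = balanced_dataset()
        model = gv.train(gv.build_meta_classifier(fast_config), d)
        with pytest.raises(ValueError):
            model.predict_proba(d.features.drop(columns=["cent"]))

    def test_empty_dataset_rejected(self, fast_config):
        d = balanced_dataset()
        empty = gv.LabeledDataset(d.features.iloc[:0], d.labels.iloc[:0], d.provenance)
        with pytest.raises(ValueError):
            gv.train(gv.build_meta_classifier(fast_config), empty)


class TestEvaluatePredictions:
    def test_recall_and_precision_formulas(self):
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0]
        probs = [0.9, 0.8, 0.7, 0.2, 0.6, 0.55, 0.1, 0.2, 0.3]
        result = gv.evaluate_predictions(labels, probs)
        assert result.tp == 3 and result.fn == 1 and result.fp == 2
        assert math.isclose(result.recall, 0.75)
        assert math.isclose(result.precision, 0.6)

    def test_perfect_and_tied_rankings(self):
        assert gv.evaluate_predictions([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]).auc == 1.0
        assert gv.evaluate_predictions([1, 1, 0, 0], [0.5] * 4).auc == 0.5

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError):
            gv.evaluate_predictions([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_pairwise_mann_whitney_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        probs = np.round(rng.random(n), 1)  # coarse grid forces ties
        assert math.isclose(
            mann_whitney_auc(labels, probs), brute_auc(labels, probs), abs_tol=1e-12
        )


class TestCrossValidate:
    def test_separable_dataset_scores_near_one(self, fast_config):
        result = gv.cross_validate(separable_dataset(n=80), fast_config, folds=5)
        assert result.auc > 0.95

    def test_shuffled_labels_score_near_chance(self, fast_config):
        rng = np.random.default_rng(4)
        d = separable_dataset(seed=4, n=100)
        aucs = []
        for i in range(5):
            shuffled = gv.shuffle_dataset_labels(d, seed=i)
            aucs.append(gv.cross_validate(shuffled, fast_config, folds=5).auc)
        assert 0.35 < float(np.median(aucs)) < 0.65

    def test_too_many_folds_rejected(self, fast_config):
        with pytest.raises(ValueError):
            gv.cross_validate(balanced_dataset(), fast_config, folds=1000)


class TestSummarize:
    def test_median_min_max_per_measure(self):
        results = [
            gv.EvalResult(recall=r, precision=p, auc=a)
            for r, p, a in [(0.5, 0.4, 0.7), (0.6, 0.5, 0.8), (0.7, 0.6, 0.9)]
        ]
        summary = gv.summarize(results)
        assert summary["auc"] == {"median": 0.8, "min": 0.7, "max": 0.9}

    def test_single_result_collapses(self):
        summary = gv.summarize([gv.EvalResult(recall=0.5, precision=0.5, auc=0.5)])
        assert summary["recall"]["median"] == summary["recall"]["min"] == 0.5

    def test_even_count_uses_central_pair_mean(self):
        results = [gv.EvalResult(recall=r, precision=r, auc=r) for r in (0.2, 0.4, 0.6, 0.8)]
        assert gv.summarize(results)["auc"]["median"] == 0.5


class TestWilcoxonSignedRank:
    def test_all_positive_differences_give_zero_statistic(self):
        result = gv.wilcoxon_signed_rank(np.arange(10) + 1.0, np.arange(10) * 0.5)
        assert result.W == 0.0 and result.N == 10 and result.significant

    def test_zero_differences_reduce_n(self):
        a = np.arange(10, dtype=float)
        b = a.copy()
        b[:9] -= np.linspace(1, 2, 9)
        result = gv.wilcoxon_signed_rank(a, b)
        assert result.N == 9 and result.W_c == 5.0

    def test_all_zero_differences_is_undefined_sentinel(self):
        result = gv.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert result.W is None and result.N == 0 and not result.significant

    @pytest.mark.parametrize("n", range(6, 13))
    def test_critical_values_match_published_table(self, n):
        table = {6: 0, 7: 2, 8: 3, 9: 5, 10: 8, 11: 10, 12: 13}
        assert gv.wilcoxon_critical_value(n) == table[n]

    def test_below_n6_nothing_is_significant(self):
        assert gv.wilcoxon_critical_value(5) is None
        result = gv.wilcoxon_signed_rank([1, 2, 3, 4, 5.0], [0, 0, 0, 0, 0.0])
        assert not result.significant

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_sign_pattern_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        a = np.round(rng.normal(size=n), 1)
        b = np.round(rng.normal(size=n), 1)
        w, n_eff, p = brute_wilcoxon(a, b)
        result = gv.wilcoxon_signed_rank(a, b)
        assert result.N == n_eff
        if w is None:
            assert result.W is None
        else:
            assert math.isclose(result.W, w)
            assert math.isclose(result.exact_p, p, abs_tol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_tie_free_p_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 10
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        ours = gv.wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="exact", alternative="two-sided")
        assert math.isclose(ours.exact_p, ref.pvalue, rel_tol=1e-9)

    def test_statistic_bounded_by_rank_sum(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=12)
        result = gv.wilcoxon_signed_rank(a, b)
        assert 0 <= result.W <= result.N * (result.N + 1) / 2


class TestCompareConditions:
    def res(self, value, replicate):
        return gv.EvalResult(
            recall=value, precision=value, auc=value,
            provenance=gv.Provenance(replicate=replicate),
        )

    def test_identical_lists_not_significant(self):
        normal = [self.res(0.7, i) for i in range(10)]
        result = gv.compare_conditions(normal, list(normal), "auc")
        assert result.N == 0 and not result.significant

    def test_consistent_advantage_is_significant_with_zero_w(self):
        normal = [self.res(0.7 + 0.01 * i, i) for i in range(10)]
        other = [self.res(0.5 + 0.005 * i, i) for i in range(10)]
        result = gv.compare_conditions(normal, other, "auc")
        assert result.W == 0.0 and result.significant

    def test_pairing_respects_replicate_index_not_order(self):
        normal = [self.res(0.7 + 0.01 * i, i) for i in range(10)]
        other = [self.res(0.7 + 0.01 * i, i) for i in range(10)]
        result = gv.compare_conditions(normal, list(reversed(other)), "auc")
        assert result.N == 0  # all paired differences are zero

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            gv.compare_conditions([self.res(0.5, 0)], [], "auc")


class TestGenomeWideScoring:
    def constant_models(self, columns, p):
        config = gv.EnsembleConfig(
            members=(("c", ConstantClassifier(p)),), bags_per_member=2
        )
        d = balanced_dataset()
        return [gv.train(gv.build_meta_classifier(config), d) for _ in range(10)]

    def test_constant_half_models_score_half_everywhere(self):
        matrix = random_matrix(np.random.default_rng(0), n=20)
        models = self.constant_models(matrix.columns, 0.5)
        table = gv.score_genome_wide(models, models, matrix)
        assert all(r.normal_median == 0.5 for r in table.rows)
        assert not any(r.wilcoxon.significant for r in table.rows)

    def test_table_sorted_by_normal_median_descending(self, fast_config):
        matrix = random_matrix(np.random.default_rng(2), n=30)
        positives = list(matrix.index[:8])
        normal = gv.build_balanced_datasets(matrix, positives, 10, seed=1)
        shuffled = [gv.shuffle_dataset_labels(d, seed=i) for i, d in enumerate(normal)]
        models_n = [gv.train(gv.build_meta_classifier(fast_config), d) for d in normal]
        models_s = [gv.train(gv.build_meta_classifier(fast_config), d) for d in shuffled]
        table = gv.score_genome_wide(models_n, models_s, matrix)
        medians = [r.normal_median for r in table.rows]
        assert medians == sorted(medians, reverse=True)
        for r in table.rows:
            assert r.normal_min <= r.normal_median <= r.normal_max
            assert 0.0 <= r.normal_min and r.normal_max <= 1.0

    def test_model_count_mismatch_rejected(self):
        matrix = random_matrix(np.random.default_rng(0), n=10)
        models = self.constant_models(matrix.columns, 0.5)
        with pytest.raises(ValueError):
            gv.score_genome_wide(models, models[:5], matrix)


class TestScoreHistogram:
    def table(self, medians):
        from genevote.learning import GeneScore, GeneScoreTable, WilcoxonResult

        rows = [
            GeneScore(
                gene=f"g{i}", normal_scores=(), shuffled_scores=(),
                normal_median=m, normal_min=m, normal_max=m,
                shuffled_median=0.5, shuffled_min=0.5, shuffled_max=0.5,
                wilcoxon=WilcoxonResult(None, 0, None, False, None),
            )
            for i, m in enumerate(medians)
        ]
        return GeneScoreTable(rows=rows)

    def test_concentrated_scores_fill_last_bin(self):
        table = self.table([0.9, 0.95, 0.85])
        fractions = gv.score_histogram(table, [f"g{i}" for i in range(3)])
        assert fractions[-1] == 100.0

    def test_uniformly_spread_scores(self):
        table = self.table([0.1, 0.3, 0.5, 0.7, 0.9])
        fractions = gv.score_histogram(table, [f"g{i}" for i in range(5)])
        assert all(math.isclose(f, 20.0) for f in fractions)

    def test_fractions_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        medians = list(rng.random(37))
        table = self.table(medians)
        fractions = gv.score_histogram(table, [f"g{i}" for i in range(37)])
        assert math.isclose(sum(fractions), 100.0)
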