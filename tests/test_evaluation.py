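import collections

import numpy as np
import pytest

import kvarpred as kv
from kvarpred.evaluation import (
    ConfusionMatrix,
    EvaluationError,
    confusion,
    entropy_separation,
)


def pearson_mcc(cm):
    """Oracle: MCC as the Pearson correlation of the binary label vectors."""
    y_true = [1] * cm.tp + [1] * cm.fn + [0] * cm.tn + [0] * cm.fp
    y_pred = [1] * cm.tp + [0] * cm.fn + [0] * cm.tn + [1] * cm.fp
    a, b = np.asarray(y_true, float), np.asarray(y_pred, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def pair_count_auc(scores, labels):
    """Oracle: fraction of positive-negative pairs ranked correctly, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = wins = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                wins += 1
            elif p == n:
                wins += 0.5
    return wins / total


class TestMcc:
    @pytest.mark.parametrize(
        "cm,expected",
        [
            (ConfusionMatrix(10, 10, 0, 0), 1.0),
            (ConfusionMatrix(0, 0, 10, 10), -1.0),
            (ConfusionMatrix(3, 4, 1, 2), 10 / np.sqrt(600)),
            (ConfusionMatrix(5, 0, 0, 0), 0.0),  # degenerate denominator
        ],
    )
    def test_direct_values(self, cm, expected):
        assert kv.mcc(cm) == pytest.approx(expected)

    def test_matches_pearson_oracle_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            cm = ConfusionMatrix(*[int(x) for x in rng.integers(0, 30, size=4)])
            assert kv.mcc(cm) == pytest.approx(pearson_mcc(cm), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestRoc:
    def test_perfect_separation(self):
        curve = kv.roc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_three_of_four_pairs_concordant(self):
        curve = kv.roc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(0.75)

    def test_all_ties_is_chance(self):
        assert kv.roc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(EvaluationError):
            kv.roc([0.1, 0.9], [1, 1])

    def test_curve_is_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        curve = kv.roc(scores, labels)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all((curve.fpr >= 0) & (curve.fpr <= 1))
        assert np.all((curve.tpr >= 0) & (curve.tpr <= 1))

    def test_auc_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(4, 20))
            scores = rng.integers(0, 6, size=n) / 5.0  # coarse grid forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert kv.roc(scores, labels).auc == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-9
            )


class TestOptimizeThreshold:
    def test_exhaustive_scan_returns_smallest_optimal_threshold(self):
        t, m = kv.optimize_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m == pytest.approx(1.0)
        assert t == pytest.approx(0.21)

    def test_scores_equal_to_labels(self):
        t, m = kv.optimize_threshold([0.0, 1.0, 1.0, 0.0], [0, 1, 1, 0])
        assert m == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            kv.optimize_threshold([0.2, 0.8], [1, 1])

    def test_never_worse_than_default_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            _, best = kv.optimize_threshold(scores, labels)
            assert best >= kv.mcc(confusion(scores, labels, 0.5)) - 1e-12


class TestCvPlan:
    def test_study_scale_partition(self):
        plan = kv.make_cv_plan(470, k=25, seed=0)
        sizes = collections.Counter(
            np.bincount(plan.assignment, minlength=25).tolist()
        )
        assert sizes == {19: 20, 18: 5}
        held_out = [len(te) for _, _, _, te in plan.folds()]
        train_sizes = [len(tr) for _, tr, _, _ in plan.folds()]
        assert collections.Counter(held_out).most_common(1)[0][0] == 19
        assert collections.Counter(train_sizes).most_common(1)[0][0] == 432

    def test_rotation_covers_each_subset_once(self):
        plan = kv.make_cv_plan(20, k=5, seed=1)
        test_sets = [tuple(sorted(te)) for _, _, _, te in plan.folds()]
        assert len(set(test_sets)) == 5
        assert sorted(i for te in test_sets for i in te) == list(range(20))

    def test_tiny_split(self):
        plan = kv.make_cv_plan(4, k=2, seed=0)
        assert sorted(np.bincount(plan.assignment).tolist()) == [2, 2]

    def test_same_seed_same_plan(self):
        a = kv.make_cv_plan(100, k=25, seed=7)
        b = kv.make_cv_plan(100, k=25, seed=7)
        assert np.array_equal(a.assignment, b.assignment)

    def test_too_few_records_rejected(self):
        with pytest.raises(EvaluationError):
            kv.make_cv_plan(10, k=25, seed=0)


class TestOversample:
    def test_replication_arithmetic_mirrors_study_folds(self):
        experimental = np.zeros(500, dtype=bool)
        experimental[:115] = True  # 115 experimental + 317 non-perturbing fold
        fold = np.arange(432)
        expanded = kv.oversample(fold, experimental, 3, np.random.default_rng(0))
        assert len(expanded) == 115 * 3 + 317

    def test_no_experimental_records_unchanged(self):
        experimental = np.zeros(50, dtype=bool)
        fold = np.arange(50)
        expanded = kv.oversample(fold, experimental, 3, np.random.default_rng(0))
        assert sorted(expanded) == sorted(fold)

    def test_multiset_of_identities_preserved(self):
        experimental = np.array([True, False, True, False])
        expanded = kv.oversample(np.arange(4), experimental, 3,
                                 np.random.default_rng(1))
        assert collections.Counter(expanded.tolist()) == {0: 3, 2: 3, 1: 1, 3: 1}


class TestEntropySeparation:
    def test_pure_sides_score_zero(self):
        scores = [0.01, 0.02, 0.2, 0.9]
        is_benign = [0, 0, 1, 1]
        assert entropy_separation(scores, is_benign) == pytest.approx(0.0)

    def test_fully_mixed_sides_score_one(self):
        scores = [0.01, 0.01, 0.9, 0.9]
        is_benign = [0, 1, 0, 1]
        assert entropy_separation(scores, is_benign) == pytest.approx(1.0)

    def test_half_pure_half_mixed(self):
        # one side pure (two non-perturbing), other side 50/50, equal weights
        scores = [0.01, 0.01, 0.9, 0.9]
        is_benign = [0, 0, 0, 1]
        assert entropy_separation(scores, is_benign) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            entropy_separation([0.1, 0.9], [1, 1])


class TestRocConfidenceBand:
    def test_band_brackets_member_curves_and_collapses_for_one(self):
        from kvarpred.evaluation import roc_confidence_band

        rng = np.random.default_rng(8)
        curves = []
        for _ in range(10):
            scores = rng.random(40)
            labels = rng.integers(0, 2, 40)
            labels[:2] = [0, 1]
            curves.append(kv.roc(scores, labels))
        grid, low, high = roc_confidence_band(curves, level=0.5)
        assert np.all(low <= high)
        assert np.all((low >= 0) & (high <= 1))
        # a single curve yields a zero-width band equal to itself
        g, l, h = roc_confidence_band(curves[:1])
        assert np.allclose(l, h)

    def test_degenerate_inputs_rejected(self):
        from kvarpred.evaluation import roc_confidence_band

        with pytest.raises(EvaluationError):
            roc_confidence_band([])


@pytest.fixture(scope="module")
def tiny_cv():
    rng = np.random.default_rng(0)
    n = 60
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + 0.3 * rng.normal(size=n) > 0).astype(int)
    Y = np.column_stack([y] * 4)
    experimental = np.ones(n, dtype=bool)
    experimental[45:] = False
    Y[45:] = 0
    cfg = kv.config_for("EVO2", iterations=60)
    plan = kv.make_cv_plan(n, k=5, seed=2)
    return kv.run_cv(X, Y, experimental, "EVO2", cfg, plan, seed=2)


class TestRunCv:
    def test_report_is_internally_consistent(self, tiny_cv):
        _, report = tiny_cv
        assert report.mcc_average == pytest.approx(
            np.mean(list(report.mcc_per_output.values()))
        )
        assert report.n_experimental == 45
        assert report.n_nonperturbing == 15
        for v in report.mcc_per_output.values():
            assert -1.0 <= v <= 1.0

    def test_ensemble_has_one_model_per_rotation_and_thresholds(self, tiny_cv):
        ensemble, _ = tiny_cv
        assert len(ensemble.models) == 5
        assert ensemble.thresholds.shape == (4,)
        scores = ensemble.predict(np.zeros((3, 2)))
        assert scores.shape == (3, 4)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_single_class_labels_surface_as_error(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        Y = np.zeros((30, 4), dtype=int)
        cfg = kv.config_for("EVO2", iterations=10)
        plan = kv.make_cv_plan(30, k=5, seed=0)
        with pytest.raises(EvaluationError):
            kv.run_cv(X, Y, np.ones(30, dtype=bool), "EVO2", cfg, plan, seed=0)
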