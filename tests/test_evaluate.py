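import itertools

import numpy as np
import pytest

from dtifuse.cnn import LabeledPairSet
from dtifuse.data import InteractionNetwork
from dtifuse.evaluate import (
    classification_metrics,
    cold_start_features,
    kfold_split,
    pr_auc,
    roc_auc,
    run_cross_validation,
    sample_negative_pairs,
    shuffled_network,
)
from dtifuse.features import FeatureMatrix


def brute_force_roc_auc(scores, labels):
    """P(score_pos > score_neg) + P(tie)/2 over all positive-negative pairs."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            wins += sp > sn
            ties += sp == sn
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_pr_auc(scores, labels):
    """Step-curve area from an exhaustive descending-threshold sweep."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos = labels.sum()
    area = prev_recall = 0.0
    thresholds = sorted(set(scores), reverse=True)
    for t in thresholds:
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        precision = tp / pred.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestMetricOracles:
    def test_spec_hand_case(self):
        assert roc_auc([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        assert roc_auc(scores, labels) == 1.0
        assert pr_auc(scores, labels) == 1.0

    def test_all_ties_gives_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [0, 0])

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(2, 21))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force plenty of ties
            scores = rng.integers(0, 5, n) / 4.0
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_roc_auc(scores, labels), abs=1e-12
            )
            assert pr_auc(scores, labels) == pytest.approx(
                brute_force_pr_auc(scores, labels), abs=1e-12
            )

    def test_matches_brute_force_on_all_label_patterns(self):
        rng = np.random.default_rng(1)
        for n in (2, 3, 4, 5):
            scores = rng.random(n)
            for labels in itertools.product([0, 1], repeat=n):
                labels = np.array(labels)
                if labels.min() == labels.max():
                    continue
                assert roc_auc(scores, labels) == pytest.approx(
                    brute_force_roc_auc(scores, labels), abs=1e-12
                )
                assert pr_auc(scores, labels) == pytest.approx(
                    brute_force_pr_auc(scores, labels), abs=1e-12
                )


class TestClassificationMetrics:
    def test_perfect(self):
        m = classification_metrics([0.9, 0.1], [1, 0], 0.5)
        assert (m["acc"], m["precision"], m["recall"], m["f1"]) == (1, 1, 1, 1)

    def test_total_inversion(self):
        m = classification_metrics([0.1, 0.9], [1, 0], 0.5)
        assert (m["acc"], m["precision"], m["recall"], m["f1"]) == (0, 0, 0, 0)

    def test_confusion_arithmetic(self):
        # 3 TP, 1 FP, 1 FN, 1 TN
        scores = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1]
        labels = [1, 1, 1, 0, 1, 0]
        m = classification_metrics(scores, labels, 0.5)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.75)

    def test_no_positive_predictions_flagged(self):
        m = classification_metrics([0.1, 0.2], [1, 0], 0.5)
        assert m["precision"] == 0.0 and m["no_positive_predictions"]


class TestNegativeSampling:
    def test_saturated_network_errors(self):
        net = InteractionNetwork(np.ones((2, 2), dtype=np.int8), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            sample_negative_pairs(net, 1, seed=0)

    def test_forced_outcome(self):
        A = np.array([[1, 0], [1, 1]], dtype=np.int8)
        net = InteractionNetwork(A, ["a", "b"], ["x", "y"])
        assert sample_negative_pairs(net, 1, seed=123) == [(0, 1)]

    def test_disjoint_from_positives_and_exclusions(self):
        rng = np.random.default_rng(2)
        A = (rng.random((10, 12)) < 0.3).astype(np.int8)
        net = InteractionNetwork(A, [f"d{i}" for i in range(10)], [f"p{j}" for j in range(12)])
        exclude = {(0, 1), (2, 3)} - set(map(tuple, np.argwhere(A == 1)))
        got = sample_negative_pairs(net, 20, seed=5, exclude=exclude)
        assert len(set(got)) == 20
        for i, j in got:
            assert A[i, j] == 0 and (i, j) not in exclude

    def test_deterministic(self):
        A = np.zeros((6, 6), dtype=np.int8)
        net = InteractionNetwork(A, [f"d{i}" for i in range(6)], [f"p{j}" for j in range(6)])
        assert sample_negative_pairs(net, 5, seed=9) == sample_negative_pairs(net, 5, seed=9)


class TestKfold:
    def make_set(self, n_pos, n_neg):
        pairs = [(i, 0) for i in range(n_pos + n_neg)]
        labels = np.array([1] * n_pos + [0] * n_neg)
        return LabeledPairSet(pairs, labels)

    def test_even_sizes(self):
        folds = kfold_split(self.make_set(5, 5), 5, seed=0, stratified=False)
        assert sorted(np.bincount(folds).tolist()) == [2, 2, 2, 2, 2]

    def test_stratified_balance(self):
        s = self.make_set(10, 10)
        folds = kfold_split(s, 5, seed=1, stratified=True)
        for f in range(5):
            mask = folds == f
            assert s.labels[mask].sum() == 2 and (1 - s.labels[mask]).sum() == 2

    def test_partition(self):
        s = self.make_set(7, 6)
        folds = kfold_split(s, 3, seed=2)
        assert folds.shape == (13,)
        assert set(folds) == {0, 1, 2}

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kfold_split(self.make_set(2, 5), 5, seed=0, stratified=True)


class TestColdStart:
    def make_fused(self, rows):
        ids = [f"e{i}" for i in range(len(rows))]
        return FeatureMatrix(np.array(rows, dtype=float), ids, "fused")

    def test_identical_neighbors_reproduce_vector(self):
        attrs = FeatureMatrix(np.tile([1.0, 0.0, 1.0, 0.0], (3, 1)),
                              ["e0", "e1", "e2"], "fingerprint")
        fused = self.make_fused([[2.0, 4.0]] * 3)
        out = cold_start_features(attrs, fused, np.array([1, 0, 1, 0]))
        assert np.allclose(out, [2.0, 4.0])

    def test_unit_basis_weighting(self):
        attrs = FeatureMatrix(
            np.array([[1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 1], [0, 1, 1, 1]], dtype=float),
            ["e0", "e1", "e2", "e3"], "fingerprint",
        )
        fused = self.make_fused(np.eye(4).tolist())
        # query equals e0's fingerprint: similarity order e0 > e1 = e2 > e3,
        # with the e1/e2 tie broken lexicographically
        out = cold_start_features(attrs, fused, np.array([1, 1, 0, 0]))
        assert np.allclose(out, [0.6, 0.3, 0.1, 0.0])

    def test_tie_breaks_by_id(self):
        attrs = FeatureMatrix(np.tile([1.0, 0.0], (4, 1)), ["b", "a", "d", "c"], "fingerprint")
        fused = FeatureMatrix(np.diag([1.0, 2.0, 3.0, 4.0]), ["b", "a", "d", "c"], "fused")
        out = cold_start_features(attrs, fused, np.array([1.0, 0.0]))
        # all similarities tie; neighbors are a, b, c by id order
        assert np.allclose(out, [0.3 * 1, 0.6 * 2, 0.0, 0.1 * 4])

    def test_needs_three_entities(self):
        attrs = FeatureMatrix(np.ones((2, 2)), ["a", "b"], "fingerprint")
        fused = FeatureMatrix(np.ones((2, 3)), ["a", "b"], "fused")
        with pytest.raises(ValueError, match="at least 3"):
            cold_start_features(attrs, fused, np.ones(2))

    def test_cosine_metric_for_kmer(self):
        attrs = FeatureMatrix(
            np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]]), ["e0", "e1", "e2"], "kmer"
        )
        fused = self.make_fused([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        out = cold_start_features(attrs, fused, np.array([1.0, 0.0]))
        # cosine: a=1.0, c=0.707, b=0.0
        assert np.allclose(out, [0.6, 0.1, 0.3])


class TestCrossValidationSmall:
    def test_report_structure_and_determinism(self, tiny_dataset, fast_config):
        net = tiny_dataset["network"]
        rep1 = run_cross_validation(net, tiny_dataset["drugs"], tiny_dataset["proteins"],
                                    fast_config, k=3, seed=5)
        rep2 = run_cross_validation(net, tiny_dataset["drugs"], tiny_dataset["proteins"],
                                    fast_config, k=3, seed=5)
        assert rep1.to_dict() == rep2.to_dict()
        assert len(rep1.per_fold) == 3
        for rec in rep1.per_fold:
            for m in ("auc", "aupr", "acc", "precision", "recall", "f1"):
                assert 0.0 <= rec[m] <= 1.0
        n_test = sum(r["n_test_pos"] for r in rep1.per_fold)
        assert n_test == net.A.sum()

    def test_recovers_planted_structure(self, tiny_dataset, fast_config):
        net = tiny_dataset["network"]
        rep = run_cross_validation(net, tiny_dataset["drugs"], tiny_dataset["proteins"],
                                   fast_config, k=3, seed=5)
        assert rep.mean["auc"] > 0.7

    def test_noise_free_reference_benchmark_recovery(self):
        """Without label noise the pipeline recovers the planted structure on
        the reference-size benchmark (100 x 80, density 0.05, seed 7)."""
        from dtifuse.simulate import SyntheticConfig, simulate_dataset

        cfg = SyntheticConfig(
            n_drugs=100, n_targets=80, interaction_density_target=0.05,
            label_noise=0.0, seed=7,
        )
        net, drugs, prots, _, _ = simulate_dataset(cfg)
        rep = run_cross_validation(net, drugs, prots, None, k=5, seed=7)
        assert rep.mean["auc"] >= 0.80
        assert rep.mean["aupr"] >= 0.75

    def test_shuffled_network_preserves_count(self, tiny_dataset):
        net = tiny_dataset["network"]
        null = shuffled_network(net, seed=3)
        assert null.A.sum() == net.A.sum()
        assert not np.array_equal(null.A, net.A)
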