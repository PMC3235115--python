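"""Nearest-neighbor prediction, jackknife, metrics, IFS and analysis."""

import math

import numpy as np
import pytest

import pcasite as p


class TestDistance:
    def test_self_distance_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert p.nna_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_distance_one(self):
        assert p.nna_distance(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 1.0

    def test_antiparallel_vectors_distance_two(self):
        a = np.array([1.0, -2.0, 0.5])
        assert p.nna_distance(a, -a) == pytest.approx(2.0, abs=1e-12)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError, match="zero vector"):
            p.nna_distance(np.zeros(3), np.ones(3))

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            p.nna_distance(np.ones(3), np.ones(4))


class TestPredict:
    def test_query_equal_to_training_vector(self):
        train = np.array([[1.0, 0.0], [0.0, 1.0]])
        labels = np.array([1, 0])
        assert p.nna_predict(train, np.array([0.0, 1.0]), labels) == 0

    def test_equidistant_tie_goes_to_lower_index(self):
        train = np.array([[1.0, 1.0], [1.0, 1.0]])
        labels = np.array([0, 1])
        assert p.nna_predict(train, np.array([2.0, 2.0]), labels) == 0

    def test_two_cluster_separation(self):
        rng = np.random.default_rng(4)
        a = rng.normal([5, 5, 5], 0.2, size=(20, 3))
        b = rng.normal([5, -5, 5], 0.2, size=(20, 3))
        train = np.vstack([a, b])
        labels = np.array([1] * 20 + [0] * 20)
        for q in rng.normal([5, 5, 5], 0.2, size=(10, 3)):
            assert p.nna_predict(train, q, labels) == 1

    def test_agrees_with_pairwise_oracle(self):
        """Prediction equals an exhaustive per-sample distance scan."""
        rng = np.random.default_rng(8)
        for _ in range(100):
            train = rng.integers(1, 6, size=(12, 4)).astype(float)
            labels = rng.integers(0, 2, size=12)
            q = rng.integers(1, 6, size=4).astype(float)
            dists = [p.nna_distance(q, t) for t in train]
            expected = labels[int(np.argmin(dists))]
            assert p.nna_predict(train, q, labels) == expected


class TestJackknife:
    def test_two_mutually_nearest_opposite_labels(self):
        values = np.array([[1.0, 0.9], [0.9, 1.0]])
        labels = np.array([1, 0])
        c = p.jackknife(values, [0, 1], labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 1, 1)

    def test_perfect_separation_has_no_errors(self):
        rng = np.random.default_rng(5)
        a = rng.normal([10, 10], 0.1, size=(10, 2))
        b = rng.normal([10, -10], 0.1, size=(10, 2))
        values = np.vstack([a, b])
        labels = np.array([1] * 10 + [0] * 10)
        c = p.jackknife(values, [0, 1], labels)
        assert c.fp == 0 and c.fn == 0

    def test_duplicated_samples_give_perfect_accuracy(self):
        rng = np.random.default_rng(6)
        base = rng.integers(1, 9, size=(15, 5)).astype(float)
        labels_base = rng.integers(0, 2, size=15)
        values = np.vstack([base, base])
        labels = np.concatenate([labels_base, labels_base])
        c = p.jackknife(values, list(range(5)), labels)
        m = p.compute_metrics(c)
        assert m.accuracy == 1.0

    def test_matches_per_sample_refit_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            values = rng.integers(1, 7, size=(20, 5)).astype(float)
            labels = rng.integers(0, 2, size=20)
            c = p.jackknife(values, list(range(5)), labels)
            tp = tn = fp = fn = 0
            for i in range(20):
                rest = np.delete(values, i, axis=0)
                rest_y = np.delete(labels, i)
                pred = p.nna_predict(rest, values[i], rest_y)
                if pred and labels[i]:
                    tp += 1
                elif pred and not labels[i]:
                    fp += 1
                elif not pred and labels[i]:
                    fn += 1
                else:
                    tn += 1
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_empty_feature_subset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            p.jackknife(np.ones((3, 2)), [], np.array([0, 1, 0]))


class TestMetrics:
    def test_perfect_prediction(self):
        m = p.compute_metrics(p.ConfusionCounts(333, 1665, 0, 0))
        assert (m.sensitivity, m.specificity, m.accuracy, m.mcc) == (1, 1, 1, 1)

    def test_all_negative_predictions_mcc_zero(self):
        m = p.compute_metrics(p.ConfusionCounts(0, 10, 0, 5))
        assert m.sensitivity == 0.0
        assert m.mcc == 0.0  # zero-denominator convention

    def test_hand_arithmetic(self):
        m = p.compute_metrics(p.ConfusionCounts(5, 7, 1, 3))
        assert m.sensitivity == pytest.approx(5 / 8)
        assert m.specificity == pytest.approx(7 / 8)
        assert m.accuracy == pytest.approx(12 / 16)
        assert m.mcc == pytest.approx((5 * 7 - 1 * 3) / math.sqrt(6 * 8 * 8 * 10))

    def test_mcc_invariant_under_class_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            a = p.compute_metrics(p.ConfusionCounts(tp, tn, fp, fn)).mcc
            b = p.compute_metrics(p.ConfusionCounts(tn, tp, fn, fp)).mcc
            assert a == pytest.approx(b, abs=1e-12)


class TestIFS:
    def test_single_feature_table(self):
        values = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        y = np.array([1, 1, 0, 0])
        ranked = p.RankedFeatures([0], [1], [0.5])
        table = p.ifs(values, ranked, y)
        assert len(table.records) == 1
        assert table.optimal_k == 1

    def test_prefix_metrics_match_direct_jackknife(self, planted_matrix):
        """Incremental Gram evaluation equals per-subset jackknife."""
        values = np.round(planted_matrix.values * 2)  # integer-valued
        y = planted_matrix.labels
        ranked = p.mrmr_rank(values, y)
        table = p.ifs(values, ranked, y)
        for k, metrics in table.records[:8] + table.records[-2:]:
            direct = p.compute_metrics(
                p.jackknife(values, ranked.order[:k], y)
            )
            assert metrics == direct

    def test_optimal_k_is_smallest_argmax(self):
        values = np.array([[3.0, 1.0], [2.9, -1.0], [-3.0, 1.0], [-2.9, -1.0]] * 3)
        y = np.array([1, 1, 0, 0] * 3)
        ranked = p.RankedFeatures([0, 1], [1, 2], [1.0, 0.0])
        table = p.ifs(values, ranked, y)
        ks = [k for k, m in table.records if m.mcc == table.max_mcc]
        assert table.optimal_k == min(ks)

    def test_stride_includes_full_set(self, planted_matrix):
        ranked = p.mrmr_rank(planted_matrix)
        table = p.ifs(planted_matrix, ranked, stride=7)
        ks = [k for k, _ in table.records]
        assert ks[-1] == planted_matrix.n_features
        assert all(b - a == 7 for a, b in zip(ks, ks[1:-1]))

    def test_reproducible(self, planted_matrix):
        ranked = p.mrmr_rank(planted_matrix)
        a = p.ifs(planted_matrix, ranked)
        b = p.ifs(planted_matrix, ranked)
        assert a.records == b.records and a.optimal_k == b.optimal_k


class TestAnalysis:
    def test_full_schema_family_counts(self, schema10):
        analysis = p.analyze_feature_set(schema10, list(range(727)))
        assert analysis.counts_by_family == {
            "PSSM": 420, "AAFactor": 100, "Disorder": 21,
            "SecondaryStructure": 63, "Accessibility": 42,
            "InterfaceSurface": 40, "GainLoss": 20, "CarbonDeviation": 21,
        }
        assert all(
            analysis.counts_by_site[s] == (27 if s == 11 else 35)
            for s in range(1, 22)
        )
        assert analysis.total == 727

    def test_empty_subset_all_zeros(self, schema10):
        analysis = p.analyze_feature_set(schema10, [])
        assert analysis.total == 0

    def test_single_site_pssm_block(self, schema10):
        cols = [j for j, d in enumerate(schema10)
                if d.site == 10 and d.family == "PSSM"]
        analysis = p.analyze_feature_set(schema10, cols)
        assert analysis.counts_by_family["PSSM"] == 20
        assert analysis.counts_by_site[10] == 20

    def test_duplicate_indices_error(self, schema10):
        with pytest.raises(ValueError, match="duplicate"):
            p.analyze_feature_set(schema10, [1, 1, 2])
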