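"""Mutual information, discretization and mRMR ranking."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcasite as p


def mi_oracle(x, y):
    """Direct double-sum over the empirical joint table, in bits."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    mi = 0.0
    for a in sorted(px):
        for b in sorted(py):
            c = joint.get((a, b), 0)
            if c:
                pab = c / n
                mi += pab * math.log2(pab / ((px[a] / n) * (py[b] / n)))
    return max(mi, 0.0)


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = np.array([0, 1] * 16)
        assert p.mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_product_table_is_zero(self):
        # joint counts equal the product of the marginals by construction
        x, y = np.meshgrid(np.arange(3), np.arange(4))
        assert p.mutual_information(x.ravel(), y.ravel()) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_matches_direct_summation_on_2x2_counts(self):
        counts = {(0, 0): 30, (0, 1): 10, (1, 0): 5, (1, 1): 25}
        x = np.concatenate([[a] * c for (a, _), c in sorted(counts.items())])
        y = np.concatenate([[b] * c for (_, b), c in sorted(counts.items())])
        assert p.mutual_information(x, y) == pytest.approx(
            mi_oracle(x, y), abs=1e-12
        )

    def test_symmetry_and_entropy_bound_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, size=100)
            y = rng.integers(0, 3, size=100)
            mi = p.mutual_information(x, y)
            assert mi == pytest.approx(p.mutual_information(y, x), abs=1e-12)
            assert -1e-12 <= mi <= min(p.entropy(x), p.entropy(y)) + 1e-12

    def test_deterministic_relation_gives_full_entropy(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 5, size=200)
        y = (x * 7 + 3) % 5  # bijection of categories
        assert p.mutual_information(x, y) == pytest.approx(p.entropy(x), abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="equal-length"):
            p.mutual_information(np.arange(5), np.arange(6))

    def test_cross_check_against_sklearn(self):
        """Independent route: sklearn's plug-in MI (nats) times 1/ln 2."""
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.integers(0, 4, size=150)
            y = (x + rng.integers(0, 3, size=150)) % 4
            expected = mutual_info_score(x, y) / math.log(2)
            assert p.mutual_information(x, y) == pytest.approx(expected, abs=1e-10)


class TestDiscretize:
    def test_constant_column_single_category(self):
        out = p.discretize(np.full(10, 3.3), p.DiscretizationRule())
        assert set(out) == {0}

    def test_three_state_thresholds(self):
        x = np.array([-10.0, 0.0, 10.0])
        # mu = 0, sigma = sqrt(200/3); +/- sigma brackets only the extremes
        out = p.discretize(x, p.DiscretizationRule())
        np.testing.assert_array_equal(out, [0, 1, 2])

    def test_three_states_populated_on_normal_sample(self):
        x = np.random.default_rng(2).standard_normal(5000)
        out = p.discretize(x, p.DiscretizationRule())
        assert set(out) == {0, 1, 2}
        # ~68% of a normal sample falls within mean +/- sigma
        assert 0.6 < np.mean(out == 1) < 0.76

    def test_equal_frequency_bins_are_balanced(self):
        x = np.arange(100, dtype=float)
        out = p.discretize(x, p.DiscretizationRule("equal-frequency", 4))
        assert [np.sum(out == b) for b in range(4)] == [25, 25, 25, 25]

    def test_none_passes_categories_through(self):
        x = np.array([5.0, 5.0, 9.0, 7.0])
        out = p.discretize(x, p.DiscretizationRule("none"))
        assert len(np.unique(out)) == 3


def mrmr_oracle(values, y, rule):
    """Exhaustive greedy recomputation: each round rescans every
    remaining feature, recomputing relevance and redundancy from scratch."""
    n_feat = values.shape[1]
    disc = [p.discretize(values[:, j], rule) for j in range(n_feat)]
    selected: list[int] = []
    remaining = list(range(n_feat))
    while remaining:
        best, best_score = None, None
        for j in remaining:  # ascending index -> lowest-index tie-break
            rel = mi_oracle(disc[j], y)
            if selected:
                red = 0.0
                for s in selected:  # selection order
                    red += mi_oracle(disc[j], disc[s])
                score = rel - red / len(selected)
            else:
                score = rel
            if best_score is None or score > best_score:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return selected


class TestMrmrRank:
    def test_single_feature(self):
        values = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        ranked = p.mrmr_rank(values, y, rule=p.DiscretizationRule("none"))
        assert ranked.order.tolist() == [0]
        assert ranked.round_index.tolist() == [1]

    def test_round_one_maximizes_pure_relevance(self, planted_matrix):
        ranked = p.mrmr_rank(planted_matrix)
        rule = p.DiscretizationRule()
        rels = [
            p.mutual_information(
                p.discretize(planted_matrix.values[:, j], rule),
                planted_matrix.labels,
            )
            for j in range(planted_matrix.n_features)
        ]
        assert rels[ranked.order[0]] == max(rels)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        rule = p.DiscretizationRule("none")
        for _ in range(8):
            n, m = int(rng.integers(20, 60)), int(rng.integers(2, 7))
            values = rng.integers(0, 3, size=(n, m)).astype(float)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            ranked = p.mrmr_rank(values, y, rule=rule)
            assert ranked.order.tolist() == mrmr_oracle(values, y, rule)

    def test_duplicated_column_selected_later_than_twin(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=80)
        informative = (y + rng.integers(0, 2, size=80)).astype(float)
        values = np.column_stack(
            [informative, informative, rng.integers(0, 3, size=80).astype(float)]
        )
        ranked = p.mrmr_rank(values, y, rule=p.DiscretizationRule("none"))
        assert ranked.round_index[0] < ranked.round_index[1]
        assert ranked.order[0] == 0  # tie at round 1 broken to lowest index

    def test_invariant_to_row_order(self, planted_matrix):
        ranked = p.mrmr_rank(planted_matrix)
        rng = np.random.default_rng(0)
        perm = rng.permutation(planted_matrix.n_samples)
        shuffled = p.mrmr_rank(
            planted_matrix.values[perm], planted_matrix.labels[perm]
        )
        assert ranked.order.tolist() == shuffled.order.tolist()

    def test_constant_labels_error(self):
        values = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="constant"):
            p.mrmr_rank(values, np.zeros(10, dtype=int))


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_mi_nonnegative_and_symmetric(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 5, size=50)
    y = rng.integers(0, 5, size=50)
    mi = p.mutual_information(x, y)
    assert mi >= 0.0
    assert mi == pytest.approx(p.mutual_information(y, x), abs=1e-12)
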