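"""MRMR ranking, RUSBoost, and hyperparameter optimization."""

import itertools

import numpy as np
import pytest

from arslab.exceptions import ValidationError
from arslab.selection import (
    DEFAULT_SPACES,
    RUSBoostClassifier,
    discretize_equal_frequency,
    mrmr_rank,
    mutual_information,
    optimize_and_fit,
    predict,
    select_subset,
)


def brute_force_miq(codes: np.ndarray, y: np.ndarray) -> list[int]:
    """Independent oracle: literal greedy MIQ over discrete columns."""
    n = codes.shape[1]
    relevance = [mutual_information(codes[:, j], y) for j in range(n)]
    selected: list[int] = []
    remaining = list(range(n))
    while remaining:
        if not selected:
            scores = [relevance[j] for j in remaining]
        else:
            scores = []
            for j in remaining:
                red = np.mean([mutual_information(codes[:, j], codes[:, s]) for s in selected])
                scores.append(relevance[j] / max(red, 1e-12))
        pick = remaining[int(np.argmax(scores))]
        selected.append(pick)
        remaining.remove(pick)
    return selected


class TestMRMR:
    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=300)
        X = rng.standard_normal((300, 5))
        X[:, 3] = y + 0.01 * rng.standard_normal(300)
        ranking = mrmr_rank(X, y)
        assert ranking.order[0] == 3

    def test_duplicate_of_top_feature_penalized(self):
        """An exact duplicate of the top feature falls behind a weaker but
        independent feature at position 2."""
        rng = np.random.default_rng(1)
        n = 2000
        y = rng.integers(0, 2, size=n)
        strong = y + 0.05 * rng.standard_normal(n)
        weak = y + 1.5 * rng.standard_normal(n)  # informative but noisy
        X = np.column_stack([strong, strong.copy(), weak])
        ranking = mrmr_rank(X, y)
        assert ranking.order[0] == 0
        assert ranking.order[1] == 2  # independent feature beats the duplicate
        # hand MIQ check: the duplicate's redundancy is the full bin entropy
        codes = discretize_equal_frequency(X)
        miq_dup = mutual_information(codes[:, 1], y) / mutual_information(codes[:, 1], codes[:, 0])
        miq_weak = mutual_information(codes[:, 2], y) / mutual_information(codes[:, 2], codes[:, 0])
        assert miq_weak > miq_dup

    def test_single_feature(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 1))
        y = (X[:, 0] > 0).astype(int)
        ranking = mrmr_rank(X, y)
        assert list(ranking.order) == [0]

    def test_matches_brute_force_on_small_instances(self):
        """Exhaustive equivalence on <=6-feature problems."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            n, d = 150, 5
            y = rng.integers(0, 3, size=n)
            X = rng.standard_normal((n, d))
            X[:, 0] += y
            X[:, 2] += 0.5 * y
            ranking = mrmr_rank(X, y)
            codes = discretize_equal_frequency(X)
            y_codes = np.unique(y, return_inverse=True)[1]
            assert list(ranking.order) == brute_force_miq(codes, y_codes)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            mrmr_rank(np.random.default_rng(4).standard_normal((20, 3)), np.zeros(20))

    def test_top_k_prefix_matches_full_ranking(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=200)
        X = rng.standard_normal((200, 8))
        X[:, 1] += y
        X[:, 6] += 0.7 * y
        full = mrmr_rank(X, y)
        partial = mrmr_rank(X, y, top_k=4)
        assert list(full.order[:4]) == list(partial.order[:4])
        assert sorted(partial.order) == list(range(8))


class TestSelectSubset:
    def _ranking(self, n=20):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=100)
        X = rng.standard_normal((100, n))
        return mrmr_rank(X, y)

    def test_all_is_identity_permutation(self):
        r = self._ranking()
        assert sorted(select_subset(r, "all")) == list(range(20))

    def test_prefix_and_nesting(self):
        r = self._ranking()
        s5 = select_subset(r, 5)
        s10 = select_subset(r, 10)
        assert list(s5) == list(r.order[:5])
        assert set(s5) <= set(s10)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValidationError):
            select_subset(self._ranking(), 21)


class TestRUSBoost:
    def _imbalanced_blobs(self, n_major=380, n_minor=20, seed=7):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [
                rng.standard_normal((n_major, 2)) + [0, 0],
                rng.standard_normal((n_minor, 2)) + [5, 5],
            ]
        )
        y = np.array([0] * n_major + [1] * n_minor)
        return X, y

    def test_round_subsets_are_class_balanced(self):
        X, y = self._imbalanced_blobs()
        clf = RUSBoostClassifier(n_estimators=10, random_state=0).fit(X, y)
        assert clf.round_class_counts_  # instrumentation hook populated
        for counts in clf.round_class_counts_:
            assert counts[0] == counts[1] == 20

    def test_minority_sensitivity_on_separable_imbalance(self):
        """95:5 imbalanced but separable blobs: minority recall >= 0.9."""
        X, y = self._imbalanced_blobs()
        Xte, yte = self._imbalanced_blobs(seed=8)
        clf = RUSBoostClassifier(n_estimators=30, learning_rate=0.5, random_state=1).fit(X, y)
        pred = clf.predict(Xte)
        minority_recall = np.mean(pred[yte == 1] == 1)
        assert minority_recall >= 0.9

    def test_reproducible(self):
        X, y = self._imbalanced_blobs()
        a = RUSBoostClassifier(n_estimators=15, random_state=3).fit(X, y).predict(X)
        b = RUSBoostClassifier(n_estimators=15, random_state=3).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_proba_rows_sum_to_one(self):
        X, y = self._imbalanced_blobs()
        clf = RUSBoostClassifier(n_estimators=10, random_state=0).fit(X, y)
        proba = clf.predict_proba(X[:10])
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestOptimizeAndFit:
    def _blobs(self, seed=0, n=120, gap=6.0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.standard_normal((n // 2, 3)), rng.standard_normal((n // 2, 3)) + gap]
        )
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    @pytest.mark.parametrize("kind", ["lda", "svm_rbf", "rusboost"])
    def test_chosen_config_inside_declared_ranges(self, kind):
        X, y = self._blobs()
        for seed in (0, 1, 2):
            res = optimize_and_fit(kind, X, y, budget=6, seed=seed)
            for name, rng_ in DEFAULT_SPACES[kind].items():
                lo = rng_.low if not rng_.integer else int(round(rng_.low))
                hi = rng_.high if not rng_.integer else int(round(rng_.high))
                assert lo <= res.params[name] <= hi, (kind, name)

    def test_deterministic_given_seed(self):
        X, y = self._blobs(seed=1)
        r1 = optimize_and_fit("svm_rbf", X, y, budget=10, seed=5)
        r2 = optimize_and_fit("svm_rbf", X, y, budget=10, seed=5)
        assert r1.params == r2.params
        assert [s for _, s in r1.history] == [s for _, s in r2.history]

    def test_tuned_svm_separates_gaussian_blobs(self):
        X, y = self._blobs(seed=2)
        res = optimize_and_fit("svm_rbf", X, y, budget=15, seed=0)
        assert res.best_score >= 0.99

    def test_budget_below_one_rejected(self):
        X, y = self._blobs()
        with pytest.raises(ValidationError):
            optimize_and_fit("lda", X, y, budget=0, seed=0)


class TestPredict:
    def test_lda_training_accuracy_on_separable_problem(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.standard_normal((40, 2)), rng.standard_normal((40, 2)) + 8])
        y = np.array([0] * 40 + [1] * 40)
        res = optimize_and_fit("lda", X, y, budget=4, seed=0)
        labels, proba = predict(res.model, X)
        assert np.mean(labels == y) == 1.0
        assert proba is not None and np.allclose(proba.sum(axis=1), 1.0)

    def test_empty_input(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 2))
        y = (X[:, 0] > 0).astype(int)
        res = optimize_and_fit("lda", X, y, budget=2, seed=0)
        labels, proba = predict(res.model, np.empty((0, 2)))
        assert labels.size == 0

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((30, 4))
        y = (X[:, 0] > 0).astype(int)
        res = optimize_and_fit("lda", X, y, budget=2, seed=0)
        with pytest.raises(ValidationError):
            predict(res.model, np.zeros((3, 5)))
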