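import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncdis.metrics import (
    auc_mann_whitney,
    auc_roc,
    aupr,
    confusion_at,
    sweep,
    topk_recall,
)
from lncdis.similarity import functional_similarity
from lncdis.train_eval import (
    FoldSplit,
    fuse_scores,
    make_folds,
    mask_and_recompute,
    sample_negatives,
)
from oracles import auc_pairwise_oracle


class TestSampleNegatives:
    def test_no_zero_cells_raises(self):
        with pytest.raises(ValueError):
            sample_negatives(np.ones((3, 3)), 1, seed=0)

    def test_requesting_all_zero_cells_returns_exact_complement(self):
        A = np.zeros((4, 4))
        A[0, 0] = A[1, 2] = 1
        neg = sample_negatives(A, 14, seed=0)
        got = {tuple(p) for p in neg}
        expected = {(i, j) for i in range(4) for j in range(4)} - {(0, 0), (1, 2)}
        assert got == expected

    def test_sample_is_duplicate_free_subset_of_zero_cells(self):
        rng = np.random.default_rng(0)
        A = np.zeros((10, 10))
        ones = rng.choice(100, size=20, replace=False)
        A[np.unravel_index(ones, A.shape)] = 1
        neg = sample_negatives(A, 20, seed=3)
        assert len({tuple(p) for p in neg}) == 20
        assert all(A[i, j] == 0 for i, j in neg)

    def test_reproducible_per_seed(self):
        A = np.zeros((6, 6))
        A[0, 0] = 1
        np.testing.assert_array_equal(sample_negatives(A, 5, seed=9),
                                      sample_negatives(A, 5, seed=9))

    def test_sampling_is_uniform_over_zero_cells(self):
        # chi-square over 5000 resamples of 20 cells from the 80 zero cells
        rng = np.random.default_rng(0)
        A = np.zeros((10, 10))
        ones = rng.choice(100, size=20, replace=False)
        A[np.unravel_index(ones, A.shape)] = 1
        counts = np.zeros((10, 10))
        for s in range(5000):
            for i, j in sample_negatives(A, 20, seed=s):
                counts[i, j] += 1
        observed = counts[A == 0]
        expected = 5000 * 20 / 80
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=79)


class TestMakeFolds:
    def test_even_split_into_five_equal_folds(self):
        pairs = np.arange(20).reshape(10, 2)
        folds = make_folds(pairs, pairs, seed=0)
        assert [len(f) for f in folds.pos_folds] == [2] * 5

    def test_uneven_split_differs_by_at_most_one(self):
        pairs = np.arange(22).reshape(11, 2)
        folds = make_folds(pairs, pairs, seed=0)
        sizes = [len(f) for f in folds.pos_folds]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 11

    def test_folds_partition_the_input(self, rng):
        pos = rng.integers(0, 50, size=(17, 2))
        neg = rng.integers(0, 50, size=(17, 2))
        folds = make_folds(pos, neg, seed=1)
        for source, parts in ((pos, folds.pos_folds), (neg, folds.neg_folds)):
            rows = {tuple(r) for part in parts for r in part}
            counts = sum(len(p) for p in parts)
            assert counts == len(source)
            assert rows == {tuple(r) for r in source}

    def test_too_few_positives_raises(self):
        with pytest.raises(ValueError):
            make_folds(np.zeros((3, 2)), np.zeros((10, 2)), seed=0)

    def test_train_test_views_are_complementary(self, rng):
        pos = np.arange(20).reshape(10, 2)
        neg = np.arange(100, 120).reshape(10, 2)
        folds = make_folds(pos, neg, seed=2)
        tr_pos, tr_neg, te_pos, te_neg = folds.train_test(3)
        assert len(tr_pos) + len(te_pos) == 10
        assert not ({tuple(r) for r in tr_pos} & {tuple(r) for r in te_pos})


class TestMaskAndRecompute:
    def _setup(self, rng):
        A = (rng.random((6, 5)) < 0.5).astype(float)
        D = rng.random((5, 5))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 1.0)
        return A, D

    def test_empty_test_set_is_identity(self, rng):
        A, D = self._setup(rng)
        A_tr, L_tr = mask_and_recompute(A, np.zeros((0, 2), dtype=int), D)
        np.testing.assert_array_equal(A_tr, A)
        np.testing.assert_array_equal(L_tr, functional_similarity(A, D))

    def test_masking_all_associations_of_one_lncRNA_zeroes_its_row(self, rng):
        A, D = self._setup(rng)
        A[0] = 0
        A[0, 1] = A[0, 3] = 1
        A_tr, L_tr = mask_and_recompute(A, np.array([[0, 1], [0, 3]]), D)
        assert A_tr[0].sum() == 0
        np.testing.assert_array_equal(L_tr[0, 1:], np.zeros(5))
        assert L_tr[0, 0] == 1.0

    def test_masking_one_pair_changes_only_affected_rows(self, rng):
        A, D = self._setup(rng)
        ones = np.argwhere(A == 1)
        i, j = ones[0]
        A_tr, L_tr = mask_and_recompute(A, ones[:1], D)
        L_full = functional_similarity(A, D)
        others = [e for e in range(6) if e != i]
        np.testing.assert_array_equal(L_tr[np.ix_(others, others)],
                                      L_full[np.ix_(others, others)])

    def test_masking_a_non_positive_raises(self, rng):
        A, D = self._setup(rng)
        A[2, 2] = 0
        with pytest.raises(ValueError, match="not a positive"):
            mask_and_recompute(A, np.array([[2, 2]]), D)


class TestFusion:
    def test_lambda_one_returns_left_branch(self):
        assert fuse_scores(0.9, 0.1, 1.0) == 0.9

    def test_lambda_zero_returns_right_branch(self):
        assert fuse_scores(0.9, 0.1, 0.0) == 0.1

    def test_weighted_sum_hand_value(self):
        assert fuse_scores(0.9, 0.5, 0.8) == pytest.approx(0.82)

    def test_fused_score_bounded_by_branch_scores(self, rng):
        sl, sr = rng.random(100), rng.random(100)
        lam = 0.8
        fused = fuse_scores(sl, sr, lam)
        assert (fused >= np.minimum(sl, sr) - 1e-15).all()
        assert (fused <= np.maximum(sl, sr) + 1e-15).all()
        np.testing.assert_allclose(fused, lam * sl + (1 - lam) * sr)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores(0.5, 0.5, 1.5)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(sl=st.floats(0, 1), sr=st.floats(0, 1), lam=st.floats(0, 1))
    def test_fusion_is_affine_and_bounded_for_any_inputs(self, sl, sr, lam):
        fused = fuse_scores(sl, sr, lam)
        assert min(sl, sr) - 1e-12 <= fused <= max(sl, sr) + 1e-12
        # affine in lambda: matches the two-point interpolation exactly
        assert fused == pytest.approx(sr + lam * (sl - sr), abs=1e-12)


class TestConfusion:
    def test_threshold_below_all_scores_marks_everything_positive(self):
        c = confusion_at(np.array([0.2, 0.8]), np.array([1, 0]), theta=0.0)
        assert c["TPR"] == 1.0 and c["FPR"] == 1.0

    def test_threshold_above_all_scores_marks_nothing(self):
        c = confusion_at(np.array([0.2, 0.8]), np.array([1, 0]), theta=0.9)
        assert c["TP"] == 0 and c["FP"] == 0 and c["Precision"] == 1.0

    def test_hand_counted_example(self):
        scores = np.array([0.9, 0.6, 0.4, 0.1])
        labels = np.array([1, 0, 1, 0])
        c = confusion_at(scores, labels, theta=0.5)
        assert (c["TP"], c["FP"], c["FN"], c["TN"]) == (1, 1, 1, 1)
        assert c["TPR"] == c["FPR"] == c["Precision"] == c["Recall"] == 0.5

    def test_counts_always_partition_classes(self, rng):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.5).astype(int)
        for theta in [0.0, 0.3, 0.7, 1.0]:
            c = confusion_at(scores, labels, theta)
            assert c["TP"] + c["FN"] == labels.sum()
            assert c["TN"] + c["FP"] == (1 - labels).sum()

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(data=st.data(), theta=st.floats(0, 1))
    def test_rates_stay_in_unit_interval_for_any_threshold(self, data, theta):
        n = data.draw(st.integers(2, 30))
        scores = np.asarray(data.draw(
            st.lists(st.floats(0, 1), min_size=n, max_size=n)))
        labels = np.asarray(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        c = confusion_at(scores, labels, theta)
        for key in ("TPR", "FPR", "Precision", "Recall"):
            assert 0.0 <= c[key] <= 1.0


class TestAUC:
    def test_perfect_separation_gives_one(self):
        assert auc_roc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_random_scores_give_about_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        assert auc_roc(scores, labels) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(50), 2)  # rounding forces ties
        labels = (rng.random(50) < 0.4).astype(int)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        assert auc_roc(scores, labels) == pytest.approx(
            auc_pairwise_oracle(scores, labels), abs=1e-12)
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            auc_roc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = (rng.random(100) < 0.5).astype(int)
        before = auc_roc(scores, labels)
        after = auc_roc(np.exp(3 * scores) + 7, labels)
        assert after == pytest.approx(before, abs=1e-12)

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError):
            auc_roc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        assert auc_roc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestSweepAndAUPR:
    def test_rates_monotone_in_threshold(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < 0.4).astype(int)
        sw = sweep(scores, labels)
        # thresholds descend, so TPR/FPR/Recall must be non-decreasing row-wise
        assert (np.diff(sw["TPR"]) >= 0).all()
        assert (np.diff(sw["FPR"]) >= 0).all()
        assert (np.diff(sw["Recall"]) >= 0).all()

    def test_curve_endpoints(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        sw = sweep(scores, labels)
        assert sw["TPR"][0] == 0 and sw["FPR"][0] == 0
        assert sw["TPR"][-1] == 1 and sw["FPR"][-1] == 1
        assert sw["Precision"][0] == 1.0  # anchored at recall 0

    def test_perfect_ranking_gives_unit_aupr(self):
        assert aupr(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_aupr_of_random_scores_near_class_prevalence(self):
        rng = np.random.default_rng(1)
        scores = rng.random(4000)
        labels = (rng.random(4000) < 0.2).astype(int)
        assert aupr(scores, labels) == pytest.approx(0.2, abs=0.05)


class TestTopkRecall:
    def test_all_positives_ranked_first(self):
        rankings = {0: list(range(40))}
        positives = {0: {0, 1, 2}}
        table = topk_recall(rankings, positives, [10, 40])
        assert table == {10: 1.0, 40: 1.0}

    def test_k_equal_to_candidate_count_recalls_everything(self):
        rankings = {0: [3, 1, 0, 2]}
        positives = {0: {2}}
        assert topk_recall(rankings, positives, [4]) == {4: 1.0}

    def test_positive_just_outside_top_k(self):
        ranked = list(range(40))
        positives = {0: {30}}  # sits at rank 31
        table = topk_recall({0: ranked}, positives, [30, 40])
        assert table == {30: 0.0, 40: 1.0}

    def test_k_exceeding_candidates_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            topk_recall({0: [1, 2]}, {0: {1}}, [3])

    def test_average_over_diseases(self):
        rankings = {0: [0, 1, 2, 3], 1: [3, 2, 1, 0]}
        positives = {0: {0}, 1: {0}}  # hit at rank 1 vs rank 4
        table = topk_recall(rankings, positives, [1])
        assert table[1] == pytest.approx(0.5)
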