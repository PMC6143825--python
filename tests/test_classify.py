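"""Feature extraction, nested LOOCV bookkeeping, and metric identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groupsice.classify import (
    CVResult,
    _inner_select_lambda,
    compute_metrics,
    connection_frequency,
    nested_loocv,
    train_classifier,
    unvectorize,
    vectorize,
)
from groupsice.synthetic import make_two_group_cohort


def _cv_from_scores(labels, predictions, scores, selected=None, P=3):
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    rows, cols = np.divmod(np.arange(P * P), P)
    return CVResult(
        subject_ids=[f"s{i}" for i in range(len(labels))],
        labels=labels,
        outer_predictions=predictions,
        outer_scores=np.asarray(scores, float),
        chosen_lambda=[None] * len(labels),
        selected_connections=selected or [np.zeros(0, int)] * len(labels),
        inner_fold_counts=[0] * len(labels),
        edge_index=np.column_stack([rows, cols]),
        confusion={"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        seed=0,
        mode="partial",
        P=P,
    )


class TestVectorize:
    def test_90_regions_give_8100_features(self):
        mats = [np.zeros((90, 90))]
        fm = vectorize(mats)
        assert fm.X.shape == (1, 8100)
        assert len(fm.edge_index) == 8100

    def test_row_major_order(self):
        theta = np.array([[0.0, 2.5], [1.5, 0.0]])
        fm = vectorize([theta])
        np.testing.assert_array_equal(fm.X[0], [0.0, 2.5, 1.5, 0.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.normal(size=(6, 6))
        fm = vectorize([theta])
        np.testing.assert_array_equal(unvectorize(fm.X[0], 6), theta)

    def test_edge_index_is_bijection(self):
        fm = vectorize([np.zeros((7, 7))])
        pairs = {tuple(e) for e in fm.edge_index}
        assert len(pairs) == 49
        assert pairs == {(q, p) for q in range(7) for p in range(7)}


class TestTrainClassifier:
    def test_perfect_split_uses_exactly_that_feature(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5)) * 0.01
        y = np.array([0] * 10 + [1] * 10)
        X[:, 3] = np.where(y == 1, 5.0, -5.0) + rng.normal(size=20) * 0.01
        tree = train_classifier(X, y, seed=1)
        np.testing.assert_array_equal(tree.predict(X), y)
        assert list(tree.used_features) == [3]

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(16, 10))
        y = rng.integers(0, 2, size=16)
        y[:2] = [0, 1]
        t1 = train_classifier(X, y, seed=42)
        t2 = train_classifier(X, y, seed=42)
        np.testing.assert_array_equal(t1.used_features, t2.used_features)
        np.testing.assert_array_equal(t1.predict(X), t2.predict(X))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(np.zeros((4, 2)), np.zeros(4), seed=0)

    def test_used_features_have_nonzero_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 8))
        X[:, [1, 5]] = 3.0  # constant columns cannot split
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        tree = train_classifier(X, y, seed=0)
        variances = X.var(axis=0)
        assert all(variances[f] > 0 for f in tree.used_features)


@pytest.fixture(scope="module")
def tiny_panel():
    return make_two_group_cohort(3, P=6, n_edges=6, n_flip=3, M_per_group=3, n_t=60)


class TestNestedLoocv:
    def test_three_subjects_three_outer_two_inner_folds(self):
        panel = make_two_group_cohort(
            5, P=5, n_edges=4, n_flip=2, M_per_group=2, n_t=40
        ).subset([0, 1, 2])
        cv = nested_loocv(panel, mode="sice", lambda_pool=[0.1, 0.3])
        assert len(cv.outer_predictions) == 3
        assert cv.inner_fold_counts == [2, 2, 2]

    def test_singleton_pool_forces_lambda(self, tiny_panel):
        cv = nested_loocv(tiny_panel, mode="sice", lambda_pool=[0.2])
        assert cv.chosen_lambda == [0.2] * tiny_panel.M

    def test_every_subject_tested_once_and_confusion_consistent(self, tiny_panel):
        cv = nested_loocv(tiny_panel, mode="partial")
        assert cv.M == tiny_panel.M
        c = cv.confusion
        assert c["TP"] + c["FN"] == int(np.sum(tiny_panel.labels == 1))
        assert c["TN"] + c["FP"] == int(np.sum(tiny_panel.labels == 0))

    def test_partial_modes_have_no_lambda(self, tiny_panel):
        cv = nested_loocv(tiny_panel, mode="partial", lambda_pool=[0.1, 0.2])
        assert all(l is None for l in cv.chosen_lambda)

    def test_inner_selection_never_touches_outer_test_row(self):
        # the held-out row is poisoned with NaN: any use would propagate
        rng = np.random.default_rng(7)
        M = 8
        labels = np.array([0, 1] * 4)
        F = rng.normal(size=(M, 10))
        F[0, :] = np.nan
        feats = {0.1: F, 0.2: F.copy()}
        train_idx = np.arange(1, M)
        lam, n_inner = _inner_select_lambda(feats, labels, train_idx, [0.1, 0.2], 0)
        assert lam in (0.1, 0.2)
        assert n_inner == M - 1

    def test_tie_breaks_toward_smallest_lambda(self):
        rng = np.random.default_rng(8)
        M = 6
        labels = np.array([0, 1] * 3)
        F = rng.normal(size=(M, 4))
        feats = {0.1: F, 0.5: F.copy()}  # identical features -> tied accuracy
        lam, _ = _inner_select_lambda(feats, labels, np.arange(M), [0.1, 0.5], 0)
        assert lam == 0.1

    def test_train_only_scope_runs(self, tiny_panel):
        cv = nested_loocv(
            tiny_panel,
            mode="group-partial",
            topology_scope="train_only",
            phi_grid=[0.5],
        )
        assert len(cv.outer_predictions) == tiny_panel.M


class TestMetrics:
    def test_perfect_classifier(self):
        labels = [0, 0, 1, 1]
        cv = _cv_from_scores(labels, labels, [0.0, 0.1, 0.9, 1.0])
        rep = compute_metrics(cv)
        assert (rep.acc, rep.sen, rep.spe) == (100.0, 100.0, 100.0)
        assert rep.auc == 1.0

    def test_implied_confusion_arithmetic(self):
        # TP=20, FN=5, TN=25, FP=5 -> ACC 45/55, SEN 20/25, SPE 25/30
        labels = [1] * 25 + [0] * 30
        preds = [1] * 20 + [0] * 5 + [0] * 25 + [1] * 5
        scores = [float(p) for p in preds]
        rep = compute_metrics(_cv_from_scores(labels, preds, scores))
        assert abs(rep.acc - 81.82) < 0.005
        assert abs(rep.sen - 80.00) < 0.005
        assert abs(rep.spe - 83.33) < 0.005

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_auc_equals_mann_whitney_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() == 0 or labels.sum() == n:
            return
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        rep = compute_metrics(_cv_from_scores(labels, labels, scores))
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = np.mean(
            [
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos
                for q in neg
            ]
        )
        assert abs(rep.auc - conc) < 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metric_identities_on_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = int(rng.integers(1, 12)), int(rng.integers(1, 12))
        labels = np.array([1] * n_pos + [0] * n_neg)
        preds = rng.integers(0, 2, size=n_pos + n_neg)
        rep = compute_metrics(
            _cv_from_scores(labels, preds, preds.astype(float))
        )
        c = rep.confusion
        M = n_pos + n_neg
        assert rep.acc == 100.0 * (c["TP"] + c["TN"]) / M
        assert rep.sen == 100.0 * c["TP"] / n_pos
        assert rep.spe == 100.0 * c["TN"] / n_neg

    def test_label_flip_reverses_auc(self):
        rng = np.random.default_rng(9)
        labels = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        scores = rng.normal(size=8)
        a1 = compute_metrics(_cv_from_scores(labels, labels, scores)).auc
        a2 = compute_metrics(_cv_from_scores(1 - labels, 1 - labels, scores)).auc
        assert abs(a1 + a2 - 1.0) < 1e-12

    def test_roc_is_monotone_staircase(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 2, size=15)
        labels[:2] = [0, 1]
        rep = compute_metrics(
            _cv_from_scores(labels, labels, rng.normal(size=15))
        )
        pts = rep.roc_points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_single_class_cohort_flags_not_crashes(self):
        labels = np.ones(4, int)
        rep = compute_metrics(_cv_from_scores(labels, labels, labels.astype(float)))
        assert np.isnan(rep.spe) and np.isnan(rep.auc)
        assert any("spe" in f for f in rep.flags)


class TestConnectionFrequency:
    def test_edge_in_every_fold_counts_m(self):
        labels = [0, 1, 0, 1]
        selected = [np.array([2]) for _ in labels]
        cv = _cv_from_scores(labels, labels, [0.0, 1.0, 0.0, 1.0], selected)
        table = connection_frequency(cv)
        assert table.iloc[0]["count"] == 4

    def test_empty_selections_give_empty_table(self):
        labels = [0, 1]
        cv = _cv_from_scores(labels, labels, [0.0, 1.0])
        assert len(connection_frequency(cv)) == 0

    def test_counts_sum_matches_flat_recount(self):
        rng = np.random.default_rng(11)
        labels = [0, 1, 0, 1, 0, 1]
        selected = [
            rng.choice(9, size=rng.integers(0, 5), replace=False) for _ in labels
        ]
        cv = _cv_from_scores(labels, labels, np.array(labels, float), selected)
        table = connection_frequency(cv)
        assert table["count"].sum() == sum(len(s) for s in selected)

    def test_sorted_descending_ties_by_feature_index(self):
        labels = [0, 1, 0, 1]
        selected = [np.array([5, 3]), np.array([3]), np.array([5]), np.array([1])]
        cv = _cv_from_scores(labels, labels, [0.0, 1.0, 0.0, 1.0], selected)
        table = connection_frequency(cv)
        assert list(table["feature"]) == [3, 5, 1]
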