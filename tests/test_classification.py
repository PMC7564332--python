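import numpy as np
import pandas as pd
import pytest

from nen_mirna.classification import (
    accuracy_from_confusion,
    confusion_matrix,
    correlate_markers,
    evaluate_hierarchical,
    subset_search,
    train,
    train_cosine_knn,
    train_kernel_nb,
    train_lda,
)
from nen_mirna.core_io import RFMatrix
from tests.conftest import make_annotations, uniform_rf


def _frame(rows, ids=None, feats=None):
    rows = np.asarray(rows, float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    feats = feats or [f"f{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=ids, columns=feats)


class TestLDA:
    def test_mirrored_classes_boundary_at_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(-1, 1, size=(20, 1))
        X = _frame(np.vstack([a, -a]))
        labels = pd.Series(["neg"] * 20 + ["pos"] * 20, index=X.index)
        model = train_lda(X, labels)
        q = _frame([[-0.05], [0.05]], ids=["q1", "q2"])
        pred = model.predict(q)
        assert pred["q1"] == "neg" and pred["q2"] == "pos"

    def test_weights_match_closed_form(self):
        X = _frame([[0.0, 0.0], [1.0, 1.0], [3.0, 0.0], [4.0, 1.0]])
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        model = train_lda(X, labels)
        m0 = np.array([0.5, 0.5])
        m1 = np.array([3.5, 0.5])
        s = (
            np.cov(X.to_numpy()[:2].T, ddof=1) + np.cov(X.to_numpy()[2:].T, ddof=1)
        ) / 2
        w_expected = np.linalg.solve(
            s + 1e-6 * np.trace(s) / 2 * np.eye(2), m0 - m1
        )
        assert np.allclose(model.params["weights"], w_expected, rtol=1e-5)

    def test_affine_invariance_of_predictions(self):
        rng = np.random.default_rng(1)
        X = _frame(rng.normal(size=(24, 3)))
        labels = pd.Series(["a"] * 12 + ["b"] * 12, index=X.index)
        X.iloc[12:] += [1.5, -1.0, 0.5]
        q = _frame(rng.normal(size=(10, 3)), ids=[f"q{i}" for i in range(10)])
        base = train_lda(X, labels).predict(q)
        A = np.array([[2.0, 0.3, 0.0], [0.1, 1.5, -0.2], [0.0, 0.4, 0.8]])
        b = np.array([5.0, -3.0, 1.0])
        Xt = _frame(X.to_numpy() @ A.T + b, ids=list(X.index))
        qt = _frame(q.to_numpy() @ A.T + b, ids=list(q.index))
        mapped = train_lda(Xt, labels).predict(qt)
        assert (base == mapped).all()

    def test_matches_sklearn_decisions(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(30, 2)))
        X.iloc[15:] += [2.0, 1.0]
        labels = pd.Series(["a"] * 15 + ["b"] * 15, index=X.index)
        model = train_lda(X, labels)
        ref = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(
            X.to_numpy(), labels.to_numpy()
        )
        q = _frame(rng.normal(0.8, 1.5, size=(40, 2)), ids=[f"q{i}" for i in range(40)])
        assert (model.predict(q).to_numpy() == ref.predict(q.to_numpy())).mean() == 1.0

    def test_too_many_features_rejected(self):
        X = _frame(np.eye(4))
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        with pytest.raises(ValueError, match="features"):
            train_lda(X, labels)


class TestKernelNB:
    def test_nearer_class_wins(self):
        X = _frame([[0.0], [0.2], [10.0], [10.2]])
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        model = train_kernel_nb(X, labels)
        pred = model.predict(_frame([[1.0], [9.0]], ids=["q1", "q2"]))
        assert pred["q1"] == "a" and pred["q2"] == "b"

    def test_training_point_far_from_other_class(self):
        X = _frame([[0.0], [0.5], [100.0], [100.5]])
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        model = train_kernel_nb(X, labels)
        x0, x1 = model.params["train"]
        h0, h1 = model.params["bandwidths"]
        from nen_mirna.classification import _class_log_density

        q = np.array([[0.0]])
        la = _class_log_density(x0, h0, q)[0]
        lb = _class_log_density(x1, h1, q)[0]
        post_a = 1.0 / (1.0 + np.exp(lb - la))
        assert post_a > 0.99

    def test_duplicated_feature_keeps_decision(self):
        X = _frame([[0.0], [1.0], [5.0], [6.0]])
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        q = _frame([[0.5], [5.5]], ids=["q1", "q2"])
        base = train_kernel_nb(X, labels).predict(q)
        X2 = _frame(np.hstack([X.to_numpy()] * 2), ids=list(X.index))
        q2 = _frame(np.hstack([q.to_numpy()] * 2), ids=list(q.index))
        doubled = train_kernel_nb(X2, labels).predict(q2)
        assert (base == doubled).all()

    def test_feature_permutation_invariant(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(16, 4)))
        X.iloc[8:] += 2.0
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=X.index)
        q = _frame(rng.normal(1, 1, size=(12, 4)), ids=[f"q{i}" for i in range(12)])
        base = train_kernel_nb(X, labels).predict(q)
        perm = list(X.columns[::-1])
        permuted = train_kernel_nb(X[perm], labels).predict(q[perm])
        assert (base == permuted).all()

    def test_bandwidth_floor(self):
        X = _frame([[1.0], [1.0], [2.0], [2.0]])
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        model = train_kernel_nb(X, labels)
        assert all(h.min() >= 1e-3 for h in model.params["bandwidths"])


class TestCosineKNN:
    def test_identical_to_training_vector_k1(self):
        X = _frame([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 2.1]])
        labels = pd.Series(["a", "b", "b", "b"], index=X.index)
        model = train_cosine_knn(X, labels, k=1)
        pred = model.predict(_frame([[2.0, 0.0]], ids=["q"]))
        assert pred["q"] == "a"

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        X = _frame(np.abs(rng.normal(1, 0.3, size=(10, 3))))
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=X.index)
        X.iloc[5:, 0] *= 4
        q = np.abs(rng.normal(1, 0.5, size=(6, 3)))
        model = train_cosine_knn(X, labels, k=3)
        base = model.predict(_frame(q, ids=[f"q{i}" for i in range(6)]))
        scaled = model.predict(
            _frame(q * rng.uniform(0.1, 10, size=(6, 1)), ids=[f"q{i}" for i in range(6)])
        )
        assert (base == scaled).all()

    def test_vote_matches_bruteforce(self):
        X = _frame(
            [[1, 0], [0.9, 0.1], [0.8, 0.3], [0, 1], [0.1, 0.9], [0.3, 0.8]]
        )
        labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=X.index)
        model = train_cosine_knn(X, labels, k=3)
        rng = np.random.default_rng(5)
        q = np.abs(rng.normal(0.5, 0.3, size=(8, 2))) + 0.01
        pred = model.predict(_frame(q, ids=[f"q{i}" for i in range(8)]))
        for i in range(8):
            d = [
                1 - q[i] @ X.iloc[j].to_numpy()
                / (np.linalg.norm(q[i]) * np.linalg.norm(X.iloc[j]))
                for j in range(6)
            ]
            top3 = np.argsort(d, kind="stable")[:3]
            votes = labels.iloc[top3].value_counts()
            assert pred.iloc[i] == votes.idxmax()

    def test_matches_sklearn(self):
        neighbors = pytest.importorskip("sklearn.neighbors")
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(2, 1, size=(20, 4)))
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=X.index)
        X.iloc[10:, 1] += 3
        model = train_cosine_knn(X, labels, k=3)
        ref = neighbors.KNeighborsClassifier(n_neighbors=3, metric="cosine").fit(
            X.to_numpy(), labels.to_numpy()
        )
        q = rng.normal(2, 1.2, size=(30, 4))
        mine = model.predict(_frame(q, ids=[f"q{i}" for i in range(30)]))
        assert (mine.to_numpy() == ref.predict(q)).mean() == 1.0

    def test_even_k_rejected(self):
        X = _frame([[1.0], [2.0], [3.0], [4.0]])
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        with pytest.raises(ValueError, match="odd"):
            train_cosine_knn(X, labels, k=2)

    def test_zero_vector_rejected(self):
        X = _frame([[0.0, 0.0], [1.0, 1.0], [2.0, 1.0], [1.0, 2.0]])
        labels = pd.Series(["a", "a", "b", "b"], index=X.index)
        with pytest.raises(ValueError, match="zero"):
            train_cosine_knn(X, labels, k=1)


class TestSubsetSearch:
    def _rf_with_markers(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 20
        x = np.abs(rng.normal(0.01, 0.003, size=(n, 10)))
        x[:10, 0] = 0.002  # marker1 low in class a
        x[10:, 0] = 0.05
        x[:10, 1] = 0.04  # marker2 high in class a
        x[10:, 1] = 0.004
        x = x / x.sum(axis=1, keepdims=True)
        ids = [f"s{i}" for i in range(n)]
        feats = [f"m{j}" for j in range(10)]
        rf = uniform_rf(x, ids, feats)
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=ids)
        return rf, labels

    def test_planted_pair_found_with_perfect_cv(self):
        rf, labels = self._rf_with_markers()
        res = subset_search(rf, labels, [f"m{j}" for j in range(10)], seed=0)
        assert set(res.features) <= {"m0", "m1"}
        assert res.cv_accuracy == 1.0

    def test_single_candidate_degenerates(self):
        rf, labels = self._rf_with_markers()
        res = subset_search(rf, labels, ["m3"], seed=0)
        assert res.features == ["m3"]

    def test_deterministic(self):
        rf, labels = self._rf_with_markers()
        a = subset_search(rf, labels, [f"m{j}" for j in range(6)], seed=3)
        b = subset_search(rf, labels, [f"m{j}" for j in range(6)], seed=3)
        assert (a.algorithm, a.features, a.cv_accuracy) == (
            b.algorithm, b.features, b.cv_accuracy
        )

    def test_absent_candidate_rejected(self):
        rf, labels = self._rf_with_markers()
        with pytest.raises(KeyError):
            subset_search(rf, labels, ["nope"], seed=0)

    def test_too_many_candidates_rejected(self):
        rf, labels = self._rf_with_markers()
        with pytest.raises(ValueError, match="25"):
            subset_search(rf, labels, [f"c{i}" for i in range(26)], seed=0)


def _hierarchical_fixture():
    """Cohort where one feature separates groups and one separates each
    subtype pair perfectly."""
    types = ["TC"] * 4 + ["AC"] * 4 + ["SCLC"] * 4 + ["LCNEC"] * 4
    ids = [f"s{i}" for i in range(16)]
    x = np.full((16, 4), 0.1)
    x[8:, 0] = 0.4    # f0 high in NECs
    x[4:8, 1] = 0.3   # f1 high in AC (vs TC)
    x[12:, 2] = 0.3   # f2 high in LCNEC (vs SCLC)
    x[:, 3] = 1.0 - x[:, :3].sum(axis=1)
    rf = uniform_rf(x, ids, ["f0", "f1", "f2", "rest"])
    sets = (["discovery"] * 3 + ["validation"]) * 4
    ann = make_annotations(ids, types, set_labels=sets)
    return rf, ann


class TestEvaluateHierarchical:
    def _models(self, rf, ann):
        disc = ann.samples_of_set("discovery")
        log2 = rf.log2()
        group = ann.subset(disc).group
        m1 = train_lda(log2.loc[disc, ["f0"]], group)
        carc = [s for s in disc if ann.table.loc[s, "tumor_type"] in ("TC", "AC")]
        nec = [s for s in disc if ann.table.loc[s, "tumor_type"] in ("SCLC", "LCNEC")]
        m2a = train_lda(log2.loc[carc, ["f1"]], ann.table.loc[carc, "tumor_type"])
        m2b = train_lda(log2.loc[nec, ["f2"]], ann.table.loc[nec, "tumor_type"])
        return m1, m2a, m2b

    def test_perfect_models_give_full_accuracy(self):
        rf, ann = _hierarchical_fixture()
        report = evaluate_hierarchical(*self._models(rf, ann), rf, ann)
        for s in ("discovery", "validation"):
            assert report.accuracy[s]["level1"] == 1.0
            assert report.accuracy[s]["subtype_given_level1"] == 1.0
            assert report.misclassified[s] == []

    def test_confusion_sums_to_set_sizes(self):
        rf, ann = _hierarchical_fixture()
        report = evaluate_hierarchical(*self._models(rf, ann), rf, ann)
        assert report.confusion["discovery"].to_numpy().sum() == 12
        assert report.confusion["validation"].to_numpy().sum() == 4

    def test_training_on_validation_rejected(self):
        rf, ann = _hierarchical_fixture()
        log2 = rf.log2()
        group = ann.group
        bad = train_lda(log2[["f0"]], group)  # trained on all samples
        _, m2a, m2b = self._models(rf, ann)
        with pytest.raises(ValueError, match="validation"):
            evaluate_hierarchical(bad, m2a, m2b, rf, ann)

    def test_printed_confusion_accuracy_arithmetic(self):
        """A 2x2 confusion of [[20, 0], [3, 21]] yields 41/44 ~ 93%."""
        mat = pd.DataFrame(
            [[20, 0], [3, 21]],
            index=["carcinoid", "NEC"],
            columns=["carcinoid", "NEC"],
        )
        assert accuracy_from_confusion(mat) == pytest.approx(41 / 44)
        assert round(100 * accuracy_from_confusion(mat)) == 93

    def test_constant_predictor_accuracy_is_prevalence(self):
        true = pd.Series(["carcinoid"] * 6 + ["NEC"] * 5)
        pred = pd.Series(["carcinoid"] * 11)
        mat = confusion_matrix(true, pred, ["carcinoid", "NEC"])
        assert accuracy_from_confusion(mat) == pytest.approx(6 / 11)


class TestCorrelateMarkers:
    def test_marker_monotone_in_ki67(self):
        n = 12
        ids = [f"s{i}" for i in range(n)]
        ki67 = np.linspace(1, 60, n)
        x = np.zeros((n, 2))
        x[:, 0] = ki67 / 1000.0
        x[:, 1] = 1.0 - x[:, 0]
        rf = uniform_rf(x, ids, ["m", "rest"])
        ann = make_annotations(
            ids, ["TC"] * 6 + ["SCLC"] * 6, ki67_percent=list(ki67),
            necrosis=["no"] * 6 + ["yes"] * 6, pN=["0"] * 6 + ["1"] * 6,
        )
        table = correlate_markers(rf, ann, ["m"])
        row = table[(table.covariate == "ki67_percent")].iloc[0]
        assert row.statistic == pytest.approx(1.0)
        necrosis_rows = table[table.covariate == "necrosis"]
        assert len(necrosis_rows) == 3
        assert (necrosis_rows[necrosis_rows.comparison != "yes_vs_no"].note
                == "undefined").all()  # no focal samples present

    def test_constant_covariate_flagged_undefined(self):
        ids = ["a", "b", "c", "d"]
        rf = uniform_rf(np.tile([0.2, 0.8], (4, 1)), ids, ["m", "rest"])
        ann = make_annotations(ids, ["TC"] * 4, ki67_percent=[5.0] * 4)
        table = correlate_markers(rf, ann, ["m"])
        row = table[table.covariate == "ki67_percent"].iloc[0]
        assert row.note == "undefined"

    def test_empty_marker_list(self):
        ids = ["a", "b"]
        rf = uniform_rf(np.tile([0.5, 0.5], (2, 1)), ids, ["m", "rest"])
        ann = make_annotations(ids, ["TC", "AC"])
        assert len(correlate_markers(rf, ann, [])) == 0
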