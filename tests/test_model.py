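import numpy as np
import pandas as pd
import pytest

from dceqc.model import (CVConfig, QualityModel, _patient_metrics,
                         make_classifier, soft_vote_patient,
                         stratified_patient_folds)
from dceqc.selection import SelectionConfig


def _synthetic_table(rng, n_patients=40, slices_per_patient=1, effect=4.0,
                     n_noise=10):
    """Feature table with one strongly separating feature per slice."""
    rows = []
    for i in range(n_patients):
        label = i % 2
        for s in range(slices_per_patient):
            row = {"patient_id": f"P{i:03d}", "slice_index": s, "label": label,
                   "signal": label * effect + rng.normal(0, 1)}
            for k in range(n_noise):
                row[f"noise{k}"] = rng.normal(0, 1)
            rows.append(row)
    return pd.DataFrame(rows)


class TestStratifiedFolds:
    def test_110_plus_110_gives_11_per_class_per_fold(self):
        labels = pd.Series([i % 2 for i in range(220)],
                           index=[f"P{i}" for i in range(220)])
        folds = stratified_patient_folds(labels, n_folds=10, seed=0)
        for f in range(10):
            members = folds[folds == f].index
            assert (labels[members] == 0).sum() == 11
            assert (labels[members] == 1).sum() == 11

    def test_no_patient_straddles_folds(self, rng):
        tbl = _synthetic_table(rng, n_patients=24, slices_per_patient=12)
        cfg = CVConfig(n_folds=4, classifiers=("logreg",),
                       selection=SelectionConfig(variance_threshold=0.01))
        res = QualityModel(tbl, cfg).fit()
        seen = {}
        for fold in res.fold_results["logreg"]:
            for pid in fold.test_patients:
                assert pid not in seen
                seen[pid] = fold.fold_id
        assert len(seen) == 24

    def test_seed_permutes_but_preserves_counts(self):
        labels = pd.Series([i % 2 for i in range(60)],
                           index=[f"P{i}" for i in range(60)])
        f0 = stratified_patient_folds(labels, 6, seed=0)
        f1 = stratified_patient_folds(labels, 6, seed=1)
        assert not f0.equals(f1)
        for f in (f0, f1):
            counts = labels.groupby(f).value_counts()
            assert (counts == 5).all()

    def test_too_few_patients(self):
        labels = pd.Series([0] * 5 + [1] * 20,
                           index=[f"P{i}" for i in range(25)])
        with pytest.raises(ValueError, match="fewer patients"):
            stratified_patient_folds(labels, n_folds=10)


class TestSoftVote:
    def test_uniform_probabilities(self):
        mean, label = soft_vote_patient([0.6] * 12)
        assert mean == pytest.approx(0.6) and label == 1

    def test_tie_resolves_to_high_quality(self):
        mean, label = soft_vote_patient([0.9] * 6 + [0.1] * 6)
        assert mean == pytest.approx(0.5) and label == 0

    def test_hand_computed_mean(self):
        mean, label = soft_vote_patient([0.55] + [0.45] * 11)
        assert mean == pytest.approx(0.4583, abs=1e-4) and label == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            soft_vote_patient([])


class TestMetrics:
    def test_confusion_hand_example(self):
        # TP=9, FN=1, TN=8, FP=2
        y = np.array([1] * 10 + [0] * 10)
        probs = np.array([0.9] * 9 + [0.1] + [0.1] * 8 + [0.9] * 2)
        m = _patient_metrics(y, probs, 0.5)
        assert m["sensitivity"] == pytest.approx(90.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["accuracy"] == pytest.approx(85.0)

    def test_aggregate_mean_and_population_sd(self, rng):
        tbl = _synthetic_table(rng, n_patients=20)
        cfg = CVConfig(n_folds=2, classifiers=("logreg",),
                       selection=SelectionConfig(variance_threshold=0.01))
        res = QualityModel(tbl, cfg).fit()
        accs = np.array([f.accuracy for f in res.fold_results["logreg"]])
        summ = res.summary()
        assert summ.loc["logreg", "accuracy_mean"] == pytest.approx(accs.mean())
        assert summ.loc["logreg", "accuracy_sd"] == pytest.approx(accs.std())

    def test_separable_cohort_perfect_scores(self, rng):
        tbl = _synthetic_table(rng, n_patients=40, effect=8.0)
        cfg = CVConfig(n_folds=5, classifiers=("svm_rbf", "logreg"),
                       selection=SelectionConfig(variance_threshold=0.01))
        res = QualityModel(tbl, cfg).fit()
        for clf in ("svm_rbf", "logreg"):
            assert res.mean_metric(clf, "accuracy") == pytest.approx(100.0)
            assert res.mean_metric(clf, "auc") == pytest.approx(100.0)

    def test_label_permutation_auc_near_chance(self):
        aucs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            tbl = _synthetic_table(rng, n_patients=40, effect=0.0)
            cfg = CVConfig(n_folds=4, seed=seed, classifiers=("logreg",),
                           selection=SelectionConfig(variance_threshold=0.01,
                                                     anova_alpha=None,
                                                     top_k=5))
            res = QualityModel(tbl, cfg).fit()
            aucs.append(res.mean_metric("logreg", "auc"))
        assert abs(np.mean(aucs) - 50.0) < 10.0

    def test_best_fold_tiebreak(self, rng):
        tbl = _synthetic_table(rng, n_patients=40, effect=8.0)
        cfg = CVConfig(n_folds=4, classifiers=("logreg",),
                       selection=SelectionConfig(variance_threshold=0.01))
        res = QualityModel(tbl, cfg).fit()
        best = res.best_fold("logreg")
        ranked = sorted(res.fold_results["logreg"],
                        key=lambda f: (f.accuracy, f.auc, -f.fold_id))
        assert best is ranked[-1]


class TestNoLeakage:
    def test_corrupting_test_fold_leaves_fit_unchanged(self, rng):
        tbl = _synthetic_table(rng, n_patients=30, n_noise=8)
        # top-k ANOVA keeps the other folds fittable even after their train
        # rows (this fold's test rows) are corrupted
        cfg = CVConfig(n_folds=3, classifiers=("logreg",),
                       selection=SelectionConfig(variance_threshold=0.01,
                                                 anova_alpha=None, top_k=5))
        res1 = QualityModel(tbl, cfg).fit()
        fold0 = res1.fold_results["logreg"][0]
        # corrupt every feature of fold-0 test patients (their labels enter
        # only fold stratification and scoring, never any fit)
        tbl2 = tbl.copy()
        in_test = tbl2["patient_id"].isin(fold0.test_patients)
        feat_cols = [c for c in tbl2.columns
                     if c not in ("patient_id", "slice_index", "label")]
        # affine corruption: large enough that any leakage into the fold-0
        # fit would move the scaler/selector, yet the other folds (where
        # these patients are training rows) remain fittable
        tbl2.loc[in_test, feat_cols] = (tbl2.loc[in_test, feat_cols] * 3.0
                                        + 25.0)
        res2 = QualityModel(tbl2, cfg).fit()
        fold0b = res2.fold_results["logreg"][0]
        assert fold0.selected_features == fold0b.selected_features
        np.testing.assert_array_equal(fold0.estimator.coef_,
                                      fold0b.estimator.coef_)
        np.testing.assert_array_equal(fold0.scaler.mean_, fold0b.scaler.mean_)


class TestClassifierZoo:
    def test_all_six_ids_construct_and_fit(self, rng):
        X = rng.normal(0, 1, (30, 3))
        y = np.repeat([0, 1], 15)
        X[y == 1] += 2
        for clf_id in ("logreg", "svm_rbf", "knn", "random_forest",
                       "adaboost", "gaussian_nb"):
            clf = make_classifier(clf_id, seed=0).fit(X, y)
            probs = clf.predict_proba(X)[:, 1]
            assert probs.shape == (30,) and np.all((0 <= probs) & (probs <= 1))

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            make_classifier("mlp")
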