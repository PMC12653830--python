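"""Quality classification under patient-stratified cross-validation.

The modelling surface follows the model/results idiom: a
:class:`QualityModel` is built from a feature table (one row per
patient-slice, with ``patient_id`` and ``label`` columns) and a
:class:`CVConfig`; ``fit()`` runs the patient-stratified 10-fold CV —
feature selection, standardization and classifier fitting all on training
folds only — and returns a :class:`QualityResults` carrying per-fold and
aggregate sensitivity/specificity/accuracy/AUC (percent, mean +- SD across
folds), patient-level soft-voted predictions, and the fitted per-fold
pipelines, from which ``summary()`` tables and Shapley explanations hang.

Class 1 (low quality) is the positive class for sensitivity/AUC.  In the
12-slice scenario the per-slice class-1 probabilities of a patient are
averaged (soft voting) and thresholded at 0.5, a tie counting as high
quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import SelectionConfig, ThreeStepSelector

__all__ = ["CVConfig", "FoldResult", "QualityModel", "QualityResults",
           "CLASSIFIER_IDS", "make_classifier", "stratified_patient_folds",
           "soft_vote_patient"]

CLASSIFIER_IDS = ("logreg", "svm_rbf", "knn", "random_forest", "adaboost",
                  "gaussian_nb")

META_COLUMNS = ("patient_id", "slice_index", "label")


def make_classifier(classifier_id: str, seed: int = 0):
    """A fresh classifier with library-default hyperparameters, seeded."""
    if classifier_id == "logreg":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if classifier_id == "svm_rbf":
        # probability estimates via Platt calibration on the training fold
        return CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                      ensemble=False)
    if classifier_id == "knn":
        return KNeighborsClassifier()
    if classifier_id == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if classifier_id == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if classifier_id == "gaussian_nb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {classifier_id!r}")


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    seed: int = 0
    classifiers: tuple[str, ...] = CLASSIFIER_IDS
    vote_threshold: float = 0.5
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.vote_threshold < 1:
            raise ValueError("vote_threshold must be in (0, 1)")
        unknown = set(self.classifiers) - set(CLASSIFIER_IDS)
        if unknown:
            raise ValueError(f"unknown classifiers {sorted(unknown)}")


def stratified_patient_folds(patient_labels: pd.Series, n_folds: int = 10,
                             seed: int = 0) -> pd.Series:
    """Fold id per patient, stratified by the patient's label.

    All slices of a patient share the patient's fold, so no patient ever
    straddles the train/test boundary.
    """
    patients = patient_labels.index.to_numpy()
    y = patient_labels.to_numpy()
    for cls in np.unique(y):
        if (y == cls).sum() < n_folds:
            raise ValueError(
                f"class {cls} has fewer patients than folds ({n_folds})")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(patients), dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(patients, y)):
        fold_of[test_idx] = fold_id
    return pd.Series(fold_of, index=patients, name="fold")


def soft_vote_patient(slice_probabilities, threshold: float = 0.5
                      ) -> tuple[float, int]:
    """Average the per-slice class-1 probabilities and threshold.

    The label is 1 (low quality) iff the mean strictly exceeds the
    threshold; a tie at exactly 0.5 resolves to high quality.
    """
    probs = np.asarray(list(slice_probabilities), dtype=float)
    if probs.size == 0:
        raise ValueError("no probabilities to vote on")
    mean = float(probs.mean())
    return mean, int(mean > threshold)


def _patient_metrics(y_true: np.ndarray, mean_probs: np.ndarray,
                     threshold: float) -> dict[str, float]:
    y_pred = (mean_probs > threshold).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / len(y_true)
    auc = 100.0 * roc_auc_score(y_true, mean_probs) \
        if len(np.unique(y_true)) == 2 else float("nan")
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "auc": auc}


@dataclass
class FoldResult:
    """Patient-level evaluation of one classifier on one held-out fold."""

    fold_id: int
    classifier: str
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    patient_probs: pd.Series
    patient_true: pd.Series
    selected_features: list[str]
    selector: ThreeStepSelector
    scaler: StandardScaler
    estimator: object
    test_patients: list[str]

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Class-1 probability for rows of a raw feature table."""
        X = self.scaler.transform(self.selector.transform(table).to_numpy())
        return self.estimator.predict_proba(X)[:, 1]


class QualityModel:
    """Patient-level quality classifier built from a slice feature table."""

    def __init__(self, table: pd.DataFrame, config: CVConfig = CVConfig()):
        missing = {"patient_id", "label"} - set(table.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.config = config
        self.feature_columns = [c for c in table.columns
                                if c not in META_COLUMNS]
        per_patient = self.table.groupby("patient_id")["label"].nunique()
        if (per_patient > 1).any():
            raise ValueError("inconsistent labels within a patient")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame,
                           config: CVConfig = CVConfig()) -> "QualityModel":
        return cls(table, config)

    def fit(self) -> "QualityResults":
        cfg = self.config
        patient_labels = self.table.groupby("patient_id")["label"].first()
        folds = stratified_patient_folds(patient_labels, cfg.n_folds, cfg.seed)
        fold_col = self.table["patient_id"].map(folds)

        X_all = self.table[self.feature_columns]
        y_all = self.table["label"].to_numpy()
        results: dict[str, list[FoldResult]] = {c: [] for c in cfg.classifiers}
        for fold_id in range(cfg.n_folds):
            train = fold_col != fold_id
            test = ~train
            selector = ThreeStepSelector(cfg.selection)
            Xtr = selector.fit_transform(X_all[train], y_all[train])
            scaler = StandardScaler().fit(Xtr.to_numpy())
            Xtr_s = scaler.transform(Xtr.to_numpy())
            Xte_s = scaler.transform(selector.transform(X_all[test]).to_numpy())
            test_pids = self.table.loc[test, "patient_id"].to_numpy()
            for clf_id in cfg.classifiers:
                clf = make_classifier(clf_id, cfg.seed)
                clf.fit(Xtr_s, y_all[train])
                slice_probs = clf.predict_proba(Xte_s)[:, 1]
                by_pid = pd.Series(slice_probs, index=test_pids)
                mean_probs = by_pid.groupby(level=0).mean()
                y_true = patient_labels.loc[mean_probs.index]
                metrics = _patient_metrics(y_true.to_numpy(),
                                           mean_probs.to_numpy(),
                                           cfg.vote_threshold)
                results[clf_id].append(FoldResult(
                    fold_id=fold_id, classifier=clf_id,
                    patient_probs=mean_probs, patient_true=y_true,
                    selected_features=list(selector.selected_features_),
                    selector=selector, scaler=scaler, estimator=clf,
                    test_patients=list(mean_probs.index), **metrics))
        return QualityResults(self, results, folds)


class QualityResults:
    """Cross-validated estimates, fold artifacts and explanation hooks."""

    METRICS = ("sensitivity", "specificity", "accuracy", "auc")

    def __init__(self, model: QualityModel,
                 fold_results: dict[str, list[FoldResult]],
                 patient_folds: pd.Series):
        self.model = model
        self.fold_results = fold_results
        self.patient_folds = patient_folds

    def summary(self) -> pd.DataFrame:
        """Per-classifier mean +- population SD of each metric, in percent."""
        rows = []
        for clf_id, folds in self.fold_results.items():
            row: dict[str, object] = {"classifier": clf_id}
            for metric in self.METRICS:
                vals = np.array([getattr(f, metric) for f in folds])
                row[f"{metric}_mean"] = float(vals.mean())
                row[f"{metric}_sd"] = float(vals.std())  # across folds
            rows.append(row)
        return pd.DataFrame(rows).set_index("classifier")

    def summary_table(self) -> pd.DataFrame:
        """Human-readable 'mean +- SD' table, one row per classifier."""
        num = self.summary()
        out = pd.DataFrame(index=num.index)
        for metric in self.METRICS:
            out[metric] = [f"{m:.2f} ± {s:.2f}" for m, s in
                           zip(num[f"{metric}_mean"], num[f"{metric}_sd"])]
        return out

    def best_fold(self, classifier: str) -> FoldResult:
        """Highest-accuracy fold, ties broken by AUC then lowest fold id."""
        folds = self.fold_results[classifier]
        return max(folds, key=lambda f: (f.accuracy, f.auc, -f.fold_id))

    def mean_metric(self, classifier: str, metric: str) -> float:
        return float(np.mean([getattr(f, metric)
                              for f in self.fold_results[classifier]]))

    def patient_predictions(self, classifier: str) -> pd.DataFrame:
        """Soft-voted out-of-fold probability and label for every patient."""
        rows = []
        for fold in self.fold_results[classifier]:
            for pid in fold.patient_probs.index:
                prob = float(fold.patient_probs[pid])
                rows.append({"patient_id": pid, "fold": fold.fold_id,
                             "probability": prob,
                             "label": int(fold.patient_true[pid]),
                             "prediction": int(prob > self.model.config.vote_threshold)})
        return pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)

    def explain(self, classifier: str = "svm_rbf", fold: int | None = None,
                n_permutations: int = 10, max_background: int = 100,
                seed: int = 0):
        """Shapley attributions for the test samples of a fold.

        Defaults to the best-performing fold (highest accuracy, then AUC).
        The reference (background) set is the training-fold feature matrix,
        subsampled to ``max_background`` rows.
        """
        from .shapley import shapley_attributions

        if fold is None:
            fr = self.best_fold(classifier)
        else:
            fr = next(f for f in self.fold_results[classifier]
                      if f.fold_id == fold)
        tbl = self.model.table
        in_test = tbl["patient_id"].isin(fr.test_patients)
        X = tbl[self.model.feature_columns]
        Xtr = fr.scaler.transform(fr.selector.transform(X[~in_test]).to_numpy())
        Xte = fr.scaler.transform(fr.selector.transform(X[in_test]).to_numpy())
        rng = np.random.default_rng(seed)
        if Xtr.shape[0] > max_background:
            Xtr = Xtr[rng.choice(Xtr.shape[0], max_background, replace=False)]
        predict = lambda A: fr.estimator.predict_proba(A)[:, 1]
        return shapley_attributions(predict, Xtr, Xte,
                                    feature_names=fr.selected_features,
                                    n_permutations=n_permutations, seed=seed)
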