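"""Passive screening: binary classification of clinically relevant scores
(PHQ-9 >= 11) from 120-dimensional window descriptors, validated with
leave-one-subject-out cross-validation.

Per fold, the held-out subject's rows are all tested together; imputation
(training-fold column medians), standardization (training-fold mean/sd) and
any hyperparameter search see training rows only.  The SVM uses an RBF
kernel with (C, gamma) tuned by Nelder-Mead simplex over log-scale
parameters against an inner grouped-CV accuracy objective; the random
forest uses 450 trees by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold
from sklearn.svm import SVC

from .aggregation import FEATURE_NAMES, FeatureVector

DEFAULT_N_TREES = 450
MODELS = ("random_forest", "svm_rbf")


class DatasetError(ValueError):
    pass


class MetricError(ValueError):
    pass


@dataclass
class CohortDataset:
    """(X, y, subject) triples for grouped cross-validation.

    X may contain NaN for masked features; imputation happens inside each
    training fold.
    """
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise DatasetError("X, y and groups must have equal length")

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.groups))


@dataclass
class FoldResult:
    subject: str
    test_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    train_index: np.ndarray
    hyperparameters: dict = field(default_factory=dict)
    skipped: bool = False


@dataclass
class CvReport:
    model: str
    hyperparameters: dict
    seed: int
    accuracy: float          # percent
    sensitivity: float       # percent, on the score >= 11 class
    specificity: float       # percent
    folds: list[FoldResult]
    n_samples: int
    n_subjects: int
    skipped_folds: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "hyperparameters": self.hyperparameters,
            "seed": self.seed, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "n_samples": self.n_samples, "n_subjects": self.n_subjects,
            "skipped_folds": self.skipped_folds,
            "predictions": [
                {"subject": f.subject, "y_true": f.y_true.tolist(),
                 "y_pred": f.y_pred.tolist()} for f in self.folds if not f.skipped],
        }


def assemble_dataset(vectors: Sequence[FeatureVector]) -> CohortDataset:
    """Stack feature vectors into a cohort dataset (labels thresholded at 11)."""
    if not vectors:
        raise DatasetError("no feature vectors supplied")
    X = np.vstack([fv.values for fv in vectors])
    y = np.array([int(fv.label) for fv in vectors])
    groups = np.array([fv.subject_id for fv in vectors])
    if len(np.unique(y)) < 2:
        raise DatasetError("dataset contains a single class; metrics undefined")
    return CohortDataset(X=X, y=y, groups=groups)


def dataset_from_frame(frame: pd.DataFrame) -> CohortDataset:
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise DatasetError(f"dataset missing feature columns: {missing[:3]}...")
    ds = CohortDataset(X=frame[list(FEATURE_NAMES)].to_numpy(float),
                       y=frame["label"].to_numpy(int),
                       groups=frame["subject_id"].to_numpy())
    if len(np.unique(ds.y)) < 2:
        raise DatasetError("dataset contains a single class; metrics undefined")
    return ds


def classification_metrics(y_true: Sequence[int],
                           y_pred: Sequence[int]) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as percentages.

    Sensitivity is the fraction of positive-class (score >= 11) samples
    classified positive; specificity the analogue on the negative class.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise MetricError("label arrays must have equal length")
    if len(np.unique(y_true)) < 2:
        raise MetricError("both classes must be present in y_true")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    accuracy = 100.0 * (tp + tn) / len(y_true)
    sensitivity = 100.0 * tp / (tp + fn)
    specificity = 100.0 * tn / (tn + fp)
    return accuracy, sensitivity, specificity


# ---------------------------------------------------------------------------
# per-fold preprocessing
# ---------------------------------------------------------------------------

def _fit_preprocess(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training-fold medians (for imputation), means and sds (for scaling)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN columns
        med = np.nanmedian(X_train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    Xi = np.where(np.isnan(X_train), med, X_train)
    mu = Xi.mean(axis=0)
    sd = Xi.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return med, mu, sd


def _apply_preprocess(X: np.ndarray, med, mu, sd) -> np.ndarray:
    Xi = np.where(np.isnan(X), med, X)
    return (Xi - mu) / sd


def _tune_svm(X: np.ndarray, y: np.ndarray, groups: np.ndarray, seed: int,
              inner_folds: int = 5, maxiter: int = 40) -> tuple[float, float]:
    """Nelder-Mead over (log10 C, log10 gamma) maximising inner grouped-CV
    accuracy; returns (C, gamma)."""
    n_groups = len(np.unique(groups))
    x0 = np.array([0.0, np.log10(1.0 / X.shape[1])])
    if n_groups < 2 or len(np.unique(y)) < 2:
        return 10.0 ** x0[0], 10.0 ** x0[1]
    splitter = GroupKFold(n_splits=min(inner_folds, n_groups))
    splits = [(tr, te) for tr, te in splitter.split(X, y, groups)
              if len(np.unique(y[tr])) == 2]
    if not splits:
        return 10.0 ** x0[0], 10.0 ** x0[1]

    def objective(log_params: np.ndarray) -> float:
        c = 10.0 ** float(np.clip(log_params[0], -4, 4))
        g = 10.0 ** float(np.clip(log_params[1], -6, 2))
        correct = total = 0
        for tr, te in splits:
            clf = SVC(C=c, gamma=g, kernel="rbf", random_state=seed)
            clf.fit(X[tr], y[tr])
            correct += int((clf.predict(X[te]) == y[te]).sum())
            total += len(te)
        return -correct / total

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 0.1, "fatol": 1e-3})
    best = res.x
    return (10.0 ** float(np.clip(best[0], -4, 4)),
            10.0 ** float(np.clip(best[1], -6, 2)))


def loso_cv(data: CohortDataset, model: str = "random_forest", seed: int = 0,
            n_trees: int = DEFAULT_N_TREES, svm_maxiter: int = 40,
            inner_folds: int = 5) -> CvReport:
    """Leave-one-subject-out cross-validation.

    Folds are subjects; every row of the held-out subject is tested at once,
    never appearing in its own training set.  Training folds reduced to a
    single class are skipped with a warning and reported.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    subjects = np.unique(data.groups)
    if len(subjects) < 3:
        raise DatasetError("leave-one-subject-out needs >= 3 subjects")
    if len(np.unique(data.y)) < 2:
        raise DatasetError("both classes must be present")

    folds: list[FoldResult] = []
    skipped: list[str] = []
    hyper_record: dict = {"n_trees": n_trees} if model == "random_forest" else {}

    for subj in subjects:
        test_mask = data.groups == subj
        train_mask = ~test_mask
        y_train = data.y[train_mask]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {subj!r} skipped: single-class training fold")
            skipped.append(str(subj))
            folds.append(FoldResult(subject=str(subj),
                                    test_index=np.flatnonzero(test_mask),
                                    y_true=data.y[test_mask],
                                    y_pred=np.array([], dtype=int),
                                    train_index=np.flatnonzero(train_mask),
                                    skipped=True))
            continue

        med, mu, sd = _fit_preprocess(data.X[train_mask])
        X_train = _apply_preprocess(data.X[train_mask], med, mu, sd)
        X_test = _apply_preprocess(data.X[test_mask], med, mu, sd)

        hp: dict = {}
        if model == "random_forest":
            clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                         n_jobs=1)
            hp = {"n_trees": n_trees}
        else:
            c, g = _tune_svm(X_train, y_train, data.groups[train_mask], seed,
                             inner_folds=inner_folds, maxiter=svm_maxiter)
            clf = SVC(C=c, gamma=g, kernel="rbf", random_state=seed)
            hp = {"C": c, "gamma": g}
        clf.fit(X_train, y_train)
        y_pred = clf.predict(X_test)
        folds.append(FoldResult(subject=str(subj),
                                test_index=np.flatnonzero(test_mask),
                                y_true=data.y[test_mask], y_pred=y_pred,
                                train_index=np.flatnonzero(train_mask),
                                hyperparameters=hp))

    y_true = np.concatenate([f.y_true for f in folds if not f.skipped])
    y_pred = np.concatenate([f.y_pred for f in folds if not f.skipped])
    if len(np.unique(y_true)) == 2:
        acc, sens, spec = classification_metrics(y_true, y_pred)
    else:
        # skipped folds removed one class from the pooled truth: accuracy is
        # still defined, the class-conditional rates are not
        warnings.warn("pooled predictions cover a single class; "
                      "sensitivity/specificity undefined")
        acc = 100.0 * float(np.mean(y_true == y_pred))
        sens = spec = float("nan")
    return CvReport(model=model, hyperparameters=hyper_record, seed=seed,
                    accuracy=acc, sensitivity=sens, specificity=spec,
                    folds=folds, n_samples=len(data.y),
                    n_subjects=len(subjects), skipped_folds=skipped)
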