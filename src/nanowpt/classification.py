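"""Automatic protein / negative-control discrimination from sensorgrams.

Four features summarize the post-addition kinetics of each experiment:
successive 50-s output-voltage differences starting 50 s after the
instantaneous change,

    f_i = V(t_step + 50 (i+1)) - V(t_step + 50 i),   i = 1..4,

in raw volts (a pure exponential response makes them a geometric
sequence with ratio exp(-50/tau)).  A soft-margin SVM with a small-scale
Gaussian kernel — the "fine Gaussian" convention, kernel scale
sqrt(P)/4 = 0.5 for P = 4 standardized features — separates the two
classes; :class:`FineGaussianSVC` packages it as a scikit-learn
estimator so it composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .trace import Trace

N_FEATURES = 4
FEATURE_INTERVAL = 50.0  # s between compared output values
POSITIVE_LABEL = "protein"
NEGATIVE_LABEL = "negative_control"


def extract_features(trace: Trace, step_time: float) -> np.ndarray:
    """The 4 successive 50-s voltage differences after the instantaneous change.

    ``step_time`` is the instant of the instantaneous change (the
    reagent-addition annotation).  Requires the trace to cover
    ``step_time + 250 s``; values are read as nearest samples and the
    features are raw voltage differences, not percentages.
    """
    t_last = step_time + FEATURE_INTERVAL * (N_FEATURES + 1)
    if trace.times[-1] < t_last or trace.times[0] > step_time:
        raise ValueError(
            f"trace span [{trace.times[0]:g}, {trace.times[-1]:g}] s does not cover "
            f"[{step_time:g}, {t_last:g}] s needed for feature extraction"
        )
    marks = [trace.value_at(step_time + FEATURE_INTERVAL * i)
             for i in range(1, N_FEATURES + 2)]
    return np.diff(marks)


@dataclass
class LabelledDataset:
    """Feature vectors plus class labels for the protein/NC task."""

    features: np.ndarray  # (n, 4)
    labels: np.ndarray  # str labels, POSITIVE_LABEL / NEGATIVE_LABEL
    split_seed: int = 0
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (n, {N_FEATURES})")
        if len(self.labels) != len(self.features):
            raise ValueError("labels and features must align")
        if len(set(self.labels.tolist())) < 2:
            raise ValueError("both classes must be present")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset(self, idx) -> "LabelledDataset":
        ds = object.__new__(LabelledDataset)
        ds.features = self.features[idx]
        ds.labels = self.labels[idx]
        ds.split_seed = self.split_seed
        ds.conditions = [self.conditions[i] for i in idx] if self.conditions else []
        return ds

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=[f"f{i}_v" for i in range(1, 5)])
        df["label"] = self.labels
        if self.conditions:
            df["condition"] = self.conditions
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, split_seed: int = 0) -> "LabelledDataset":
        cols = [f"f{i}_v" for i in range(1, 5)]
        conditions = df["condition"].tolist() if "condition" in df else []
        return cls(df[cols].to_numpy(float), df["label"].to_numpy(),
                   split_seed=split_seed, conditions=conditions)


def split_dataset(dataset: LabelledDataset, train_fraction: float = 0.7,
                  ) -> tuple[LabelledDataset, LabelledDataset]:
    """Stratified random train/test partition, deterministic given split_seed.

    Per-class train counts are the nearest integers to
    ``train_fraction * n_class``, adjusted (largest class first) so the
    overall train size is the nearest integer to ``train_fraction * n``
    (54 vectors at 0.7 -> 38 train / 16 test).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(dataset.split_seed)
    classes, counts = np.unique(dataset.labels, return_counts=True)
    n_train_total = round(train_fraction * len(dataset))
    n_train = {c: round(train_fraction * n) for c, n in zip(classes, counts)}
    # reconcile rounding so the train side is exactly n_train_total
    order = classes[np.argsort(-counts)]
    i = 0
    while sum(n_train.values()) != n_train_total:
        c = order[i % len(order)]
        n_train[c] += 1 if sum(n_train.values()) < n_train_total else -1
        i += 1
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(dataset.labels == c)
        rng.shuffle(idx)
        k = int(n_train[c])
        if k < 1 or k >= len(idx):
            warnings.warn(
                f"class {c!r} would be absent from one side of the split; "
                "clamping to keep both classes on both sides",
                stacklevel=2,
            )
            k = min(max(k, 1), len(idx) - 1)
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


class FineGaussianSVC(ClassifierMixin, BaseEstimator):
    """Soft-margin SVM with a fine-scale Gaussian kernel on standardized features.

    Kernel k(x, x') = exp(-||x - x'||^2 / (2 kernel_scale^2)) with the
    default ``kernel_scale = sqrt(P)/4 = 0.5`` for P = 4 features (the
    "fine" convention), box constraint ``C = 1``.

    Parameters
    ----------
    kernel_scale : float, default 0.5
        Gaussian kernel scale sigma; gamma = 1/(2 sigma^2).
    C : float, default 1.0
        Soft-margin box constraint.
    standardize : bool, default True
        Z-score the features before the kernel.

    Attributes
    ----------
    classes_ : ndarray
        Class labels seen during fit.
    pipeline_ : sklearn Pipeline
        Fitted scaler + SVC.
    """

    def __init__(self, kernel_scale: float = 0.5, C: float = 1.0,
                 standardize: bool = True):
        self.kernel_scale = kernel_scale
        self.C = C
        self.standardize = standardize

    def fit(self, X, y) -> "FineGaussianSVC":
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        if self.kernel_scale <= 0 or self.C <= 0:
            raise ValueError("kernel_scale and C must be > 0")
        gamma = 1.0 / (2.0 * self.kernel_scale**2)
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("svc", SVC(C=self.C, kernel="rbf", gamma=gamma)))
        self.pipeline_ = Pipeline(steps).fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svc"].classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        X = check_array(X, dtype=float)
        return self.pipeline_.predict(X)

    def decision_function(self, X) -> np.ndarray:
        """Signed margin scores, oriented so that larger means more
        protein-like whenever the protein label is present."""
        check_is_fitted(self, "pipeline_")
        X = check_array(X, dtype=float)
        scores = self.pipeline_.decision_function(X)
        if POSITIVE_LABEL in self.classes_ and self.classes_[1] != POSITIVE_LABEL:
            scores = -scores
        return scores


def train_rbf_svm(train: LabelledDataset, kernel_scale: float = 0.5,
                  C: float = 1.0, standardize: bool = True) -> FineGaussianSVC:
    """Fit a :class:`FineGaussianSVC` on a labelled dataset."""
    return FineGaussianSVC(kernel_scale=kernel_scale, C=C,
                           standardize=standardize).fit(train.features, train.labels)


@dataclass
class EvaluationReport:
    """Held-out performance: accuracy (%), confusion matrix, ROC."""

    accuracy_pct: float
    confusion: np.ndarray  # rows = true class, order = class_order
    class_order: list[str]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "confusion_matrix": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "auc": self.auc,
        }


def evaluate(classifier, test: LabelledDataset) -> EvaluationReport:
    """Accuracy, confusion matrix and ROC of a fitted classifier on held-out data.

    Confusion-matrix rows are the true classes (negative control first,
    protein second when both named labels are present); the ROC treats
    protein as the positive class and is built from decision-function
    scores.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    pred = classifier.predict(test.features)
    acc = 100.0 * float(np.mean(pred == test.labels))
    present = sorted(set(test.labels.tolist()) | set(pred.tolist()))
    if set(present) == {NEGATIVE_LABEL, POSITIVE_LABEL}:
        order = [NEGATIVE_LABEL, POSITIVE_LABEL]
    else:
        order = present
    cm = _sk_confusion(test.labels, pred, labels=order)
    scores = classifier.decision_function(test.features)
    y_true = (test.labels == POSITIVE_LABEL).astype(int)
    if y_true.min() == y_true.max():  # single-class test set: ROC undefined
        fpr, tpr, auc = np.array([]), np.array([]), float("nan")
    else:
        fpr, tpr, _ = roc_curve(y_true, scores)
        auc = float(roc_auc_score(y_true, scores))
    return EvaluationReport(accuracy_pct=acc, confusion=cm, class_order=order,
                            roc_fpr=fpr, roc_tpr=tpr, auc=auc)
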