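"""Predicting above-median dose-plan quality from tumor shape features.

Labels are built by median binarization of each plan index over the whole
cohort (for the gradient index the polarity is inverted: LOW GI is the
high-quality class, since a low GI means steeper dose falloff).  Features are
z-scored with training statistics only; feature subsets come from recursive
feature elimination with a linear SVM; five classifiers (logistic regression,
LDA, gradient boosting, SVM, random forest) are tuned by 3-fold CV on the
training split and evaluated on the held-out 20%.

Note the cohort-median labeling deliberately uses the *entire* cohort before
splitting, as is common in retrospective designs; ``median_scope="train"``
computes the median on the training split only, avoiding that mild leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.svm import SVC

#: plan indices where a LOW value is the "high quality" class
INVERTED_INDICES = ("gi",)

MODEL_GRIDS = {
    "LR": (LogisticRegression(max_iter=5000), {"C": [0.1, 1.0, 10.0]}),
    "LDA": (LinearDiscriminantAnalysis(), {}),
    "GB": (
        GradientBoostingClassifier(random_state=0),
        {"n_estimators": [100], "max_depth": [2, 3], "learning_rate": [0.1]},
    ),
    "SVM": (SVC(random_state=0), {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"]}),
    "RF": (
        RandomForestClassifier(random_state=0),
        {"n_estimators": [200], "max_depth": [None, 4]},
    ),
}


def binarize_by_median(values, invert: bool = False) -> tuple[np.ndarray, float]:
    """Label 1 for values at or above the median (at or below when inverted).

    The median is computed on all supplied values (the whole cohort).
    Returns (labels, median).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values")
    if np.all(values == values[0]):
        raise ValueError("cannot binarize a constant index")
    med = float(np.median(values))
    labels = (values <= med) if invert else (values >= med)
    return labels.astype(int), med


def standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score with training statistics only; constant columns are dropped.

    Returns (train_z, test_z, kept-column mask).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn("dropping constant training column(s)", stacklevel=2)
    return (
        (train[:, keep] - mu[keep]) / sd[keep],
        (test[:, keep] - mu[keep]) / sd[keep],
        keep,
    )


def rfe_svm_select(X, y, folds: int = 3, seed: int = 0) -> list[int]:
    """RFE with a linear SVM; subset size chosen by cross-validated accuracy.

    Features are iteratively dropped by smallest absolute linear-SVM weight;
    the retained subset size is the one with the best k-fold CV accuracy of a
    linear SVM (ties favor the smaller subset).  Returns column indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    p = X.shape[1]
    if p < 2:
        return list(range(p))

    # elimination order by recursive linear-SVM weight ranking
    remaining = list(range(p))
    order = []  # dropped first -> last
    while len(remaining) > 1:
        svm = SVC(kernel="linear", C=1.0)
        svm.fit(X[:, remaining], y)
        w = np.abs(svm.coef_[0])
        drop = remaining[int(np.argmin(w))]
        order.append(drop)
        remaining.remove(drop)
    order.append(remaining[0])
    ranked = order[::-1]  # most important first

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_k, best_acc = 1, -np.inf
    for k in range(1, p + 1):
        cols = ranked[:k]
        accs = []
        for tr, te in cv.split(X, y):
            svm = SVC(kernel="linear", C=1.0)
            svm.fit(X[np.ix_(tr, cols)], y[tr])
            accs.append(svm.score(X[np.ix_(te, cols)], y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_k = acc, k
    return sorted(ranked[:best_k])


@dataclass
class ClassificationReport:
    index: str
    model: str
    selected_features: list[str]
    n0_train: int
    n1_train: int
    n0_test: int
    n1_test: int
    train_accuracy: float
    train_sensitivity: float
    train_specificity: float
    test_accuracy: float
    test_sensitivity: float
    test_specificity: float
    best_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def _metrics_percent(y_true, y_pred) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent; positive class is 1."""
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, sens, spec


def train_eval(
    table: pd.DataFrame,
    features: list[str],
    index: str,
    model: str = "RF",
    split: float = 0.8,
    seed: int = 0,
    folds: int = 3,
    select_features: bool = True,
    median_scope: str = "cohort",
) -> ClassificationReport:
    """Fit one classifier on a stratified split and report test metrics.

    Hyperparameters are tuned by k-fold CV on the training split only;
    sensitivity is reported on the high-quality (label 1) class.
    """
    if model not in MODEL_GRIDS:
        raise ValueError(f"model must be one of {sorted(MODEL_GRIDS)}")
    if median_scope not in ("cohort", "train"):
        raise ValueError("median_scope must be 'cohort' or 'train'")
    X = table[features].to_numpy(dtype=float)
    values = table[index].to_numpy(dtype=float)
    invert = index in INVERTED_INDICES

    if median_scope == "cohort":
        y, _ = binarize_by_median(values, invert=invert)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=split, random_state=seed, stratify=y
        )
    else:
        X_tr, X_te, v_tr, v_te = train_test_split(
            X, values, train_size=split, random_state=seed
        )
        y_tr, med = binarize_by_median(v_tr, invert=invert)
        y_te = ((v_te <= med) if invert else (v_te >= med)).astype(int)

    Z_tr, Z_te, keep = standardize(X_tr, X_te)
    names = [f for f, k in zip(features, keep) if k]

    if select_features and Z_tr.shape[1] > 1:
        cols = rfe_svm_select(Z_tr, y_tr, folds=folds, seed=seed)
    else:
        cols = list(range(Z_tr.shape[1]))
    Z_tr, Z_te = Z_tr[:, cols], Z_te[:, cols]
    selected = [names[c] for c in cols]

    base, grid = MODEL_GRIDS[model]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, cv=cv, scoring="accuracy")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(Z_tr, y_tr)
    clf = search.best_estimator_

    tr_acc, tr_sens, tr_spec = _metrics_percent(y_tr, clf.predict(Z_tr))
    te_acc, te_sens, te_spec = _metrics_percent(y_te, clf.predict(Z_te))
    return ClassificationReport(
        index=index,
        model=model,
        selected_features=selected,
        n0_train=int((y_tr == 0).sum()),
        n1_train=int((y_tr == 1).sum()),
        n0_test=int((y_te == 0).sum()),
        n1_test=int((y_te == 1).sum()),
        train_accuracy=tr_acc,
        train_sensitivity=tr_sens,
        train_specificity=tr_spec,
        test_accuracy=te_acc,
        test_sensitivity=te_sens,
        test_specificity=te_spec,
        best_params=dict(search.best_params_),
    )
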