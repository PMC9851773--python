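"""Connectome-based diagnostic classification.

FC matrices are vectorised to subject x edge feature tables, reduced to
a small number of principal components and classified with a linear
support-vector machine under repeated stratified k-fold
cross-validation (defaults: 5 components, 15 folds, 1000 repetitions,
C = 1).  PCA is fit inside each training fold by default so no test
information leaks into the feature reduction; the permissive variant
(PCA fit once on all subjects) is available behind a flag for
comparison.  Accuracy distributions from two estimators are compared
with a Wilcoxon signed-rank test over the paired per-repetition
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .fc_core import FcMatrix
from .group_inference import stack_edges

__all__ = [
    "ClassificationConfig",
    "ClassificationResult",
    "vectorize_fc",
    "svm_cv_accuracy",
    "compare_accuracy_distributions",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Cross-validated PCA + linear-SVM settings."""

    n_components: int = 5
    n_folds: int = 15
    n_iterations: int = 1000
    svm_c: float = 1.0
    base_seed: int = 0
    pca_global: bool = False

    def __post_init__(self):
        if self.n_components < 1 or self.n_folds < 2 or self.n_iterations < 1:
            raise ValueError("invalid classification configuration")
        if self.svm_c <= 0:
            raise ValueError("SVM regularisation must be positive")


@dataclass
class ClassificationResult:
    """Per-iteration accuracies per estimator plus their paired comparison."""

    accuracies: dict[str, np.ndarray]
    statistic: float | None = None
    pvalue: float | None = None

    def summary(self) -> dict:
        out = {}
        for name, acc in self.accuracies.items():
            out[name] = {"mean": float(acc.mean()), "sd": float(acc.std(ddof=1))}
        if self.pvalue is not None:
            out["wilcoxon"] = {"statistic": self.statistic, "p": self.pvalue}
        return out


def vectorize_fc(matrices: list[FcMatrix]) -> np.ndarray:
    """Subjects x edges feature table (upper triangle, row-major i < j)."""
    return stack_edges(matrices)


def _check_stratification(labels: np.ndarray, n_folds: int) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if classes.shape[0] != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    if counts.sum() < n_folds:
        raise ValueError("fewer subjects than folds")


def svm_cv_accuracy(
    features: np.ndarray, labels: np.ndarray, config: ClassificationConfig
) -> np.ndarray:
    """Per-iteration pooled cross-validated accuracy.

    Each iteration draws a stratified fold assignment seeded by
    ``base_seed + iteration``; within every training fold the features
    are reduced by PCA (centring and projection estimated on the
    training subjects only) and classified with a linear SVM; the
    iteration's accuracy pools the held-out predictions over all folds.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("one label per subject required")
    _check_stratification(y, config.n_folds)
    n = x.shape[0]
    min_train = n - int(np.ceil(n / config.n_folds))
    n_comp = min(config.n_components, min_train, x.shape[1])

    global_pca = None
    if config.pca_global:
        global_pca = PCA(n_components=n_comp).fit(x)

    accuracies = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.base_seed + it
        )
        correct = 0
        for train_idx, test_idx in skf.split(x, y):
            if np.unique(y[train_idx]).shape[0] < 2:
                raise ValueError("single-class training fold; reduce n_folds")
            if global_pca is not None:
                clf = SVC(kernel="linear", C=config.svm_c)
                clf.fit(global_pca.transform(x[train_idx]), y[train_idx])
                pred = clf.predict(global_pca.transform(x[test_idx]))
            else:
                pipe = Pipeline(
                    [
                        ("pca", PCA(n_components=min(n_comp, train_idx.shape[0]))),
                        ("svm", SVC(kernel="linear", C=config.svm_c)),
                    ]
                )
                pipe.fit(x[train_idx], y[train_idx])
                pred = pipe.predict(x[test_idx])
            correct += int((pred == y[test_idx]).sum())
        accuracies[it] = correct / n
    return accuracies


def compare_accuracy_distributions(
    acc_a: np.ndarray, acc_b: np.ndarray
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired per-iteration accuracies.

    Zero differences are dropped (standard convention); if every
    difference is zero the comparison is degenerate and (0.0, 1.0) is
    returned.
    """
    a = np.asarray(acc_a, dtype=float).ravel()
    b = np.asarray(acc_b, dtype=float).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError("accuracy vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)
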