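"""Cross-validated disease classification with balanced accuracy.

The harness mirrors a common evaluation protocol for imaging biomarkers:
stratified 6-fold cross-validation repeated over reshuffled runs, linear
discriminant analysis for single features, linear-kernel SVM and a
100-tree random forest for all-feature experiments.  Predictions are
pooled over the folds of a run, metrics computed per run and averaged over
runs.  The SVM rescales each feature to [0, 1] with min/max statistics
fitted on the training folds only, so no information leaks from held-out
folds.  The positive class is the diseased group; balanced accuracy is the
arithmetic mean of sensitivity and specificity and is therefore invariant
to class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

#: default repeat counts: 100 runs for single-feature LDA, 20 for RF/SVM
DEFAULT_RUNS = {"lda": 100, "svm": 20, "rf": 20}
CLASSIFIER_KINDS = ("lda", "svm", "rf")


def make_classifier(kind: str, seed: int | None = None):
    """Instantiate one of the harness classifiers.

    ``svm`` is a linear-kernel SVC (C=1) behind a per-training-fold min-max
    scaler; ``rf`` a 100-tree random forest; ``lda`` plain LDA.
    """
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "svm":
        return Pipeline(
            [("scale", MinMaxScaler()), ("svc", SVC(kernel="linear", C=1.0))]
        )
    if kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def compute_metrics(predictions, truth, positive_label) -> tuple[float, float, float, float]:
    """(ACC, bACC, SENS, SPEC) in percent from pooled predictions."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    pos = truth == positive_label
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("truth must contain both classes")
    tp = int(np.sum(pos & (predictions == positive_label)))
    tn = int(np.sum(neg & (predictions != positive_label)))
    sens = 100.0 * tp / int(pos.sum())
    spec = 100.0 * tn / int(neg.sum())
    acc = 100.0 * (tp + tn) / len(truth)
    bacc = (sens + spec) / 2.0
    return acc, bacc, sens, spec


@dataclass
class ClassificationResult:
    """Metrics of one repeated-CV experiment (all values in percent)."""

    classifier: str
    n_folds: int
    n_runs: int
    seed: int
    positive_label: str
    per_run: pd.DataFrame = field(repr=False)  # columns: acc, bacc, sens, spec

    @property
    def acc(self) -> float:
        return float(self.per_run["acc"].mean())

    @property
    def bacc(self) -> float:
        return float(self.per_run["bacc"].mean())

    @property
    def sens(self) -> float:
        return float(self.per_run["sens"].mean())

    @property
    def spec(self) -> float:
        return float(self.per_run["spec"].mean())


def run_cv(
    X,
    y,
    classifier_kind: str = "lda",
    n_folds: int = 6,
    n_runs: int | None = None,
    seed: int = 0,
    positive_label: str | None = None,
    stratified: bool = True,
) -> ClassificationResult:
    """Repeated stratified k-fold cross-validation.

    Each run reshuffles the fold assignment, trains on k-1 folds, predicts
    the held-out fold, pools predictions over folds and computes metrics.
    All randomness (fold shuffles and forest bootstraps) derives from
    ``seed``.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than {n_folds} folds"
        )
    if n_runs is None:
        n_runs = DEFAULT_RUNS[classifier_kind]
    if positive_label is None:
        positive_label = str(classes[-1])

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        if stratified:
            splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=run_seed)
        else:
            splitter = KFold(n_splits=n_folds, shuffle=True, random_state=run_seed)
        splits = splitter.split(X, y)
        pred = np.empty(len(y), dtype=y.dtype)
        for train_idx, test_idx in splits:
            clf = make_classifier(classifier_kind, seed=run_seed)
            clf.fit(X[train_idx], y[train_idx])
            pred[test_idx] = clf.predict(X[test_idx])
        acc, bacc, sens, spec = compute_metrics(pred, y, positive_label)
        rows.append({"acc": acc, "bacc": bacc, "sens": sens, "spec": spec})
    return ClassificationResult(
        classifier=classifier_kind,
        n_folds=n_folds,
        n_runs=n_runs,
        seed=seed,
        positive_label=str(positive_label),
        per_run=pd.DataFrame(rows),
    )
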