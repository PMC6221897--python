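"""Fast/slow trial decoding with a linear SVM and a permutation-null AUC test.

The observed statistic is the AUC of pooled cross-validated decision values:
stratified k-fold, per-fold standardization fit on the training fold only, a
linear-kernel maximum-margin classifier (C = 1), decision values pooled
across test folds, AUC against the true labels. The null distribution
re-runs the identical procedure on randomly *generated* labels (fair
Bernoulli per trial, not a permutation of the observed labels), and the
p-value uses the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm),
so p can never be exactly 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Trials x features design matrix with binary fast/slow labels."""

    X: np.ndarray
    y: np.ndarray  # 1 = fast, 0 = slow
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y).astype(int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of trials")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]


@dataclass
class DecoderResult:
    """Cross-validated AUC with its permutation null."""

    auc: float
    null_aucs: np.ndarray
    p_value: float
    folds: int
    seed: int
    n_perm: int
    feature_names: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "auc": self.auc,
                    "p_value": self.p_value,
                    "folds": self.folds,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                    "feature_names": self.feature_names,
                },
                fh,
                indent=2,
            )


def crossval_auc(features: FeatureMatrix, k: int = 10, seed: int = 0,
                 y: np.ndarray | None = None) -> float:
    """Stratified k-fold cross-validated AUC from pooled decision values.

    Standardization statistics come from each training fold alone, so no
    test information leaks into the scaling. ``y`` overrides the labels in
    ``features`` (used internally by the permutation test).
    """
    X = features.X
    labels = features.y if y is None else np.asarray(y).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} trials; cannot stratify into {k} folds"
        )
    if k < 2:
        raise ValueError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    decision = np.empty(labels.shape[0])
    for train, test in skf.split(X, labels):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=1.0)
        clf.fit((X[train] - mu) / sd, labels[train])
        decision[test] = clf.decision_function((X[test] - mu) / sd)
    return float(roc_auc_score(labels, decision))


def permutation_test(features: FeatureMatrix, k: int = 10, n_perm: int = 1000,
                     seed: int = 0, null: str = "generated") -> DecoderResult:
    """Permutation-null significance of the cross-validated AUC.

    ``null="generated"`` draws each null labeling as fair Bernoulli over
    trials (redrawing labelings too imbalanced to stratify, with the redraw
    count logged); ``null="permuted"`` shuffles the observed labels instead,
    preserving class balance.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = crossval_auc(features, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    n = features.y.shape[0]
    null_aucs = np.empty(n_perm)
    redraws = 0
    for i in range(n_perm):
        while True:
            if null == "generated":
                labels = rng.integers(0, 2, size=n)
            elif null == "permuted":
                labels = rng.permutation(features.y)
            else:
                raise ValueError(f"unknown null scheme {null!r}")
            counts = np.bincount(labels, minlength=2)
            if counts.min() >= k:
                break
            redraws += 1
        null_aucs[i] = crossval_auc(features, k=k, seed=seed + 1 + i, y=labels)
    if redraws:
        logger.info("redrew %d null labeling(s) too imbalanced for %d-fold CV", redraws, k)
    p = (1.0 + np.sum(null_aucs >= observed)) / (1.0 + n_perm)
    return DecoderResult(
        auc=observed,
        null_aucs=null_aucs,
        p_value=float(p),
        folds=k,
        seed=seed,
        n_perm=n_perm,
        feature_names=list(features.feature_names),
    )
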