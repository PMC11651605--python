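"""Relating graph structure to sensitivity outcomes with classifiers.

With only 12 node types the feature table is tiny, so it is augmented by
concatenating noisy copies (zero-mean Gaussian noise, sd 0.3 on
standardized features, i.e. 9% of total variance).  Binary questions
(preferential vs not) use ridge-penalized logistic regression; multiclass
questions (which wave is preferred) use an RBF support-vector classifier
with penalty and kernel scale chosen by grid search.  Feature importance
comes from a randomized recursive feature elimination: many repeats each
draw a small random feature subset and iteratively drop the feature whose
removal costs the least validation accuracy; features are ranked by how
often they are the sole survivor relative to how often they were drawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedGroupKFold,
    StratifiedKFold,
    cross_val_score,
)
from sklearn.svm import SVC

AUGMENT_NOISE_SD = 0.3
DEFAULT_N_COPIES = 20


def standardize(features: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance columns (population std)."""
    sd = features.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant feature(s) cannot be standardized: {bad}")
    return (features - features.mean()) / sd


def augment(features: pd.DataFrame, labels: pd.Series,
            n_copies: int = DEFAULT_N_COPIES,
            noise_sd: float = AUGMENT_NOISE_SD,
            seed: int = 0):
    """Concatenate ``n_copies`` noisy replicas of the rows onto the table.

    Expects standardized features; with the default sd of 0.3 the injected
    noise carries 9% of the total variance of the augmented data.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    blocks = [features]
    labs = [labels]
    for k in range(n_copies):
        noisy = features + rng.normal(0.0, noise_sd, features.shape)
        noisy.index = [f"{i}.copy{k}" for i in features.index]
        blocks.append(noisy)
        labs.append(pd.Series(labels.to_numpy(),
                              index=noisy.index, name=labels.name))
    return pd.concat(blocks), pd.concat(labs)


def _classifier(kind: str, tuned: bool = False, seed: int = 0):
    if kind == "logistic":
        est = LogisticRegression(l1_ratio=0.0, max_iter=2000)  # ridge penalty
        grid = {"C": np.logspace(-2, 2, 5)}
    elif kind == "svc":
        est = SVC(kernel="rbf")
        grid = {"C": np.logspace(-1, 2, 4), "gamma": ["scale", 0.1, 1.0]}
    else:
        raise ValueError(f"unknown classifier kind '{kind}'")
    if not tuned:
        return est
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    return GridSearchCV(est, grid, cv=cv, scoring="accuracy")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    accuracies: np.ndarray
    n_splits: int

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std(self) -> float:
        return float(self.accuracies.std())


def _groups_from_index(index: pd.Index) -> np.ndarray:
    """Augmented copies share their original row's group label."""
    return np.array([str(i).split(".copy")[0] for i in index])


def validate(features: pd.DataFrame, labels: pd.Series,
             classifier_kind: str = "logistic",
             n_splits: int = 10, n_repeats: int = 5,
             seed: int = 0, tuned: bool = True,
             groups: np.ndarray | None = None) -> ValidationResult:
    """Stratified k-fold validation (10 folds, 5 repeats by default).

    Folds are grouped so that the noisy copies produced by :func:`augment`
    never straddle the train/test split of their original row — otherwise
    the classifier can simply memorize the 12 prototypes and validation
    accuracy is meaningless.  Groups default to the row-index convention of
    :func:`augment`.  If the smallest class has fewer distinct groups than
    the fold count, the fold count is reduced with a warning.  Returns the
    distribution of per-fold accuracies.
    """
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = labels.to_numpy()
    if groups is None:
        groups = _groups_from_index(features.index)
    group_class = pd.DataFrame({"g": groups, "y": y}).groupby("g")["y"].first()
    smallest = group_class.value_counts().min()
    if smallest < 2:
        raise ValueError("every class needs at least two groups of members")
    if smallest < n_splits:
        warnings.warn(
            f"smallest class has {smallest} groups; reducing folds from "
            f"{n_splits} to {smallest}"
        )
        n_splits = int(smallest)
    clf = _classifier(classifier_kind, tuned=tuned, seed=seed)
    accs = []
    for rep in range(n_repeats):
        cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                  random_state=seed * 100 + rep)
        folds = list(cv.split(X, y, groups))
        accs.extend(cross_val_score(clf, X, y, cv=folds,
                                    scoring="accuracy"))
    return ValidationResult(np.asarray(accs), n_splits)


# ---------------------------------------------------------------------------
# Recursive feature elimination over random subsets
# ---------------------------------------------------------------------------

@dataclass
class RFEReport:
    """Survival statistics per feature across randomized eliminations."""

    table: pd.DataFrame       # survival_probability, n_included, n_survived

    def ranking(self) -> pd.DataFrame:
        return self.table.sort_values("survival_probability",
                                      ascending=False)

    def top(self, k: int = 1) -> list:
        return list(self.ranking().index[:k])


def _subset_accuracy(X, y, cols, clf, cv) -> float:
    return float(cross_val_score(clf, X[:, cols], y, cv=cv,
                                 scoring="accuracy").mean())


def rfe(features: pd.DataFrame, labels: pd.Series,
        classifier_kind: str = "logistic",
        n_repeats: int = 100, subset_size: int = 5,
        final_k: int | None = None, seed: int = 0,
        eval_folds: int = 3) -> RFEReport:
    """Randomized recursive feature elimination.

    Each repeat draws ``subset_size`` random features and iteratively
    removes the feature whose removal least degrades cross-validated
    accuracy until ``final_k`` remain (2 for binary tasks, 1 for multiclass
    by default).  Survival probability is the number of times a feature was
    among the final survivors divided by the number of times it appeared in
    a drawn subset.
    """
    y = labels.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if final_k is None:
        final_k = 2 if len(classes) == 2 else 1
    n_features = features.shape[1]
    if subset_size > n_features:
        raise ValueError("subset size exceeds the number of features")
    if final_k > subset_size:
        raise ValueError("final_k cannot exceed the subset size")
    X = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    included = np.zeros(n_features, dtype=int)
    survived = np.zeros(n_features, dtype=int)
    groups = _groups_from_index(features.index)
    group_class = pd.DataFrame({"g": groups, "y": y}).groupby("g")["y"].first()
    folds = min(eval_folds, int(group_class.value_counts().min()))
    for rep in range(n_repeats):
        cols = list(rng.choice(n_features, subset_size, replace=False))
        included[cols] += 1
        cv = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                  random_state=seed * 1000 + rep)
        splits = list(cv.split(X, y, groups))
        clf = _classifier(classifier_kind, tuned=False)
        while len(cols) > final_k:
            best_acc, drop = -np.inf, None
            for f in cols:
                rest = [c for c in cols if c != f]
                acc = _subset_accuracy(X, y, rest, clf, splits)
                if acc > best_acc:
                    best_acc, drop = acc, f
            cols.remove(drop)
        survived[cols] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(included > 0, survived / np.maximum(included, 1),
                        0.0)
    table = pd.DataFrame({
        "survival_probability": prob,
        "n_included": included,
        "n_survived": survived,
    }, index=features.columns)
    return RFEReport(table)


# ---------------------------------------------------------------------------
# Decision-boundary export
# ---------------------------------------------------------------------------

def decision_boundary_grid(features: pd.DataFrame, labels: pd.Series,
                           feature_pair: tuple, classifier_kind="logistic",
                           n_grid: int = 50, seed: int = 0) -> pd.DataFrame:
    """Class probabilities of a fitted 2-feature classifier on a grid.

    A plotting-friendly CSV export of the decision surface over the two
    named features.
    """
    fx, fy = feature_pair
    X = features[[fx, fy]].to_numpy(dtype=float)
    y = labels.to_numpy()
    if classifier_kind == "svc":
        clf = CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                     ensemble=False, cv=3)
    else:
        clf = LogisticRegression(l1_ratio=0.0, max_iter=2000)
    clf.fit(X, y)
    gx = np.linspace(X[:, 0].min() - 1, X[:, 0].max() + 1, n_grid)
    gy = np.linspace(X[:, 1].min() - 1, X[:, 1].max() + 1, n_grid)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    proba = clf.predict_proba(pts)
    out = pd.DataFrame({fx: pts[:, 0], fy: pts[:, 1]})
    for k, cls in enumerate(clf.classes_):
        out[f"p_{cls}"] = proba[:, k]
    return out
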