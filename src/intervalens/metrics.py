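"""Evaluation metrics and the repeated-split experiment harness.

Metrics are the three reported for multi-class expression data: accuracy
(correct predictions over total predictions), balanced accuracy (the
unweighted mean of per-class recalls, robust to class imbalance) and
macro One-vs-One ROC AUC (the average over all unordered class pairs of
the two directional pairwise AUCs, each computed from the corresponding
class's membership column on the samples of the two classes).

The harness repeats a stratified 80/20 train–test split with different
seeds, fits a min–max scaler on the training partition only (test features
may leave [0, 1] and are deliberately not clipped — clipping would distort
distances for nearest-neighbour members), evaluates every model spec on
the test partition and reports mean ± standard deviation per metric,
sorted by descending ROC AUC.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import accuracy_score, balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import MinMaxScaler

from .model_zoo import soft_labels

logger = logging.getLogger(__name__)


def accuracy(y_true, y_pred) -> float:
    """Fraction of correct predictions."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("accuracy of an empty prediction set")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    return float(accuracy_score(y_true, y_pred))


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-class recalls over the classes in ``y_true``."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("balanced accuracy of an empty prediction set")
    return float(balanced_accuracy_score(y_true, y_pred))


def ovo_roc_auc(y_true, membership, class_ids: Sequence | None = None) -> float:
    """Macro One-vs-One ROC AUC from per-class membership degrees.

    For each unordered class pair (a, b), restrict to samples of those two
    classes and average the AUC of class a's membership column (a as
    positive) with the AUC of class b's column (b as positive).  Pairs with
    a class absent from ``y_true`` are skipped with a warning; if no pair
    is scorable an error is raised.
    """
    y_true = np.asarray(y_true)
    membership = np.asarray(membership, dtype=float)
    if class_ids is None:
        class_ids = np.arange(membership.shape[1])
    class_ids = np.asarray(class_ids)
    if membership.ndim != 2 or membership.shape[1] != len(class_ids):
        raise ValueError("membership must be (samples, classes) matching class_ids")
    if membership.shape[1] < 2:
        raise ValueError("need >= 2 classes for ROC AUC")
    present = set(np.unique(y_true).tolist())
    pair_aucs = []
    for a, b in combinations(range(len(class_ids)), 2):
        ca, cb = class_ids[a], class_ids[b]
        if ca not in present or cb not in present:
            logger.warning("skipping class pair (%r, %r): class absent", ca, cb)
            continue
        mask = (y_true == ca) | (y_true == cb)
        auc_a = roc_auc_score(y_true[mask] == ca, membership[mask, a])
        auc_b = roc_auc_score(y_true[mask] == cb, membership[mask, b])
        pair_aucs.append(0.5 * (auc_a + auc_b))
    if not pair_aucs:
        raise ValueError("no class pair with both classes present in y_true")
    return float(np.mean(pair_aucs))


def split_and_scale(X, y, seed: int, test_size: float = 0.2):
    """One stratified train/test split with train-fitted min–max scaling.

    Returns ``(X_train, X_test, y_train, y_test, scaler)``; the scaler's
    parameters are functions of the training partition only.
    """
    X, y = np.asarray(X), np.asarray(y)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    scaler = MinMaxScaler().fit(X_tr)
    return scaler.transform(X_tr), scaler.transform(X_te), y_tr, y_te, scaler


def _membership(model, X, class_ids) -> np.ndarray:
    # soft_labels handles both probability and margin emitters uniformly
    return soft_labels(model, X, class_ids).values


def run_experiment(
    X,
    y,
    model_specs: Sequence[tuple[str, object]],
    n_repeats: int = 5,
    seed: int = 0,
    test_size: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Repeated stratified 80/20 evaluation of a set of model specs.

    ``model_specs`` is a sequence of ``(tag, estimator)`` pairs; estimators
    are cloned per repeat, fitted on the scaled training partition and
    scored on the scaled test partition.  Returns a results table (one row
    per spec: mean ± std of OvO ROC AUC, accuracy and balanced accuracy
    over repeats, sorted by descending ROC AUC) and the raw per-repeat
    scores keyed by tag, suitable for downstream significance testing.
    """
    X, y = np.asarray(X), np.asarray(y)
    raw: dict[str, dict[str, list[float]]] = {
        tag: {"roc_auc": [], "accuracy": [], "balanced_accuracy": []}
        for tag, _ in model_specs
    }
    for r in range(n_repeats):
        split_seed = seed + r
        X_tr, X_te, y_tr, y_te, _ = split_and_scale(X, y, split_seed, test_size)
        class_ids = np.unique(y_tr)
        for tag, proto in model_specs:
            model = clone(proto)
            model.fit(X_tr, y_tr)
            y_pred = model.predict(X_te)
            memb = _membership(model, X_te, class_ids)
            raw[tag]["roc_auc"].append(ovo_roc_auc(y_te, memb, class_ids))
            raw[tag]["accuracy"].append(accuracy(y_te, y_pred))
            raw[tag]["balanced_accuracy"].append(balanced_accuracy(y_te, y_pred))
    rows = []
    for tag, proto in model_specs:
        agg = getattr(proto, "aggregation", "")
        rows.append(
            {
                "classifier": tag,
                "aggregation": agg,
                "roc_auc_mean": float(np.mean(raw[tag]["roc_auc"])),
                "roc_auc_std": float(np.std(raw[tag]["roc_auc"])),
                "accuracy_mean": float(np.mean(raw[tag]["accuracy"])),
                "accuracy_std": float(np.std(raw[tag]["accuracy"])),
                "balanced_accuracy_mean": float(np.mean(raw[tag]["balanced_accuracy"])),
                "balanced_accuracy_std": float(np.std(raw[tag]["balanced_accuracy"])),
                "n_repeats": n_repeats,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "roc_auc_mean", ascending=False, kind="stable", ignore_index=True
    )
    return table, raw


def format_results_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable ``mean±std`` view of a :func:`run_experiment` table."""
    def fmt(m, s):
        return f"{m:.3f}±{s:.3f}"

    return pd.DataFrame(
        {
            "Classifier": table["classifier"],
            "Aggregation": table["aggregation"],
            "ROC AUC": [fmt(m, s) for m, s in zip(table["roc_auc_mean"], table["roc_auc_std"])],
            "Accuracy": [
                fmt(m, s) for m, s in zip(table["accuracy_mean"], table["accuracy_std"])
            ],
            "Balanced Accuracy": [
                fmt(m, s)
                for m, s in zip(
                    table["balanced_accuracy_mean"], table["balanced_accuracy_std"]
                )
            ],
        }
    )
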