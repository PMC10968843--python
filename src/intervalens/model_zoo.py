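"""Heterogeneous base-classifier groups and soft-label extraction.

The default ensemble consists of four groups of three members each:
random forests with {10, 50, 100} trees, multilayer perceptrons with hidden
layers {[100], [50, 50], [100, 50, 25]}, support-vector machines with
{linear, polynomial, RBF} kernels, and k-nearest-neighbour classifiers with
k in {1, 3, 5} under the Manhattan (L1) metric.  Users may register any
group of classifiers exposing ``fit`` plus per-class scores
(``predict_proba`` or ``decision_function``); group membership is always
explicit.

Soft labels are per-class membership scores in [0, 1].  Models that emit
calibrated probabilities pass through unchanged; models that emit margins
or other scores with ANY value outside [0, 1] have their whole score matrix
mapped row-wise through softmax.  The check is per matrix, not per row:
mixing calibrated and softmaxed rows in one matrix would be incoherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import softmax
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC


@dataclass
class ModelGroup:
    """A named family of >= 2 independent base classifiers.

    ``members`` are unfitted estimator prototypes; the ensemble clones and
    fits them.  Entropy selection may later prune members but never below 2.
    """

    name: str
    members: list = field(default_factory=list)
    member_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(
                f"group {self.name!r} needs >= 2 members, got {len(self.members)}"
            )
        if not self.member_names:
            self.member_names = [
                f"{self.name}_{i}" for i in range(len(self.members))
            ]
        if len(self.member_names) != len(self.members):
            raise ValueError("member_names length must match members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SoftLabelMatrix:
    """Per-sample, per-class membership scores in [0, 1].

    Columns follow ``class_ids`` ordering.  Rows need not sum to 1 (only
    the softmax branch guarantees that); only the final membership output
    of the ensemble is renormalised.
    """

    values: np.ndarray
    class_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.class_ids = np.asarray(self.class_ids)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.class_ids):
            raise ValueError("values must be (samples, classes) matching class_ids")


def _seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def build_default_groups(seed: int) -> list[ModelGroup]:
    """The default four-group, twelve-member heterogeneous zoo.

    All stochastic members are seeded deterministically from ``seed``; two
    calls with the same seed build identically configured groups.
    """
    s = _seeds(seed, 6)
    rf = ModelGroup(
        "RF",
        [
            RandomForestClassifier(n_estimators=n, random_state=s[0] + i)
            for i, n in enumerate((10, 50, 100))
        ],
        [f"RF_{n}" for n in (10, 50, 100)],
    )
    mlp = ModelGroup(
        "MLP",
        [
            MLPClassifier(hidden_layer_sizes=h, max_iter=1000, random_state=s[1] + i)
            for i, h in enumerate(((100,), (50, 50), (100, 50, 25)))
        ],
        ["MLP_100", "MLP_50x50", "MLP_100x50x25"],
    )
    # SVC emits decision scores (no internal probability calibration); the
    # softmax branch of soft_labels normalises them.
    svm = ModelGroup(
        "SVM",
        [
            SVC(kernel=k, degree=3, random_state=s[2] + i)
            for i, k in enumerate(("linear", "poly", "rbf"))
        ],
        ["SVM_linear", "SVM_poly", "SVM_rbf"],
    )
    knn = ModelGroup(
        "KNN",
        [KNeighborsClassifier(n_neighbors=k, metric="manhattan") for k in (1, 3, 5)],
        [f"{k}NN" for k in (1, 3, 5)],
    )
    return [rf, mlp, svm, knn]


def soft_labels(model, X, class_ids: Sequence) -> SoftLabelMatrix:
    """Extract normalised per-class scores from a fitted classifier.

    Native probabilities (all values already in [0, 1]) pass through; any
    out-of-range value switches the whole matrix to row-wise softmax.
    Binary margin vectors are expanded to two signed columns before the
    range check.  Columns are reordered to follow ``class_ids``.
    """
    class_ids = np.asarray(class_ids)
    if hasattr(model, "predict_proba"):
        scores = np.asarray(model.predict_proba(X), dtype=float)
    elif hasattr(model, "decision_function"):
        scores = np.asarray(model.decision_function(X), dtype=float)
        if scores.ndim == 1:
            # binary margin: positive favours the second class
            scores = np.column_stack([-scores, scores])
    else:
        raise TypeError(
            f"{type(model).__name__} exposes neither predict_proba nor decision_function"
        )
    model_classes = np.asarray(getattr(model, "classes_"))
    if scores.shape[1] != len(model_classes):
        raise ValueError(
            f"model emitted {scores.shape[1]} score columns for "
            f"{len(model_classes)} classes"
        )
    if not np.array_equal(np.sort(model_classes), np.sort(class_ids)):
        raise ValueError(
            f"model classes {model_classes.tolist()} do not match "
            f"expected class ids {class_ids.tolist()}"
        )
    # reorder model columns into the requested class order
    order = np.array(
        [int(np.flatnonzero(model_classes == c)[0]) for c in class_ids]
    )
    scores = scores[:, order]
    if np.any(scores < 0.0) or np.any(scores > 1.0):
        scores = softmax(scores, axis=1)
    return SoftLabelMatrix(scores, class_ids)
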