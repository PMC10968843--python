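"""The interval-modeling ensemble classifier and its three variants.

``pom_alg``
    Every member of every group is fitted on the training data; no
    selection takes place.
``pom_ent``
    Entropy selection (repeated stratified two-fold cross-validation on
    the training data, scored by mean cross-entropy loss) prunes members
    within each group; survivors are refitted on the full training set.
``pom_egrp``
    As ``pom_ent``, and additionally whole groups are kept or dropped by
    comparing group-mean losses; at least two groups always survive.

Prediction: for each group, the members' soft-label matrices are collapsed
per sample and class into the interval ``[min, max]`` over members; each
class's per-group intervals are aggregated with one of the ten
interval-valued aggregation functions (arity = number of surviving groups);
the predicted class is the one whose aggregated interval is greatest under
the chosen linear interval order (Xu–Yager by default).  Membership degrees
are the aggregated intervals' midpoints, renormalised to sum to 1 (uniform
if all midpoints are 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .aggregations import aggregate_bounds, coerce_aggregation
from .intervals import Interval, OrderSpec
from .model_zoo import ModelGroup, build_default_groups, soft_labels
from .selection import SelectionReport, run_selection

VARIANTS = ("pom_alg", "pom_ent", "pom_egrp")


@dataclass
class ClassIntervalTensor:
    """Per-sample, per-class, per-group soft-label intervals.

    ``lowers``/``uppers`` have shape (n_samples, n_classes, n_groups); each
    cell is the min/max over the group's members of the member's soft label
    for that class, hence always a valid interval.
    """

    lowers: np.ndarray
    uppers: np.ndarray
    class_ids: np.ndarray
    group_names: list[str]

    def interval(self, sample: int, class_index: int, group: int) -> Interval:
        return Interval(
            float(self.lowers[sample, class_index, group]),
            float(self.uppers[sample, class_index, group]),
        )


def _decision_keys(
    lo: np.ndarray, up: np.ndarray, order: OrderSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(primary, secondary) arrays; lexicographically larger = greater interval."""
    if order is OrderSpec.XY:
        return lo + up, up - lo
    if order is OrderSpec.LEX1:
        return lo, up
    return up, lo


def _lex_argmax(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Row-wise argmax under the (primary, secondary) lexicographic key,
    ties resolved to the smallest column index."""
    n, k = primary.shape
    best = np.zeros(n, dtype=int)
    rows = np.arange(n)
    for c in range(1, k):
        bp, bs = primary[rows, best], secondary[rows, best]
        better = (primary[:, c] > bp) | ((primary[:, c] == bp) & (secondary[:, c] > bs))
        best[better] = c
    return best


class IntervalEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Heterogeneous ensemble classifier based on interval modeling.

    Parameters
    ----------
    variant : {"pom_alg", "pom_ent", "pom_egrp"}
        No selection / member selection / member-and-group selection.
    groups : list of ModelGroup, optional
        Base-classifier groups (>= 2 groups of >= 2 members).  ``None``
        builds the default four-family zoo seeded from ``random_state``.
    aggregation : {"A1", ..., "A10"}
        Interval-valued aggregation combining per-group class intervals.
    order : {"xy", "lex1", "lex2"}
        Linear interval order deciding the winning class.
    n_splits, n_repeats : int
        Shape of the nested stratified cross-validation used by the
        entropy variants (default: two folds repeated ten times).
    random_state : int, optional
        Seeds the default zoo and the nested CV splits.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique training labels; fixes the class-column order used
        everywhere downstream.
    fitted_groups_ : list of ModelGroup
        Surviving groups with fitted members.
    selection_report_ : SelectionReport or None
        Audit of the entropy selection (``None`` for ``pom_alg``).
    """

    def __init__(
        self,
        variant: str = "pom_alg",
        groups: list[ModelGroup] | None = None,
        aggregation: str = "A1",
        order: str = "xy",
        n_splits: int = 2,
        n_repeats: int = 10,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.groups = groups
        self.aggregation = aggregation
        self.order = order
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y) -> "IntervalEnsembleClassifier":
        variant = str(self.variant).lower()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected {VARIANTS}")
        coerce_aggregation(self.aggregation)
        OrderSpec.coerce(self.order)

        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")

        seed = 0 if self.random_state is None else int(self.random_state)
        prototypes = self.groups if self.groups is not None else build_default_groups(seed)
        if len(prototypes) < 2:
            raise ValueError("need >= 2 model groups")

        if variant == "pom_alg":
            self.selection_report_ = None
            kept_models = [list(range(len(g))) for g in prototypes]
            kept_groups = list(range(len(prototypes)))
        else:
            report = run_selection(
                prototypes,
                X,
                y,
                select_group_level=(variant == "pom_egrp"),
                n_splits=self.n_splits,
                n_repeats=self.n_repeats,
                seed=seed,
            )
            self.selection_report_ = report
            kept_models = report.kept_models
            kept_groups = report.kept_groups

        self.fitted_groups_ = []
        for g in kept_groups:
            proto = prototypes[g]
            members = [clone(proto.members[m]).fit(X, y) for m in kept_models[g]]
            self.fitted_groups_.append(
                ModelGroup(
                    proto.name,
                    members,
                    [proto.member_names[m] for m in kept_models[g]],
                )
            )
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------------- predict

    def class_intervals(self, X) -> ClassIntervalTensor:
        """Per-group [min, max] soft-label intervals for every sample/class."""
        check_is_fitted(self, "fitted_groups_")
        X = np.asarray(X)
        lowers, uppers = [], []
        for group in self.fitted_groups_:
            sls = np.stack(
                [soft_labels(m, X, self.classes_).values for m in group.members]
            )  # (members, samples, classes)
            lowers.append(sls.min(axis=0))
            uppers.append(sls.max(axis=0))
        return ClassIntervalTensor(
            lowers=np.stack(lowers, axis=-1),
            uppers=np.stack(uppers, axis=-1),
            class_ids=self.classes_,
            group_names=[g.name for g in self.fitted_groups_],
        )

    def _aggregated_bounds(self, X) -> tuple[np.ndarray, np.ndarray]:
        tensor = self.class_intervals(X)
        return aggregate_bounds(self.aggregation, tensor.lowers, tensor.uppers)

    def predict(self, X) -> np.ndarray:
        """Class whose aggregated interval is greatest under the order."""
        lo, up = self._aggregated_bounds(X)
        if len(self.classes_) == 1:  # degenerate guard; cannot arise via fit
            return np.repeat(self.classes_[0], lo.shape[0])
        primary, secondary = _decision_keys(lo, up, OrderSpec.coerce(self.order))
        return self.classes_[_lex_argmax(primary, secondary)]

    def predict_proba(self, X) -> np.ndarray:
        """Membership degrees: normalised midpoints of aggregated intervals."""
        lo, up = self._aggregated_bounds(X)
        mid = 0.5 * (lo + up)
        sums = mid.sum(axis=1, keepdims=True)
        k = mid.shape[1]
        out = np.where(sums > 0, mid / np.where(sums > 0, sums, 1.0), 1.0 / k)
        return out

    predict_membership = predict_proba

    # ------------------------------------------------------------- persist

    def save(self, path: str) -> None:
        """Persist the fitted ensemble as a joblib bundle + JSON sidecar."""
        check_is_fitted(self, "fitted_groups_")
        joblib.dump(self, path)
        sidecar = {
            "format_version": 1,
            "variant": str(self.variant),
            "aggregation": str(self.aggregation),
            "order": str(self.order),
            "class_ids": np.asarray(self.classes_).tolist(),
            "groups": {
                g.name: list(g.member_names) for g in self.fitted_groups_
            },
            "selection": self.selection_report_.to_dict()
            if isinstance(self.selection_report_, SelectionReport)
            else None,
        }
        with open(f"{path}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @staticmethod
    def load(path: str) -> "IntervalEnsembleClassifier":
        model = joblib.load(path)
        if not isinstance(model, IntervalEnsembleClassifier):
            raise TypeError(f"{path} does not contain an IntervalEnsembleClassifier")
        return model
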