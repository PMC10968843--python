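"""Cross-entropy loss and entropy-based selection of models and groups.

The two entropy ensemble variants score every member of every group with
mean cross-entropy (log) loss under repeated stratified two-fold
cross-validation run on the training partition only, then keep per group
the two best members plus any member at or below the group's average loss.
The group-selection variant additionally keeps groups at or below the
average of group means, falling back to the best two groups when fewer
than two qualify.

Group means are computed over ALL original members, before any pruning —
the group mean is established before member selection and reused for group
selection.

Probabilities are clipped to ``[eps, 1-eps]`` with ``eps = 1e-15`` before
the logarithm: 1-NN members emit exact 0/1 soft labels, and an unclipped
log loss would be infinite, leaving selection undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import RepeatedStratifiedKFold

from .model_zoo import ModelGroup, SoftLabelMatrix, soft_labels

logger = logging.getLogger(__name__)

_EPS = 1e-15


def cross_entropy_loss(true_labels, probs) -> float:
    """Mean negative log-probability of the true classes.

    ``-(1/N) Σ_i Σ_k y_{i,k} log p_{i,k}`` with one-hot indicators ``y``.
    ``probs`` may be a :class:`SoftLabelMatrix` or a plain (N, K) array; in
    the latter case the class set is taken to be ``0..K-1``.
    """
    if isinstance(probs, SoftLabelMatrix):
        values, class_ids = probs.values, probs.class_ids
    else:
        values = np.asarray(probs, dtype=float)
        class_ids = np.arange(values.shape[1])
    true_labels = np.asarray(true_labels)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("probs must be an (N, K) matrix with K >= 2")
    if len(true_labels) != values.shape[0]:
        raise ValueError("true_labels length must match probs rows")
    lookup = {c: j for j, c in enumerate(class_ids.tolist())}
    try:
        cols = np.array([lookup[c] for c in true_labels.tolist()])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} outside the class set") from exc
    p = np.clip(values[np.arange(len(true_labels)), cols], _EPS, 1.0 - _EPS)
    return float(-np.mean(np.log(p)))


@dataclass
class LossReport:
    """Nested-CV cross-entropy losses for one family of groups.

    ``per_model_fold_losses[g][m]`` is member m's loss on each of the
    ``n_splits * n_repeats`` validation folds; ``per_model_mean[g][m]`` its
    mean; ``per_group_mean[g]`` the mean over ALL original members.
    """

    per_model_fold_losses: list[list[list[float]]]
    per_model_mean: list[list[float]]
    per_group_mean: list[float]


@dataclass
class SelectionReport:
    """Audit record of every keep/drop decision of an entropy fit."""

    kept_models: list[list[int]]
    kept_groups: list[int]
    group_means: list[float]
    group_mean_average: float
    seed: int
    n_splits: int
    n_repeats: int
    losses: LossReport | None = None
    group_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _check_stratifiable(y: np.ndarray, n_splits: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    smallest = int(np.argmin(counts))
    if counts[smallest] < n_splits:
        name = classes[smallest].item() if hasattr(classes[smallest], "item") else classes[smallest]
        raise ValueError(
            f"stratified {n_splits}-fold CV is infeasible: class "
            f"{name} has only {counts[smallest]} sample(s)"
        )


def model_mean_losses(
    group: ModelGroup,
    X,
    y,
    n_splits: int = 2,
    n_repeats: int = 10,
    seed: int = 0,
) -> tuple[list[list[float]], list[float], float]:
    """Per-member fold losses, per-member means and the group mean.

    Every member is cloned, fitted on each CV-train fold and scored with
    :func:`cross_entropy_loss` on the CV-test fold, over
    ``n_splits * n_repeats`` folds of a repeated stratified k-fold scheme
    seeded by ``seed``.  Run this on the outer training partition only.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    _check_stratifiable(y, n_splits)
    class_ids = np.unique(y)
    cv = RepeatedStratifiedKFold(
        n_splits=n_splits, n_repeats=n_repeats, random_state=seed
    )
    fold_losses: list[list[float]] = [[] for _ in group.members]
    for train_idx, test_idx in cv.split(X, y):
        for m, proto in enumerate(group.members):
            model = clone(proto)
            model.fit(X[train_idx], y[train_idx])
            sl = soft_labels(model, X[test_idx], class_ids)
            fold_losses[m].append(cross_entropy_loss(y[test_idx], sl))
    means = [float(np.mean(fl)) for fl in fold_losses]
    return fold_losses, means, float(np.mean(means))


def select_models(member_means) -> list[int]:
    """Kept member indices: the best two plus everyone at or below average.

    Ties on loss break to the smaller index.  Always returns >= 2 indices,
    sorted.
    """
    means = [float(v) for v in member_means]
    if len(means) < 2:
        raise ValueError("select_models needs >= 2 members")
    ranked = sorted(range(len(means)), key=lambda i: (means[i], i))
    kept = set(ranked[:2])
    avg = float(np.mean(means))
    kept.update(i for i, v in enumerate(means) if v <= avg)
    return sorted(kept)


def select_groups(group_means) -> list[int]:
    """Kept group indices: everyone at or below the average of group means;
    if fewer than two qualify, exactly the best two groups.

    Ties on loss break to the smaller index.  Always returns >= 2 indices,
    sorted.
    """
    means = [float(v) for v in group_means]
    if len(means) < 2:
        raise ValueError("select_groups needs >= 2 groups")
    avg = float(np.mean(means))
    kept = [i for i, v in enumerate(means) if v <= avg]
    if len(kept) < 2:
        ranked = sorted(range(len(means)), key=lambda i: (means[i], i))
        kept = sorted(ranked[:2])
    return kept


def run_selection(
    groups: list[ModelGroup],
    X,
    y,
    select_group_level: bool,
    n_splits: int = 2,
    n_repeats: int = 10,
    seed: int = 0,
    keep_losses: bool = True,
) -> SelectionReport:
    """Full nested-CV selection over a family of groups.

    Member selection always runs; group selection only when
    ``select_group_level``.  The returned report records every decision and
    the provenance needed to replay it.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 model groups")
    all_fold_losses, all_means, group_means = [], [], []
    for g, group in enumerate(groups):
        fold_losses, means, gmean = model_mean_losses(
            group, X, y, n_splits=n_splits, n_repeats=n_repeats, seed=seed
        )
        all_fold_losses.append(fold_losses)
        all_means.append(means)
        group_means.append(gmean)
        logger.debug("group %s member mean losses: %s", group.name, means)

    kept_models = [select_models(means) for means in all_means]
    for group, means, kept in zip(groups, all_means, kept_models):
        for m in range(len(means)):
            if m not in kept:
                logger.info(
                    "dropping model %s (mean loss %.4f > group avg %.4f)",
                    group.member_names[m], means[m], float(np.mean(means)),
                )

    if select_group_level:
        kept_groups = select_groups(group_means)
        for g, group in enumerate(groups):
            if g not in kept_groups:
                logger.info(
                    "dropping group %s (mean loss %.4f > overall avg %.4f)",
                    group.name, group_means[g], float(np.mean(group_means)),
                )
    else:
        kept_groups = list(range(len(groups)))

    return SelectionReport(
        kept_models=kept_models,
        kept_groups=kept_groups,
        group_means=[float(v) for v in group_means],
        group_mean_average=float(np.mean(group_means)),
        seed=seed,
        n_splits=n_splits,
        n_repeats=n_repeats,
        losses=LossReport(all_fold_losses, all_means, group_means)
        if keep_losses
        else None,
        group_names=[g.name for g in groups],
    )
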