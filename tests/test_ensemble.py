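"""The three ensemble variants: fitting, intervals, decisions, memberships."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from intervalens import IntervalEnsembleClassifier
from intervalens.model_zoo import ModelGroup
from tests.conftest import FixedSoftLabels

TRAIN_X = np.zeros((2, 1))
TRAIN_Y = np.array([0, 1])


def fixed_ensemble(group_probs, aggregation="A1", order="xy"):
    """Ensemble over dummy members emitting fixed per-class score rows.

    ``group_probs[g][m]`` is the (samples x classes) matrix of member m of
    group g.
    """
    groups = [
        ModelGroup(f"G{g}", [FixedSoftLabels(p) for p in members])
        for g, members in enumerate(group_probs)
    ]
    clf = IntervalEnsembleClassifier(
        variant="pom_alg", groups=groups, aggregation=aggregation, order=order
    )
    n_classes = len(group_probs[0][0][0])
    return clf.fit(np.zeros((n_classes, 1)), np.arange(n_classes))


class TestClassIntervals:
    def test_min_max_over_members(self):
        g = [[[0.3, 0.7]], [[0.7, 0.3]]]
        ens = fixed_ensemble([g, g])
        t = ens.class_intervals(np.zeros((1, 1)))
        assert tuple(t.interval(0, 0, 0)) == pytest.approx((0.3, 0.7))
        assert tuple(t.interval(0, 1, 0)) == pytest.approx((0.3, 0.7))

    def test_agreeing_members_give_degenerate_interval(self):
        g = [[[0.5, 0.5]], [[0.5, 0.5]]]
        ens = fixed_ensemble([g, g])
        t = ens.class_intervals(np.zeros((1, 1)))
        assert tuple(t.interval(0, 0, 0)) == pytest.approx((0.5, 0.5))

    def test_tensor_shape(self):
        probs = [[0.2, 0.3, 0.5], [0.1, 0.8, 0.1]]
        ens = fixed_ensemble([[probs, probs], [probs, probs, probs]])
        t = ens.class_intervals(np.zeros((2, 1)))
        assert t.lowers.shape == t.uppers.shape == (2, 3, 2)
        assert np.all(t.lowers <= t.uppers)


class TestPredict:
    def test_hand_worked_two_group_example(self):
        # class-0 intervals {[0.6,0.8],[0.5,0.7]} -> A1 [0.55,0.75];
        # class-1 {[0.1,0.3],[0.2,0.4]} -> [0.15,0.35]; XY sums 1.30 vs 0.50
        ens = fixed_ensemble(
            [
                [[[0.6, 0.1]], [[0.8, 0.3]]],
                [[[0.5, 0.2]], [[0.7, 0.4]]],
            ]
        )
        assert ens.predict(np.zeros((1, 1)))[0] == 0

    def test_identical_aggregated_intervals_pick_smallest_class(self):
        g = [[[0.4, 0.4]], [[0.4, 0.4]]]
        ens = fixed_ensemble([g, g])
        assert ens.predict(np.zeros((1, 1)))[0] == 0

    def test_member_permutation_within_group_is_irrelevant(self):
        other = [[[0.2, 0.9]], [[0.3, 0.8]]]
        a = fixed_ensemble([[[[0.6, 0.1]], [[0.8, 0.3]], [[0.7, 0.2]]], other])
        b = fixed_ensemble([[[[0.7, 0.2]], [[0.6, 0.1]], [[0.8, 0.3]]], other])
        X = np.zeros((1, 1))
        assert a.predict(X)[0] == b.predict(X)[0]
        np.testing.assert_allclose(a.predict_proba(X), b.predict_proba(X))

    @pytest.mark.parametrize("aggregation", ["A1", "A4", "A7", "A10"])
    def test_group_permutation_is_irrelevant(self, aggregation):
        g1 = [[[0.6, 0.1]], [[0.8, 0.3]]]
        g2 = [[[0.2, 0.5]], [[0.4, 0.9]]]
        X = np.zeros((1, 1))
        a = fixed_ensemble([g1, g2], aggregation)
        b = fixed_ensemble([g2, g1], aggregation)
        assert a.predict(X)[0] == b.predict(X)[0]
        np.testing.assert_allclose(a.predict_proba(X), b.predict_proba(X), atol=1e-12)

    def test_identical_members_reduce_to_single_model_argmax(self, rng):
        probs = rng.dirichlet(np.ones(3), size=6).tolist()
        ens = fixed_ensemble([[probs, probs], [probs, probs]])
        X = np.zeros((6, 1))
        np.testing.assert_array_equal(ens.predict(X), np.argmax(probs, axis=1))


class TestPredictMembership:
    def test_hand_worked_midpoints(self):
        # aggregated intervals [0.55,0.75] and [0.15,0.35]: midpoints
        # (0.65, 0.25), normalised (0.7222, 0.2778)
        ens = fixed_ensemble(
            [
                [[[0.6, 0.1]], [[0.8, 0.3]]],
                [[[0.5, 0.2]], [[0.7, 0.4]]],
            ]
        )
        memb = ens.predict_proba(np.zeros((1, 1)))[0]
        np.testing.assert_allclose(memb, [0.65 / 0.9, 0.25 / 0.9], atol=1e-12)

    def test_already_normalised_midpoints_unchanged(self):
        g = [[[0.6, 0.4]], [[0.6, 0.4]]]
        ens = fixed_ensemble([g, g])
        np.testing.assert_allclose(
            ens.predict_proba(np.zeros((1, 1)))[0], [0.6, 0.4], atol=1e-12
        )

    def test_all_zero_midpoints_give_uniform(self):
        g = [[[0.0, 0.0]], [[0.0, 0.0]]]
        ens = fixed_ensemble([g, g])
        np.testing.assert_allclose(
            ens.predict_proba(np.zeros((1, 1)))[0], [0.5, 0.5], atol=1e-12
        )

    def test_membership_sums_to_one(self, rng):
        probs = rng.random((5, 4)).tolist()
        ens = fixed_ensemble([[probs, probs], [probs, probs]], "A5")
        memb = ens.predict_proba(np.zeros((5, 1)))
        np.testing.assert_allclose(memb.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(memb >= 0)

    def test_membership_argmax_matches_xy_prediction(self, rng):
        # midpoint ranking equals the XY sum key ranking whenever sums differ
        for _ in range(20):
            probs1 = rng.random((4, 3)).tolist()
            probs2 = rng.random((4, 3)).tolist()
            ens = fixed_ensemble([[probs1, probs2], [probs2, probs1]], "A1", "xy")
            X = np.zeros((4, 1))
            memb = ens.predict_proba(X)
            np.testing.assert_array_equal(
                ens.predict(X), np.argmax(memb, axis=1)
            )


class TestFitVariants:
    def make_groups(self, n_groups=2, k_values=(1, 3)):
        return [
            ModelGroup(
                f"knn{g}",
                [KNeighborsClassifier(k, metric="manhattan") for k in k_values],
            )
            for g in range(n_groups)
        ]

    def test_pom_alg_keeps_everything(self, small_dataset):
        X, y = small_dataset
        ens = IntervalEnsembleClassifier(
            variant="pom_alg", groups=self.make_groups(3, (1, 3, 5)), random_state=0
        ).fit(X, y)
        assert ens.selection_report_ is None
        assert len(ens.fitted_groups_) == 3
        assert all(len(g) == 3 for g in ens.fitted_groups_)

    def test_default_zoo_pom_alg_has_twelve_members(self, small_dataset):
        X, y = small_dataset
        ens = IntervalEnsembleClassifier(variant="pom_alg", random_state=0).fit(X, y)
        assert len(ens.fitted_groups_) == 4
        assert sum(len(g) for g in ens.fitted_groups_) == 12

    def test_pom_ent_prunes_members_but_keeps_two(self, small_dataset):
        X, y = small_dataset
        ens = IntervalEnsembleClassifier(
            variant="pom_ent",
            groups=self.make_groups(2, (1, 3, 5)),
            n_repeats=2,
            random_state=0,
        ).fit(X, y)
        assert len(ens.fitted_groups_) == 2  # no group-level pruning
        for g, kept in zip(ens.fitted_groups_, ens.selection_report_.kept_models):
            assert len(g) == len(kept) >= 2

    def test_pom_egrp_keeps_at_least_two_groups(self, small_dataset):
        X, y = small_dataset
        ens = IntervalEnsembleClassifier(
            variant="pom_egrp",
            groups=self.make_groups(3, (1, 3, 5)),
            n_repeats=2,
            random_state=0,
        ).fit(X, y)
        assert len(ens.fitted_groups_) >= 2
        assert all(len(g) >= 2 for g in ens.fitted_groups_)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            IntervalEnsembleClassifier(groups=self.make_groups()).fit(
                np.zeros((4, 2)), np.zeros(4)
            )

    def test_unknown_variant_rejected(self, small_dataset):
        X, y = small_dataset
        with pytest.raises(ValueError, match="unknown variant"):
            IntervalEnsembleClassifier(variant="pom_xyz").fit(X, y)

    def test_selection_report_provenance(self, small_dataset):
        X, y = small_dataset
        ens = IntervalEnsembleClassifier(
            variant="pom_egrp",
            groups=self.make_groups(2, (1, 3)),
            n_repeats=2,
            random_state=42,
        ).fit(X, y)
        report = ens.selection_report_
        assert report.seed == 42
        assert report.n_splits == 2 and report.n_repeats == 2
        assert report.group_mean_average == pytest.approx(
            np.mean(report.group_means)
        )

    def test_save_load_roundtrip(self, small_dataset, tmp_path):
        X, y = small_dataset
        ens = IntervalEnsembleClassifier(
            variant="pom_alg", groups=self.make_groups(), random_state=0
        ).fit(X, y)
        path = tmp_path / "model.joblib"
        ens.save(str(path))
        assert (tmp_path / "model.joblib.json").exists()
        loaded = IntervalEnsembleClassifier.load(str(path))
        np.testing.assert_array_equal(loaded.predict(X[:10]), ens.predict(X[:10]))
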