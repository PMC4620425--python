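"""Selection loop, ratio condition, ensemble voting."""

import math

import numpy as np
import pytest

from rocboost import (
    SelectionCondition,
    WeakClassifier,
    auc,
    compute_ratio_stats,
    ensemble_auc,
    ensemble_score,
    result_from_json,
    result_to_json,
    run_boosting,
    select_feature,
)
from rocboost.boosting import rounds_to_csv

from _oracles import naive_run, naive_select


class TestRatioStats:
    def test_perfect_predictions_make_ratios_equal(self):
        labels = np.array([1, 1, 0, 0, 0])
        stats = compute_ratio_stats(labels, labels.astype(bool))
        assert stats.r == stats.r_prime
        assert stats.ratio_gap == 0.0

    def test_study_design_class_ratio(self):
        """148 positives vs 332+842 negatives give r = 148/1174 ≈ 0.12606."""
        labels = np.r_[np.ones(148, int), np.zeros(1174, int)]
        stats = compute_ratio_stats(labels, labels.astype(bool))
        assert stats.r == pytest.approx(0.12606, abs=5e-6)

    def test_correct_on_positives_only_leaves_r_prime_undefined(self):
        labels = np.array([1, 1, 0, 0])
        predictions = np.array([True, True, True, True])  # no negative correct
        stats = compute_ratio_stats(labels, predictions)
        assert stats.n_prime == 0
        assert stats.r_prime is None
        assert stats.ratio_gap == math.inf

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_ratio_stats(np.ones(4, int), np.ones(4, bool))


class TestSelectFeature:
    def test_perfect_separator_selected_with_full_strength(self, rng):
        values = np.column_stack([rng.normal(0, 1, 20), np.r_[np.ones(10), np.zeros(10)]])
        labels = np.repeat([1, 0], 10)
        feature_id, clf = select_feature(values, labels, SelectionCondition(mode="auc_only"))
        assert feature_id == 1
        assert clf.strength == 0.5

    def test_all_constant_features_yield_none(self):
        values = np.ones((10, 4))
        labels = np.array([1, 0] * 5)
        assert select_feature(values, labels, SelectionCondition()) is None

    def test_matches_bruteforce_argmax(self, rng):
        """Selection equals the exhaustive per-feature evaluation over the
        admissible set, for both condition modes."""
        for seed in range(10):
            local = np.random.default_rng(seed)
            values = np.round(local.normal(0, 1, (100, 20)), 2)
            labels = (local.random(100) < 0.3).astype(int)
            labels[:4] = [1, 1, 0, 0]
            values[labels == 1, :3] += local.uniform(0.2, 1.0)
            for condition in (
                SelectionCondition(mode="auc_only", epsilon_stop=0.02),
                SelectionCondition(mode="ratio", epsilon_stop=0.02, ratio_tolerance=0.3),
            ):
                got = select_feature(values, labels, condition)
                expected, _ = naive_select(values, labels, condition)
                if expected is None:
                    assert got is None
                else:
                    assert got is not None
                    assert got[0] == expected[0]
                    assert got[1].polarity == expected[1]
                    assert got[1].threshold == expected[2]

    def test_empty_view_rejected(self):
        with pytest.raises(ValueError):
            select_feature(np.empty((0, 0)), np.array([]), SelectionCondition())


class TestRunBoosting:
    def test_single_perfect_feature_stops_after_one_round(self):
        labels = np.repeat([1, 0], 6)
        values = labels[:, None].astype(float)
        result = run_boosting(values, labels, SelectionCondition(mode="auc_only"))
        assert len(result.rounds) == 1
        assert result.stop_reason in ("class_exhausted", "no_feature_beats_guess")
        assert result.rounds[0].n_remaining_after == 0

    def test_pure_noise_stops_without_selection(self):
        """On pure noise, selection strength is only sampling fluctuation:
        with 50 features on 100/100 examples the AUC noise scale is
        ~0.04, so its maximum over features hovers near 0.1 and an
        epsilon_stop clearly above that band admits nothing."""
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, (200, 50))
        labels = np.repeat([1, 0], 100)
        result = run_boosting(
            values, labels, SelectionCondition(mode="auc_only", epsilon_stop=0.15)
        )
        assert result.stop_reason == "no_feature_beats_guess"
        assert result.classifiers == []
        # at the noise band itself a handful of overfit picks may slip in
        result = run_boosting(
            values, labels, SelectionCondition(mode="auc_only", epsilon_stop=0.1)
        )
        assert len(result.classifiers) <= 3

    def test_selection_sequence_matches_loop_replay(self):
        """The full selection sequence (features, polarities, thresholds,
        stop reason) equals an independent brute-force replay, both modes."""
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(60, 160))
            n_feat = int(rng.integers(8, 30))
            values = np.round(rng.normal(0, 1, (n, n_feat)), 2)
            labels = (rng.random(n) < 0.35).astype(int)
            labels[:4] = [1, 1, 0, 0]
            values[labels == 1, : min(3, n_feat)] += rng.uniform(0.3, 1.0)
            for condition in (
                SelectionCondition(mode="auc_only", epsilon_stop=0.02),
                SelectionCondition(mode="ratio", epsilon_stop=0.02, ratio_tolerance=0.3),
            ):
                result = run_boosting(values, labels, condition, max_rounds=12)
                got = [(c.feature_index, c.polarity, c.threshold) for c in result.classifiers]
                expected, stop = naive_run(values, labels, condition, 12)
                assert got == expected
                assert result.stop_reason == stop

    def test_strict_progress_and_diagnostics(self, rng):
        values = rng.normal(0, 1, (120, 15))
        labels = (rng.random(120) < 0.4).astype(int)
        labels[:4] = [1, 1, 0, 0]
        values[labels == 1, :4] += 0.8
        result = run_boosting(values, labels, SelectionCondition(mode="auc_only"), max_rounds=20)
        remaining = len(labels)
        for diag in result.rounds:
            assert diag.n_removed >= 1
            assert diag.n_remaining_after == remaining - diag.n_removed
            remaining = diag.n_remaining_after
        assert len({c.feature_index for c in result.classifiers}) == len(result.classifiers)

    def test_every_selection_satisfies_the_condition(self, rng):
        """Admissibility: strength > epsilon_stop always; in ratio mode the
        full-training-set |r − r'| stays within tolerance with r' defined."""
        condition = SelectionCondition(mode="ratio", epsilon_stop=0.05, ratio_tolerance=0.2)
        values = rng.normal(0, 1, (150, 25))
        labels = (rng.random(150) < 0.25).astype(int)
        labels[:4] = [1, 1, 0, 0]
        values[labels == 1, :5] += 0.9
        result = run_boosting(values, labels, condition, max_rounds=20)
        assert result.classifiers, "planted signal should be selected"
        for clf in result.classifiers:
            assert clf.strength > condition.epsilon_stop
            stats = compute_ratio_stats(labels, clf.predict(values[:, clf.feature_index]))
            assert stats.p_prime > 0 and stats.n_prime > 0
            assert stats.ratio_gap <= condition.ratio_tolerance

    def test_max_rounds_cap(self, rng):
        values = rng.normal(0, 1, (400, 60))
        labels = np.repeat([1, 0], 200)
        values[labels == 1] += 0.15
        result = run_boosting(values, labels, SelectionCondition(mode="auc_only"), max_rounds=2)
        assert len(result.rounds) == 2
        assert result.stop_reason == "max_rounds"

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            run_boosting(np.empty((4, 0)), np.array([1, 0, 1, 0]), SelectionCondition())
        with pytest.raises(ValueError):
            SelectionCondition(mode="entropy")
        with pytest.raises(ValueError):
            SelectionCondition(epsilon_stop=-0.1)

    def test_mode_alias(self):
        assert SelectionCondition(mode="ratio_constrained").mode == "ratio"


class TestEnsemble:
    def test_single_classifier_reproduces_its_auc(self, rng):
        values = rng.normal(0, 1, (80, 5))
        labels = (rng.random(80) < 0.5).astype(int)
        labels[:2] = [0, 1]
        values[labels == 1, 2] += 1.0
        result = run_boosting(values, labels, SelectionCondition(mode="auc_only"), max_rounds=1)
        clf = result.classifiers[0]
        vote_auc = ensemble_auc([clf], values, labels)
        assert vote_auc == auc(np.where(clf.predict(values[:, clf.feature_index]), 1, -1), labels)

    def test_duplicated_classifier_preserves_ranking(self, rng):
        values = rng.normal(0, 1, (40, 3))
        labels = np.repeat([1, 0], 20)
        values[labels == 1, 0] += 1.0
        clf = WeakClassifier(feature_index=0, threshold=0.5, polarity=1, auc=0.75)
        assert ensemble_auc([clf], values, labels) == ensemble_auc([clf, clf], values, labels)

    def test_hand_counted_votes(self):
        values = np.array([
            [0.0, 10.0, 5.0],
            [2.0, 10.0, 5.0],
            [0.0, 0.0, 5.0],
            [2.0, 0.0, 0.0],
            [0.0, 10.0, 0.0],
            [2.0, 0.0, 0.0],
        ])
        classifiers = [
            WeakClassifier(feature_index=0, threshold=1.0, polarity=1, auc=0.7),
            WeakClassifier(feature_index=1, threshold=5.0, polarity=1, auc=0.6),
            WeakClassifier(feature_index=2, threshold=2.0, polarity=-1, auc=0.4),
        ]
        # votes: f0: ±1 by value>1; f1: value>5; f2 (reversed): value<2
        expected = np.array([
            -1 + 1 - 1,
            +1 + 1 - 1,
            -1 - 1 - 1,
            +1 - 1 + 1,
            -1 + 1 + 1,
            +1 - 1 + 1,
        ])
        np.testing.assert_array_equal(ensemble_score(classifiers, values), expected)

    def test_strength_weighted_variant(self):
        values = np.array([[0.0], [2.0]])
        clf = WeakClassifier(feature_index=0, threshold=1.0, polarity=1, auc=0.8)
        np.testing.assert_allclose(
            ensemble_score([clf], values, weighted=True),
            [-0.3, 0.3],
        )

    def test_missing_feature_id_rejected(self):
        clf = WeakClassifier(feature_index=7, threshold=0.0, polarity=1, auc=0.6)
        with pytest.raises(ValueError):
            ensemble_score([clf], np.zeros((3, 2)), feature_ids=[0, 1])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_score([], np.zeros((3, 2)))

    def test_ensemble_at_least_best_single_on_planted_signal(self):
        """Weak-learnability sanity: on planted-signal tongue images the
        vote ensemble does not fall more than 0.02 below the strongest
        single feature."""
        from rocboost import (
            COARSE_GRID, ScreenConfig, SyntheticConfig, enumerate_grid,
            extract_features, generate_dataset, t_screen,
        )

        specs = enumerate_grid(COARSE_GRID)
        for seed in range(3):
            config = SyntheticConfig(n_healthy=25, n_ill=25, seed=600 + seed)
            dataset = generate_dataset(config, test=2)
            matrix = extract_features(dataset.images, specs)
            matrix.labels = dataset.binary_labels
            screen = t_screen(matrix.values, matrix.labels, ScreenConfig(0.05))
            kept = matrix.select(screen.kept_indices)
            kept.labels = dataset.binary_labels
            result = run_boosting(
                kept.values, kept.labels, SelectionCondition(mode="ratio"),
                max_rounds=30, feature_ids=kept.feature_ids,
            )
            ens = ensemble_auc(result.classifiers, matrix.values, matrix.labels,
                               feature_ids=matrix.feature_ids)
            best = max(
                max(a, 1 - a)
                for a in (auc(matrix.values[:, j], matrix.labels)
                          for j in range(matrix.n_features))
            )
            assert ens >= best - 0.02


def test_result_json_roundtrip(tmp_path, rng):
    values = rng.normal(0, 1, (60, 8))
    labels = np.repeat([1, 0], 30)
    values[labels == 1, 1] += 1.5
    result = run_boosting(values, labels, SelectionCondition(mode="ratio", ratio_tolerance=0.4))
    result_to_json(result, tmp_path / "boost.json")
    back = result_from_json(tmp_path / "boost.json")
    assert back.classifiers == result.classifiers
    assert back.stop_reason == result.stop_reason
    assert back.condition == result.condition
    assert [r.to_dict() for r in back.rounds] == [r.to_dict() for r in result.rounds]
    rounds_to_csv(result, tmp_path / "rounds.csv")
    assert (tmp_path / "rounds.csv").read_text().startswith("round,feature_id")
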