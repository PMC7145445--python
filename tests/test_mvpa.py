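"""Decoding: feature building, LOPO classification, permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from babelnirs.mvpa import (
    FeatureMatrix, build_features, compare_accuracies, lopo_classify,
    permutation_test,
)


def _peak_table(patterns, channels=None):
    """patterns: {participant: {label: vector}} -> long peak table."""
    rows = []
    for pid, by_label in patterns.items():
        for label, vec in by_label.items():
            for ch, v in zip(channels or range(1, len(vec) + 1), vec):
                rows.append({
                    "participant_id": pid, "key": label, "kind": "modality",
                    "channel": ch, "chromophore": "hbo2",
                    "peak_amplitude": v,
                })
    return pd.DataFrame(rows)


def _noise_features(rng, n_sub=10, n_ch=46):
    """Feature matrix with no class information."""
    patterns = {
        f"p{i:02d}": {"spoken": rng.normal(size=n_ch),
                      "signed": rng.normal(size=n_ch)}
        for i in range(n_sub)
    }
    return build_features(_peak_table(patterns), ("spoken", "signed"),
                          list(range(1, n_ch + 1)))


def _separable_features(n_sub=10, n_ch=46, shift=5.0, noise_sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    patterns = {
        f"p{i:02d}": {"spoken": shift + noise_sd * rng.normal(size=n_ch),
                      "signed": -shift + noise_sd * rng.normal(size=n_ch)}
        for i in range(n_sub)
    }
    return build_features(_peak_table(patterns), ("spoken", "signed"),
                          list(range(1, n_ch + 1)))


class TestBuildFeatures:
    def test_columns_standardized(self):
        feats = _noise_features(np.random.default_rng(0))
        assert np.allclose(feats.X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(feats.X.std(axis=0), 1.0, atol=1e-12)

    def test_feature_vector_lengths(self, config):
        rng = np.random.default_rng(1)
        patterns = {
            f"p{i}": {"spoken": rng.normal(size=46),
                      "signed": rng.normal(size=46)}
            for i in range(6)
        }
        peaks = _peak_table(patterns, channels=config.montage.channel_ids)
        whole = build_features(peaks, ("spoken", "signed"),
                               config.montage.channel_ids)
        left = build_features(peaks, ("spoken", "signed"),
                              config.montage.hemisphere_ids("left"))
        right = build_features(peaks, ("spoken", "signed"),
                               config.montage.hemisphere_ids("right"))
        assert whole.X.shape[1] == 46
        assert left.X.shape[1] == 23
        assert right.X.shape[1] == 23

    def test_two_participant_zscore_by_hand(self):
        # 4 patterns x 2 channels; pencil-and-paper z-scores
        patterns = {
            "p1": {"a": [1.0, 10.0], "b": [3.0, 30.0]},
            "p2": {"a": [5.0, 50.0], "b": [7.0, 70.0]},
        }
        feats = build_features(_peak_table(patterns), ("a", "b"), [1, 2])
        col = np.array([1.0, 3.0, 5.0, 7.0])  # channel 1 values, p1 then p2
        expected = (col - 4.0) / np.std(col)
        by_pid_label = {
            (p, l): row for p, l, row
            in zip(feats.participants, feats.y, feats.X)
        }
        got = [by_pid_label[("p1", "a")][0], by_pid_label[("p1", "b")][0],
               by_pid_label[("p2", "a")][0], by_pid_label[("p2", "b")][0]]
        assert np.allclose(got, expected)

    def test_participants_missing_one_class_dropped(self):
        patterns = {
            "p1": {"spoken": [1.0], "signed": [2.0]},
            "p2": {"spoken": [3.0]},
            "p3": {"spoken": [4.0], "signed": [5.0]},
        }
        feats = build_features(_peak_table(patterns), ("spoken", "signed"), [1])
        assert feats.n_participants == 2
        assert "p2" not in feats.participants

    def test_missing_channels_imputed_at_zero(self):
        patterns = {
            "p1": {"spoken": [1.0, 2.0], "signed": [2.0, 1.0]},
            "p2": {"spoken": [3.0, 4.0], "signed": [4.0, 3.0]},
        }
        peaks = _peak_table(patterns)
        peaks = peaks[~((peaks.participant_id == "p2") & (peaks.channel == 2))]
        feats = build_features(peaks, ("spoken", "signed"), [1, 2])
        p2_rows = feats.X[feats.participants == "p2"]
        assert np.allclose(p2_rows[:, 1], 0.0)


class TestLopoClassify:
    def test_trial_bookkeeping(self):
        feats = _noise_features(np.random.default_rng(2), n_sub=20)
        res = lopo_classify(feats)
        assert res.n_trials == 40
        assert len(res.outcomes) == 40
        assert res.accuracy == res.outcomes.correct.mean()

    def test_separable_classes_perfectly_decoded(self):
        res = lopo_classify(_separable_features())
        assert res.accuracy == 1.0

    def test_pure_noise_near_chance_over_cohorts(self):
        accs = [
            lopo_classify(_noise_features(np.random.default_rng(100 + i),
                                          n_sub=8)).accuracy
            for i in range(30)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_accuracy_granularity(self):
        feats = _noise_features(np.random.default_rng(3), n_sub=7)
        res = lopo_classify(feats)
        assert (res.accuracy * 14) == pytest.approx(round(res.accuracy * 14))

    def test_degenerate_training_set_flagged(self):
        patterns = {f"p{i}": {"a": [0.0, 0.0], "b": [0.0, 0.0]}
                    for i in range(4)}
        feats = build_features(_peak_table(patterns), ("a", "b"), [1, 2])
        res = lopo_classify(feats)
        assert res.degenerate
        # deterministic tie rule: first class in canonical order
        assert (res.outcomes.predicted == "a").all()

    def test_too_few_participants_rejected(self):
        feats = _noise_features(np.random.default_rng(4), n_sub=2)
        with pytest.raises(ValueError, match="3 participants"):
            lopo_classify(feats)

    def test_leakage_free_mode_runs(self):
        feats = build_features(
            _peak_table({
                f"p{i}": {"spoken": np.random.default_rng(i).normal(
                    2, 1, size=8),
                    "signed": np.random.default_rng(100 + i).normal(
                        -2, 1, size=8)}
                for i in range(8)
            }),
            ("spoken", "signed"), list(range(1, 9)), standardize=False,
        )
        res = lopo_classify(feats, leakage_free=True)
        assert res.accuracy > 0.9

    def test_monotone_in_class_separation(self):
        """Median accuracy never decreases over a separation grid."""
        medians = []
        for shift in (0.0, 0.3, 0.8, 2.0):
            accs = [
                lopo_classify(_separable_features(
                    n_sub=8, n_ch=12, shift=shift, seed=200 + 17 * k
                )).accuracy
                for k in range(20)
            ]
            medians.append(np.median(accs))
        assert all(b >= a - 1e-12 for a, b in zip(medians, medians[1:]))


class TestPermutationTest:
    def test_strong_signal_attains_p_floor(self):
        # enough participants that the identity / all-swap patterns (which
        # also decode perfectly) are vanishingly unlikely among 200 draws
        feats = _separable_features(n_sub=14, n_ch=8)
        res = permutation_test(feats, n_permutations=200, seed=0)
        assert res.observed == 1.0
        assert res.p_value == 1 / 201

    def test_observed_below_all_nulls_gives_p_one(self):
        # anti-learnable: half the cohort uses the opposite label convention,
        # so the training majority always outvotes the held-out participant
        v = np.full(8, 3.0)
        patterns = {}
        for i in range(3):
            patterns[f"p{i}"] = {"spoken": v, "signed": -v}
        for i in range(3, 6):
            patterns[f"p{i}"] = {"spoken": -v, "signed": v}
        feats = build_features(_peak_table(patterns), ("spoken", "signed"),
                               list(range(1, 9)))
        res = permutation_test(feats, n_permutations=50, seed=1)
        assert res.observed == 0.0
        assert res.p_value == 1.0  # every null accuracy >= 0 = observed

    def test_exhaustive_three_participants_matches_enumeration(self):
        rng = np.random.default_rng(5)
        feats = _noise_features(rng, n_sub=3, n_ch=4)
        res = permutation_test(feats, exhaustive=True)
        assert res.n_permutations == 8

        # independent enumeration oracle over all 2^3 swap patterns
        from babelnirs.mvpa import _lopo_folds, _lopo_accuracy
        y_num = np.array([feats.classes.index(l) for l in feats.y])
        pids = pd.unique(feats.participants)
        folds = _lopo_folds(feats.X, feats.participants, pids)
        obs_pred, _ = _lopo_accuracy(feats.X, y_num, folds, 1.0)
        observed = (obs_pred == y_num).mean()
        null = []
        for swap in itertools.product([False, True], repeat=3):
            y_perm = y_num.copy()
            for pid, s in zip(pids, swap):
                if s:
                    sel = feats.participants == pid
                    y_perm[sel] = 1 - y_perm[sel]
            pred, _ = _lopo_accuracy(feats.X, y_perm, folds, 1.0)
            null.append((pred == y_perm).mean())
        p_oracle = (1 + sum(v >= observed for v in null)) / (len(null) + 1)
        assert res.p_value == pytest.approx(p_oracle)
        assert sorted(res.null) == sorted(null)

    def test_seed_reproducibility(self):
        feats = _noise_features(np.random.default_rng(6), n_sub=5, n_ch=6)
        a = permutation_test(feats, 30, seed=7)
        b = permutation_test(feats, 30, seed=7)
        c = permutation_test(feats, 30, seed=8)
        assert np.array_equal(a.null, b.null) and a.p_value == b.p_value
        assert not np.array_equal(a.null, c.null)

    def test_p_value_granularity(self):
        feats = _noise_features(np.random.default_rng(8), n_sub=5, n_ch=6)
        res = permutation_test(feats, 40, seed=9)
        assert (res.p_value * 41) == pytest.approx(round(res.p_value * 41))


class TestCompareAccuracies:
    def test_independent_identical_problems_give_moderate_p(self):
        feats = _noise_features(np.random.default_rng(10), n_sub=8, n_ch=10)
        a = permutation_test(feats, 100, seed=1)
        b = permutation_test(feats, 100, seed=2)
        res = compare_accuracies(a, b)
        assert res.observed == 0.0
        assert 0.2 <= res.p_value <= 0.9  # symmetric nulls around zero

    def test_degenerate_nulls_flagged_below_resolution(self):
        from babelnirs.mvpa import PermutationResult
        a = PermutationResult(observed=0.7, null=np.full(5, 0.5),
                              n_permutations=5, p_value=1 / 6)
        b = PermutationResult(observed=0.5, null=np.full(5, 0.5),
                              n_permutations=5, p_value=0.5)
        res = compare_accuracies(a, b)
        assert res.p_value == 0.0
        assert res.below_resolution

    def test_toy_nulls_counted_by_hand(self):
        from babelnirs.mvpa import PermutationResult
        a = PermutationResult(0.8, np.array([0.5, 0.6, 0.4, 0.7, 0.5]), 5, 0.2)
        b = PermutationResult(0.6, np.array([0.5, 0.4, 0.6, 0.5, 0.3]), 5, 0.4)
        res = compare_accuracies(a, b)
        # differences: 0.0, 0.2, -0.2, 0.2, 0.2; observed 0.2 -> 3/5 >= obs
        assert res.observed == pytest.approx(0.2)
        assert res.p_value == pytest.approx(3 / 5)

    def test_mismatched_counts_rejected(self):
        from babelnirs.mvpa import PermutationResult
        a = PermutationResult(0.5, np.zeros(5), 5, 1.0)
        b = PermutationResult(0.5, np.zeros(6), 6, 1.0)
        with pytest.raises(ValueError, match="counts"):
            compare_accuracies(a, b)
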