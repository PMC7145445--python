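"""Leave-one-participant-out SVM decoding with permutation inference.

Each participant contributes one HbO2 peak-pattern per condition of a
binary contrast (e.g., spoken vs. signed).  Patterns span a channel subset
(all 46 channels, or the 23 of one hemisphere), are z-scored within each
channel across all contributing patterns, and are classified with a linear
soft-margin support vector machine (C = 1) under leave-one-participant-out
cross-validation: the classifier never sees the held-out participant's two
patterns during training, and the training set stays balanced by
construction.  Inference uses participant-preserving permutations: each
permutation independently keeps or swaps (probability 1/2) every
participant's two condition labels and reruns the full evaluation; the
p value counts the observed accuracy inclusively in both numerator and
denominator, so its floor with 1,000 permutations is 1/1001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.svm import SVC


@dataclass
class FeatureMatrix:
    """Standardized participant x condition pattern vectors.

    ``X`` has one row per pattern (2 per participant), ``y`` the class
    labels, ``participants`` the owning participant of each row.
    ``channel_means``/``channel_sds`` record the z-scoring applied.
    """

    X: np.ndarray  # (n_patterns, n_features)
    y: np.ndarray  # (n_patterns,), label strings
    participants: np.ndarray  # (n_patterns,)
    channels: list[int]
    classes: tuple[str, str]
    channel_means: np.ndarray = field(default=None)
    channel_sds: np.ndarray = field(default=None)

    @property
    def n_participants(self) -> int:
        return len(np.unique(self.participants))


def build_features(
    peaks: pd.DataFrame,
    contrast: tuple[str, str],
    channel_subset: list[int],
    chromophore: str = "hbo2",
    standardize: bool = True,
) -> FeatureMatrix:
    """Assemble and z-score pattern vectors for a binary contrast.

    ``peaks`` is the long peak table; ``contrast`` names two values of its
    ``key`` column (conditions or modalities) in canonical order.  Only
    participants with both class patterns are included.  Channels missing
    for a given participant (QC-rejected) enter as NaN and are imputed at
    the standardized channel mean (0) after z-scoring.
    """
    label_a, label_b = contrast
    sub = peaks[(peaks.chromophore == chromophore)
                & (peaks.key.isin(list(contrast)))]
    wide = sub.pivot_table(
        index=["participant_id", "key"], columns="channel",
        values="peak_amplitude", aggfunc="mean",
    )
    wide = wide.reindex(columns=channel_subset)
    with_both = [
        pid for pid in wide.index.get_level_values(0).unique()
        if {label_a, label_b} <= set(wide.loc[pid].index)
    ]
    rows, y, pids = [], [], []
    for pid in with_both:
        for label in contrast:
            rows.append(wide.loc[(pid, label)].to_numpy(float))
            y.append(label)
            pids.append(pid)
    X = np.asarray(rows, float)
    if X.size == 0:
        raise ValueError("no participant has both class patterns")
    means = sds = None
    if standardize:
        X, means, sds = _zscore_columns(X)
        X = np.nan_to_num(X, nan=0.0)  # missing channels -> channel mean
    return FeatureMatrix(
        X=X, y=np.asarray(y), participants=np.asarray(pids),
        channels=list(channel_subset), classes=(label_a, label_b),
        channel_means=means, channel_sds=sds,
    )


def _zscore_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring ignoring NaN; constant columns map to 0."""
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0, ddof=0)
    safe = np.where(sds > 0, sds, 1.0)
    return (X - means) / safe, means, sds


@dataclass
class ClassificationResult:
    accuracy: float
    outcomes: pd.DataFrame  # participant_id, true, predicted, correct
    n_trials: int
    degenerate: bool = False  # some training fold had identical patterns


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    n_permutations: int
    p_value: float
    seed: int | None = None
    below_resolution: bool = False


def _lopo_folds(X: np.ndarray, participants: np.ndarray,
                unique_pids: np.ndarray) -> list[tuple]:
    """Precomputed (test mask, train mask, degenerate flag) per fold.

    Degeneracy (all training patterns identical) depends only on the
    features, so it is computed once even when many label permutations are
    evaluated on the same matrix.
    """
    folds = []
    for pid in unique_pids:
        test = participants == pid
        train = ~test
        degenerate = bool(np.allclose(X[train].var(axis=0), 0.0))
        folds.append((test, train, degenerate))
    return folds


def _lopo_accuracy(
    X: np.ndarray, y_num: np.ndarray, folds: list[tuple], C: float,
) -> tuple[np.ndarray, bool]:
    """Predictions for every pattern under leave-one-participant-out."""
    pred = np.empty_like(y_num)
    any_degenerate = False
    for test, train, degenerate in folds:
        if degenerate:
            # identical training patterns: deterministic tie -> first class
            pred[test] = 0
            any_degenerate = True
            continue
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[train], y_num[train])
        # manual w.x + b evaluation; strict tie rule: a zero decision value
        # predicts the first class in canonical order
        d = X[test] @ clf.coef_.ravel() + clf.intercept_[0]
        pred[test] = (d > 0).astype(int)
    return pred, any_degenerate


def lopo_classify(features: FeatureMatrix, C: float = 1.0,
                  leakage_free: bool = False) -> ClassificationResult:
    """Leave-one-participant-out linear SVM classification.

    With ``leakage_free=True`` the z-scoring is re-fit on each training
    fold and applied to the held-out patterns (a sensitivity variant);
    the default standardizes across all patterns up front.
    """
    if features.n_participants < 3:
        raise ValueError("need at least 3 participants")
    classes = features.classes
    y_num = np.array([classes.index(label) for label in features.y])
    unique_pids = pd.unique(features.participants)
    with sklearn.config_context(assume_finite=True):
        if leakage_free:
            pred = np.empty_like(y_num)
            degenerate = False
            for pid in unique_pids:
                test = features.participants == pid
                Xtr, mu, sd = _zscore_columns(features.X[~test])
                Xtr = np.nan_to_num(Xtr, nan=0.0)
                Xte = np.nan_to_num(
                    (features.X[test] - mu) / np.where(sd > 0, sd, 1.0), nan=0.0
                )
                if np.allclose(Xtr.var(axis=0), 0.0):
                    pred[test] = 0
                    degenerate = True
                    continue
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xtr, y_num[~test])
                pred[test] = (clf.decision_function(Xte) > 0).astype(int)
        else:
            folds = _lopo_folds(features.X, features.participants, unique_pids)
            pred, degenerate = _lopo_accuracy(features.X, y_num, folds, C)
    correct = pred == y_num
    outcomes = pd.DataFrame({
        "participant_id": features.participants,
        "true": features.y,
        "predicted": [classes[i] for i in pred],
        "correct": correct,
    })
    return ClassificationResult(
        accuracy=float(correct.mean()),
        outcomes=outcomes,
        n_trials=len(correct),
        degenerate=degenerate,
    )


def _swapped_labels(y_num: np.ndarray, pattern_owner: np.ndarray,
                    swap: np.ndarray) -> np.ndarray:
    """Flip both labels of every participant whose swap coin came up."""
    return np.where(swap[pattern_owner], 1 - y_num, y_num)


def permutation_test(
    features: FeatureMatrix,
    n_permutations: int = 1000,
    seed: int | None = 0,
    C: float = 1.0,
    exhaustive: bool = False,
) -> PermutationResult:
    """Participant-preserving label-permutation test of LOPO accuracy.

    Each permutation keeps or swaps every participant's two labels with
    probability 1/2 (i.i.d. fair coins; duplicate permutations allowed),
    then reruns the full leave-one-participant-out evaluation.  The p value
    is inclusive: ``(1 + #{null >= observed}) / (n_permutations + 1)``.
    With ``exhaustive=True`` all ``2^n`` swap patterns are enumerated
    instead (only sensible for small cohorts).
    """
    if n_permutations < 1 and not exhaustive:
        raise ValueError("n_permutations must be >= 1")
    classes = features.classes
    y_num = np.array([classes.index(label) for label in features.y])
    unique_pids = pd.unique(features.participants)
    n_sub = len(unique_pids)
    pid_index = {p: i for i, p in enumerate(unique_pids)}
    pattern_owner = np.array([pid_index[p] for p in features.participants])

    with sklearn.config_context(assume_finite=True):
        folds = _lopo_folds(features.X, features.participants, unique_pids)
        pred, _ = _lopo_accuracy(features.X, y_num, folds, C)
        observed = float((pred == y_num).mean())

        if exhaustive:
            swaps = [
                np.array([(k >> i) & 1 for i in range(n_sub)], dtype=bool)
                for k in range(2 ** n_sub)
            ]
        else:
            rng = np.random.default_rng(seed)
            swaps = list(rng.random((n_permutations, n_sub)) < 0.5)
        null = np.empty(len(swaps))
        for j, swap in enumerate(swaps):
            y_perm = _swapped_labels(y_num, pattern_owner, swap)
            pred_j, _ = _lopo_accuracy(features.X, y_perm, folds, C)
            null[j] = (pred_j == y_perm).mean()

    n_perm = len(swaps)
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        observed=observed, null=null, n_permutations=n_perm,
        p_value=float(p), seed=seed,
    )


def compare_accuracies(result_a: PermutationResult,
                       result_b: PermutationResult) -> PermutationResult:
    """Permutation test of an accuracy difference (a - b).

    The null difference distribution subtracts the two null distributions
    element-wise, paired by permutation index; the p value is the fraction
    of null differences greater than or equal to the observed difference.
    A p of exactly 0 is below the test's resolution (reported as < 1/n and
    flagged).
    """
    if result_a.n_permutations != result_b.n_permutations:
        raise ValueError("permutation counts differ between results")
    observed = result_a.observed - result_b.observed
    null = result_a.null - result_b.null
    # accuracies are k/(2n) rationals; guard the >= count against float dust
    p = float((null >= observed - 1e-9).mean())
    return PermutationResult(
        observed=observed, null=null,
        n_permutations=result_a.n_permutations,
        p_value=p, below_resolution=(p == 0.0),
    )
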