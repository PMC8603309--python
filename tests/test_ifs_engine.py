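import math

import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import matthews_corrcoef

from sublocnet.encoders import FeatureMatrix
from sublocnet.feature_selection import RankedFeatureList
from sublocnet.ifs_engine import (
    ClassifierSpec,
    CVConfig,
    IFSCurve,
    build_subsets,
    evaluate_model,
    labels_to_indicator,
    multiclass_mcc,
    run_ifs,
    select_compact,
    select_optimum,
    smote_oversample,
)
from sublocnet.ifs_engine import _metrics


def binary_mcc(tp, fn, fp, tn) -> float:
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)


def confusion_to_indicators(tp, fn, fp, tn):
    """Build prediction/truth label vectors realizing a 2x2 confusion table."""
    y_true = [1] * (tp + fn) + [0] * (fp + tn)
    y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    X = labels_to_indicator(y_pred, [0, 1])
    Y = labels_to_indicator(y_true, [0, 1])
    return X, Y


class TestBuildSubsets:
    def test_477_subsets_from_4773_features_step_10(self):
        names = [f"f{i}" for i in range(4773)]
        subsets = build_subsets(names, step=10)
        assert len(subsets) == 477
        assert len(subsets[0]) == 10 and len(subsets[-1]) == 4770

    def test_remainder_prefix_dropped(self):
        subsets = build_subsets([f"f{i}" for i in range(25)], step=10)
        assert [len(s) for s in subsets] == [10, 20]

    def test_step_one_gives_every_prefix(self):
        subsets = build_subsets([f"f{i}" for i in range(270)], step=1)
        assert len(subsets) == 270

    def test_prefixes_are_nested(self):
        names = [f"f{i}" for i in range(40)]
        subsets = build_subsets(names, step=10)
        for a, b in zip(subsets, subsets[1:]):
            assert b[: len(a)] == a

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_subsets([], step=10)


class TestSmote:
    def test_counts_equalized_and_originals_intact(self, rng):
        X = rng.normal(size=(13, 4))
        y = np.array(["A"] * 10 + ["B"] * 3)
        X2, y2 = smote_oversample(X, y, k=5, seed=0)
        vals, counts = np.unique(y2, return_counts=True)
        assert dict(zip(vals, counts)) == {"A": 10, "B": 10}
        assert np.array_equal(X2[:13], X)

    def test_already_balanced_unchanged(self, rng):
        X = rng.normal(size=(8, 2))
        y = np.array([0] * 4 + [1] * 4)
        X2, y2 = smote_oversample(X, y, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_synthetics_on_segments_between_originals(self, rng):
        # oracle: coordinate-wise segment membership over all same-class pairs
        X = rng.normal(size=(15, 3))
        y = np.array(["maj"] * 12 + ["min"] * 3)
        X2, y2 = smote_oversample(X, y, k=5, seed=1)
        minors = X[12:]
        for row in X2[15:]:
            on_segment = False
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    d = minors[j] - minors[i]
                    r = row - minors[i]
                    with np.errstate(divide="ignore", invalid="ignore"):
                        u = np.where(d != 0, r / d, np.nan)
                    us = u[~np.isnan(u)]
                    if len(us) and np.allclose(us, us[0]) and 0 <= us[0] <= 1:
                        if np.allclose(minors[i] + us[0] * d, row):
                            on_segment = True
            assert on_segment

    def test_three_member_class_uses_reduced_k(self, rng):
        # the smallest class of the motivating dataset has 3 members
        X = rng.normal(size=(23, 5))
        y = np.array(["big"] * 20 + ["tiny"] * 3)
        X2, y2 = smote_oversample(X, y, k=5, seed=2)
        assert (y2 == "tiny").sum() == 20

    def test_singleton_class_duplicated(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 1])
        X2, y2 = smote_oversample(X, y, seed=3)
        synth = X2[5:]
        assert (y2 == 1).sum() == 4
        assert np.allclose(synth, X[4])


class TestMulticlassMcc:
    def test_perfect_prediction(self):
        Y = labels_to_indicator([0, 1, 2, 0], [0, 1, 2])
        assert multiclass_mcc(Y, Y) == pytest.approx(1.0)

    def test_worked_binary_confusion(self):
        X, Y = confusion_to_indicators(tp=3, fn=1, fp=2, tn=4)
        assert multiclass_mcc(X, Y) == pytest.approx(binary_mcc(3, 1, 2, 4), rel=1e-12)

    def test_constant_predictor_zero_by_contract(self):
        X = labels_to_indicator([0, 0, 0, 0], [0, 1])
        Y = labels_to_indicator([0, 1, 0, 1], [0, 1])
        assert multiclass_mcc(X, Y) == 0.0

    def test_matches_binary_closed_form_on_random_tables(self, rng):
        for _ in range(200):
            tp, fn, fp, tn = rng.integers(0, 20, size=4)
            if tp + fn + fp + tn == 0:
                continue
            X, Y = confusion_to_indicators(int(tp), int(fn), int(fp), int(tn))
            assert multiclass_mcc(X, Y) == pytest.approx(
                binary_mcc(int(tp), int(fn), int(fp), int(tn)), rel=1e-10, abs=1e-12
            )

    def test_matches_sklearn_on_multiclass_labels(self, rng):
        classes = [0, 1, 2, 3]
        for _ in range(20):
            y_true = rng.integers(0, 4, size=60)
            y_pred = rng.integers(0, 4, size=60)
            ours = multiclass_mcc(
                labels_to_indicator(y_pred, classes), labels_to_indicator(y_true, classes)
            )
            assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-10)

    def test_invariant_under_class_column_permutation(self, rng):
        classes = list(range(5))
        y_true = rng.integers(0, 5, size=80)
        y_pred = rng.integers(0, 5, size=80)
        X = labels_to_indicator(y_pred, classes)
        Y = labels_to_indicator(y_true, classes)
        base = multiclass_mcc(X, Y)
        perm = rng.permutation(5)
        assert multiclass_mcc(X[:, perm], Y[:, perm]) == pytest.approx(base)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multiclass_mcc(np.zeros((3, 2)), np.zeros((3, 3)))

    def test_range_bounded(self, rng):
        for _ in range(50):
            y_true = rng.integers(0, 3, size=30)
            y_pred = rng.integers(0, 3, size=30)
            v = multiclass_mcc(
                labels_to_indicator(y_pred, [0, 1, 2]),
                labels_to_indicator(y_true, [0, 1, 2]),
            )
            assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


def _feature_matrix(X, prefix="f"):
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(X.shape[0])],
        feature_names=[f"{prefix}{j}" for j in range(X.shape[1])],
        values=X,
        groups={f"{prefix}{j}": "network" for j in range(X.shape[1])},
    )


class TestEvaluateModel:
    @pytest.mark.parametrize("family", ["rf", "svm", "knn", "dt"])
    def test_separable_blobs_perfect(self, family):
        X, y = make_blobs(
            n_samples=90, centers=3, cluster_std=0.2, center_box=(-20, 20), random_state=0
        )
        mcc, acc, per_class = evaluate_model(
            X, y.astype(str), spec=ClassifierSpec(family=family), cv_config=CVConfig(seed=0)
        )
        assert mcc == pytest.approx(1.0)
        assert acc == pytest.approx(1.0)
        assert all(v == 1.0 for v in per_class.values())

    def test_shuffled_labels_near_zero_mcc(self, rng):
        X = rng.normal(size=(120, 10))
        mccs = []
        for seed in range(3):
            y = rng.permutation(np.array([0, 1, 2] * 40))
            mcc, _, _ = evaluate_model(
                X,
                y,
                spec=ClassifierSpec(family="knn"),
                cv_config=CVConfig(seed=seed, smote="off"),
            )
            mccs.append(abs(mcc))
        assert np.mean(mccs) < 0.15

    def test_per_class_accuracy_definition(self):
        # 6-sample worked confusion table, checked against the definition
        y_true = np.array(["a", "a", "a", "b", "b", "c"])
        y_pred = np.array(["a", "a", "b", "b", "b", "a"])
        _, acc, per_class = _metrics(y_true, y_pred, ["a", "b", "c"])
        assert acc == pytest.approx(4 / 6)
        assert per_class == {"a": pytest.approx(2 / 3), "b": 1.0, "c": 0.0}

    def test_smote_in_train_folds_handles_tiny_class(self, rng):
        X = np.vstack([rng.normal(size=(30, 4)), rng.normal(4.0, 1.0, size=(3, 4))])
        y = np.array(["big"] * 30 + ["tiny"] * 3)
        mcc, acc, per_class = evaluate_model(
            X, y, spec=ClassifierSpec("knn"), cv_config=CVConfig(seed=0)
        )
        assert set(per_class) == {"big", "tiny"}

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 5))
        y = np.array([0, 1, 2] * 20)
        out1 = evaluate_model(X, y, spec=ClassifierSpec("rf", seed=7), cv_config=CVConfig(seed=7))
        out2 = evaluate_model(X, y, spec=ClassifierSpec("rf", seed=7), cv_config=CVConfig(seed=7))
        assert out1 == out2


class TestRunIfs:
    def _planted(self, rng, n=90):
        y = np.array([0, 1, 2] * (n // 3))
        signal = rng.normal(size=(n, 5)) + 3.0 * np.column_stack(
            [(y == c).astype(float) for c in range(3)] + [np.zeros(n), np.zeros(n)]
        )
        noise = rng.normal(size=(n, 25))
        return _feature_matrix(np.hstack([signal, noise])), y

    def test_curve_shape_and_order(self, rng):
        fm, y = self._planted(rng)
        ranked = RankedFeatureList(names=list(fm.feature_names), scores=[0.0] * 30)
        curve = run_ifs(ranked, fm, y, ClassifierSpec("knn"), step=10, cv_config=CVConfig(seed=0))
        assert curve.subset_sizes == [10, 20, 30]
        assert len(curve.mcc) == len(curve.overall_acc) == len(curve.per_class_acc) == 3
        assert all(-1 <= m <= 1 for m in curve.mcc)

    def test_single_point_curve_when_step_is_length(self, rng):
        fm, y = self._planted(rng)
        ranked = RankedFeatureList(names=list(fm.feature_names), scores=[0.0] * 30)
        curve = run_ifs(ranked, fm, y, ClassifierSpec("knn"), step=30, cv_config=CVConfig(seed=0))
        assert curve.subset_sizes == [30]


class TestModelSelection:
    def _curve(self, sizes, mccs):
        return IFSCurve(
            subset_sizes=list(sizes),
            mcc=list(mccs),
            overall_acc=[0.0] * len(mccs),
            per_class_acc=[{} for _ in mccs],
            classifier=ClassifierSpec(),
        )

    def test_optimum_tie_goes_to_smallest(self):
        size, metrics = select_optimum(self._curve([10, 20, 30], [0.2, 0.9, 0.9]))
        assert size == 20 and metrics["mcc"] == 0.9

    def test_optimum_single_point(self):
        assert select_optimum(self._curve([5], [0.4]))[0] == 5

    def test_optimum_strictly_increasing_curve(self):
        assert select_optimum(self._curve([10, 20, 30], [0.1, 0.2, 0.3]))[0] == 30

    def test_compact_first_within_band(self):
        size, _ = select_compact(
            self._curve([10, 20, 30, 40], [0.70, 0.79, 0.82, 0.823]), tolerance=0.03
        )
        assert size == 30

    def test_compact_zero_tolerance_is_optimum(self):
        curve = self._curve([10, 20, 30], [0.5, 0.8, 0.6])
        assert select_compact(curve, 0.0)[0] == select_optimum(curve)[0] == 20

    def test_compact_huge_tolerance_smallest_size(self):
        assert select_compact(self._curve([10, 20], [0.1, 0.9]), tolerance=1.0)[0] == 10
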