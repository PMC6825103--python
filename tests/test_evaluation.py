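"""Cross-validation harness, metrics and robustness sweeps."""

import numpy as np
import pandas as pd
import pytest

import oracles
from eegsex import (
    FeatureMatrix,
    ParamGrid,
    ValidationError,
    compare_groups,
    encode_labels,
    grid_search,
    nested_cv,
    roc_curve_auc,
    stratified_folds,
)
from eegsex.evaluation import (
    SEX_RATIO_CASES,
    accuracy_at_threshold,
    channel_subset_sweep,
    class_ratio_sweep,
    test_fraction_sweep as fraction_sweep,
)


def make_fm(values, labels, subjects=None, channels_per_feature=None, normalized=False):
    values = np.asarray(values, dtype=float)
    names = channels_per_feature or [f"c{j}:FE" for j in range(values.shape[1])]
    n = len(values)
    return FeatureMatrix(
        values=values,
        feature_names=names,
        labels=np.asarray(labels, dtype=object),
        subject_ids=np.asarray(subjects if subjects is not None else [f"s{i}" for i in range(n)],
                               dtype=object),
        normalized=normalized,
    )


def separable_data(n=200, seed=0, d=3):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.standard_normal((n, d)) + 3.0 * y[:, None]
    return X, y


class TestStratifiedFolds:
    def test_exact_stratification_balanced(self):
        labels = np.array([0] * 50 + [1] * 50)
        fold = stratified_folds(labels, 10, seed=0)
        for f in range(10):
            sel = fold == f
            assert sel.sum() == 10
            assert labels[sel].sum() == 5

    def test_partition_covers_all_indices(self):
        labels = np.array([0] * 33 + [1] * 44)
        fold = stratified_folds(labels, 7, seed=3)
        assert np.all(fold >= 0) and fold.max() == 6

    def test_deterministic_given_seed(self):
        labels = np.array([0, 1] * 30)
        np.testing.assert_array_equal(
            stratified_folds(labels, 5, seed=9), stratified_folds(labels, 5, seed=9))

    def test_class_smaller_than_k_rejected(self):
        labels = np.array([0] * 3 + [1] * 50)
        with pytest.raises(ValidationError):
            stratified_folds(labels, 10, seed=0)

    def test_grouped_folds_keep_subjects_together(self):
        labels = np.repeat([0, 1, 0, 1, 0, 1], 10)
        groups = np.repeat([f"s{i}" for i in range(6)], 10)
        fold = stratified_folds(labels, 3, seed=0, groups=groups)
        for g in np.unique(groups):
            assert len(np.unique(fold[groups == g])) == 1


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_curve_auc(scores, labels).auc == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.uniform(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert abs(roc_curve_auc(scores, labels).auc - 0.5) < 0.03

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert roc_curve_auc(scores, labels).auc == pytest.approx(
            oracles.auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self):
        X, y = separable_data(60)
        grid = ParamGrid(forest_nt=[10], forest_md=[2],
                         linear_penalty=["l2"], linear_C=[0.1])
        best, table = grid_search(X, y, grid, kind="LR", k=3, seed=0)
        assert best == {"nt": 10, "md": 2, "penalty": "l2", "C": 0.1}
        assert len(table) == 1

    def test_table_has_one_row_per_cell(self):
        X, y = separable_data(60)
        grid = ParamGrid(forest_nt=[5, 10], forest_md=[1, 2, 3],
                         linear_penalty=["l1", "l2"], linear_C=[0.1, 1.0])
        _, table = grid_search(X, y, grid, kind="LR", k=2, seed=0)
        assert len(table) == 2 * 3 * 2 * 2

    def test_winner_beats_every_cell_on_reevaluation(self):
        X, y = separable_data(120, seed=4)
        grid = ParamGrid(forest_nt=[5], forest_md=[1, 5],
                         linear_penalty=["l1"], linear_C=[1.0])
        best, table = grid_search(X, y, grid, kind="hybrid", k=3, seed=1)
        best_score = table.loc[
            (table.nt == best["nt"]) & (table.md == best["md"])
            & (table.penalty == best["penalty"]) & (table.C == best["C"]),
            "mean_accuracy"].item()
        assert best_score >= table.mean_accuracy.max() - 1e-12

    def test_tie_break_prefers_small_simple_cells(self):
        # constant features: every cell scores identically -> pure tie-break
        X = np.zeros((40, 2))
        X[::2, 0] = 1.0
        y = np.array([0, 1] * 20)
        grid = ParamGrid(forest_nt=[50, 10], forest_md=[4, 2],
                         linear_penalty=["l1", "l2"], linear_C=[0.1, 1.0])
        best, table = grid_search(X, y, grid, kind="LR", k=2, seed=0)
        scores = table.mean_accuracy
        tied = table[scores == scores.max()]
        assert best["nt"] == tied.nt.min()
        if (tied.penalty == "l2").any():
            assert best["penalty"] == "l2"
        assert best["C"] == tied[tied.penalty == best["penalty"]].C.max()


class ConstantClassifier:
    """Stub predicting one constant score for everything."""

    def __init__(self, score=1.0):
        self.score = score

    def fit(self, X, y):
        return self

    def scores(self, X):
        return np.full(len(X), self.score)


class TestNestedCV:
    def test_constant_stub_scores_majority_fraction(self):
        y = np.array([1] * 60 + [0] * 40)
        X = np.random.default_rng(0).standard_normal((100, 2))
        report = nested_cv(
            X, y, "LR", outer_k=10, seed=0,
            classifier_factory=lambda params, seed: ConstantClassifier(1.0))
        # constant score 1.0 -> always predicts positive -> accuracy = P(y=1)
        assert report.mean_accuracy == pytest.approx(0.6)

    def test_outer_test_folds_partition_samples(self):
        X, y = separable_data(100)
        report = nested_cv(X, y, "LR", outer_k=5, seed=2)
        all_idx = np.concatenate([f.test_idx for f in report.folds])
        assert sorted(all_idx.tolist()) == list(range(100))

    def test_inner_loop_never_sees_outer_test_samples(self):
        X, y = separable_data(100)
        grid = ParamGrid(forest_nt=[2, 3], forest_md=[1],
                         linear_penalty=["l2"], linear_C=[1.0])
        report = nested_cv(X, y, "hybrid", grid=grid, outer_k=4, inner_k=2, seed=0)
        for f in report.folds:
            assert len(np.intersect1d(f.inner_pool_idx, f.test_idx)) == 0

    def test_mean_equals_arithmetic_mean_of_folds(self):
        X, y = separable_data(80)
        report = nested_cv(X, y, "LR", outer_k=4, seed=1)
        assert report.mean_accuracy == pytest.approx(
            np.mean([f.accuracy for f in report.folds]))
        assert report.mean_auc == pytest.approx(
            np.mean([f.auc for f in report.folds]))

    def test_reports_are_bit_reproducible(self):
        X, y = separable_data(80, seed=6)
        r1 = nested_cv(X, y, "hybrid", outer_k=4, seed=5)
        r2 = nested_cv(X, y, "hybrid", outer_k=4, seed=5)
        assert [f.accuracy for f in r1.folds] == [f.accuracy for f in r2.folds]
        assert [f.auc for f in r1.folds] == [f.auc for f in r2.folds]

    def test_mean_roc_is_monotone(self):
        X, y = separable_data(100, seed=8)
        roc = nested_cv(X, y, "RF", outer_k=4, seed=3).mean_roc()
        assert (np.diff(roc.tpr) >= -1e-12).all()
        assert roc.tpr.iloc[0] >= 0 and roc.tpr.iloc[-1] == pytest.approx(1.0)


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        vals = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        fm = make_fm(vals, ["male", "male", "male", "female", "female", "female"])
        out = compare_groups(fm)
        assert out.loc["c0:FE", "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["c0:FE", "p"] == pytest.approx(1.0)
        assert not out.loc["c0:FE", "significant"]

    def test_matches_closed_form_welch_on_toy_table(self):
        female = [2.1, 2.9, 2.4]
        male = [1.1, 1.4, 1.2]
        fm = make_fm(np.array(female + male)[:, None],
                     ["female"] * 3 + ["male"] * 3)
        out = compare_groups(fm)
        t_ref, p_ref = oracles.welch_naive(female, male)
        assert out.loc["c0:FE", "t"] == pytest.approx(t_ref, abs=1e-12)
        assert out.loc["c0:FE", "p"] == pytest.approx(p_ref, abs=1e-12)
        assert out.loc["c0:FE", "female_mean"] == pytest.approx(np.mean(female))
        assert out.loc["c0:FE", "male_sd"] == pytest.approx(np.std(male, ddof=1))

    def test_tiny_group_rejected(self):
        fm = make_fm(np.zeros((3, 1)), ["male", "female", "female"])
        with pytest.raises(ValidationError):
            compare_groups(fm)


def labelled_feature_matrix(n_subjects=8, epochs_each=12, n_channels=3,
                            shift=2.0, seed=0):
    """Synthetic per-epoch features with a sex-linked mean shift."""
    rng = np.random.default_rng(seed)
    rows, labels, subjects = [], [], []
    for s in range(n_subjects):
        sex = "female" if s % 2 else "male"
        mu = shift if sex == "female" else 0.0
        rows.append(mu + rng.standard_normal((epochs_each, n_channels)))
        labels += [sex] * epochs_each
        subjects += [f"s{s}"] * epochs_each
    return make_fm(np.vstack(rows), labels, subjects,
                   channels_per_feature=[f"ch{j}:FE" for j in range(n_channels)])


class TestSweeps:
    def test_channel_sweep_row_cardinality(self):
        fm = labelled_feature_matrix()
        out = channel_subset_sweep(fm, m_values=[1, 3], kinds=("LR",),
                                   repeats=2, seed=0)
        assert len(out) == 2
        assert set(out.m) == {1, 3}

    def test_full_channel_set_beats_single_channel(self):
        fm = labelled_feature_matrix(shift=1.0, seed=3)
        out = channel_subset_sweep(fm, m_values=[1, 3], kinds=("LR",),
                                   repeats=4, seed=1)
        acc = out.set_index("m").accuracy
        assert acc[3] >= acc[1] - 0.02

    def test_channel_count_out_of_range_rejected(self):
        fm = labelled_feature_matrix()
        with pytest.raises(ValidationError):
            channel_subset_sweep(fm, m_values=[4], kinds=("LR",), repeats=1)

    def test_fraction_sweep_outputs_bounded_and_reproducible(self):
        fm = labelled_feature_matrix()
        out1 = fraction_sweep(fm, [0.2, 0.5], kinds=("LR",), repeats=3, seed=2)
        out2 = fraction_sweep(fm, [0.2, 0.5], kinds=("LR",), repeats=3, seed=2)
        pd.testing.assert_frame_equal(out1, out2)
        assert ((out1.accuracy >= 0) & (out1.accuracy <= 1)).all()
        assert ((out1.auc >= 0) & (out1.auc <= 1)).all()

    def test_infeasible_fraction_skipped_with_warning(self, caplog):
        fm = labelled_feature_matrix(n_subjects=4, epochs_each=5)
        with caplog.at_level("WARNING"):
            out = fraction_sweep(fm, [0.02, 0.5], kinds=("LR",), repeats=2)
        assert set(out.test_fraction) == {0.5}
        assert any("infeasible" in m for m in caplog.messages)

    def test_ratio_case_list_has_27_entries(self):
        assert len(SEX_RATIO_CASES) == 27
        assert SEX_RATIO_CASES[0] == (13, 1)
        assert SEX_RATIO_CASES[12] == (13, 13)
        assert SEX_RATIO_CASES[-1] == (1, 15)

    def test_ratio_sweep_uses_each_subject_at_most_once(self):
        fm = labelled_feature_matrix(n_subjects=8, epochs_each=10)
        out = class_ratio_sweep(fm, ratios=[(2, 2), (1, 3)], kinds=("LR",),
                                repeats=2, seed=0)
        assert len(out) == 2
        assert list(out.ratio) == ["2:2", "1:3"]

    def test_ratio_sweep_insufficient_subjects_rejected(self):
        fm = labelled_feature_matrix(n_subjects=4)
        with pytest.raises(ValidationError):
            class_ratio_sweep(fm, ratios=[(13, 15)], kinds=("LR",), repeats=1)


def test_encode_labels_positive_is_female():
    y = encode_labels(np.array(["male", "female", "female"], dtype=object))
    np.testing.assert_array_equal(y, [0, 1, 1])


def test_accuracy_threshold_boundary_inclusive():
    scores = np.array([0.5, 0.49, 0.51])
    y = np.array([1, 0, 1])
    assert accuracy_at_threshold(scores, y, 0.5) == 1.0
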