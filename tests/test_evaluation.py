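"""Splitting protocol, Wilcoxon signed-rank test and the method harness."""

from itertools import product

import numpy as np
import pytest
import scipy.stats

from emgpr.coding import enumerate_labels
from emgpr.errors import ConfigurationError
from emgpr.evaluation import (
    EvalConfig,
    compare_methods,
    hidden_unit_sweep,
    make_splits,
    repeated_split_evaluate,
    wilcoxon_signed_rank,
)
from emgpr.features import FeatureMatrix, default_feature_names
from emgpr.pipeline import MethodSpec

from conftest import small_eval_config


def onehot_features(n_per_class=60, n_classes=9, noise=0.0, seed=0):
    """Trivially separable features: class one-hot (+ optional noise)."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n_per_class)
    X = np.eye(n_classes)[y] + noise * rng.standard_normal((y.size, n_classes))
    n_dof = 2 if n_classes == 9 else 3
    # pad to a channels x 4 layout so FeatureMatrix validates
    pad = (-X.shape[1]) % 4
    X = np.hstack([X, np.zeros((X.shape[0], pad))])
    return FeatureMatrix(X, y, default_feature_names(X.shape[1] // 4),
                         enumerate_labels(n_dof))


# -- stratified splits -------------------------------------------------------

def test_splits_are_stratified_and_disjoint():
    fm = onehot_features()
    cfg = EvalConfig(n_repetitions=5, train_windows_per_movement=40,
                     test_windows_per_movement=20, rng_seed=7)
    for train, test in make_splits(fm.class_indices, cfg):
        assert len(np.intersect1d(train, test)) == 0
        for c in range(9):
            assert np.sum(fm.class_indices[train] == c) == 40
            assert np.sum(fm.class_indices[test] == c) == 20


def test_insufficient_windows_rejected():
    fm = onehot_features(n_per_class=50)
    with pytest.raises(ConfigurationError, match="need >="):
        make_splits(fm.class_indices, EvalConfig(
            n_repetitions=1, train_windows_per_movement=40,
            test_windows_per_movement=20))


def test_splits_deterministic_from_seed():
    fm = onehot_features()
    cfg = EvalConfig(n_repetitions=3, train_windows_per_movement=30,
                     test_windows_per_movement=20, rng_seed=5)
    a = make_splits(fm.class_indices, cfg)
    b = make_splits(fm.class_indices, cfg)
    assert all(np.array_equal(x[0], y[0]) and np.array_equal(x[1], y[1])
               for x, y in zip(a, b))


# -- repeated-split evaluation ----------------------------------------------

def test_separable_task_reaches_perfect_accuracy():
    fm = onehot_features(noise=0.01)
    cfg = EvalConfig(n_repetitions=3, train_windows_per_movement=40,
                     test_windows_per_movement=20, rng_seed=1)
    res = repeated_split_evaluate(fm, MethodSpec("lda"), cfg)
    assert res.mean_accuracy == 1.0
    assert res.sd == 0.0
    assert res.confusion.sum() == 3 * 9 * 20
    assert np.array_equal(res.confusion, np.diag(np.diag(res.confusion)))


def test_label_randomized_features_give_chance_accuracy():
    rng = np.random.default_rng(3)
    fm = onehot_features(noise=0.01)
    fm.class_indices = rng.permutation(fm.class_indices)
    cfg = EvalConfig(n_repetitions=5, train_windows_per_movement=40,
                     test_windows_per_movement=20, rng_seed=1)
    res = repeated_split_evaluate(fm, MethodSpec("lda"), cfg)
    n_total = 5 * 9 * 20
    p = 1 / 9
    se = np.sqrt(p * (1 - p) / n_total)
    assert abs(res.mean_accuracy - p) < 3 * se + 0.02


def test_evaluation_deterministic_from_seed(small_features):
    cfg = small_eval_config(n_repetitions=2)
    spec = MethodSpec("glm-scg", "single")
    a = repeated_split_evaluate(small_features, spec, cfg)
    b = repeated_split_evaluate(small_features, spec, cfg)
    assert np.array_equal(a.accuracies, b.accuracies)


# -- Wilcoxon signed-rank ----------------------------------------------------

def wilcoxon_brute_force(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2 * min(p_le, p_ge))


def test_identical_vectors_give_p_one():
    res = wilcoxon_signed_rank([1.0, 2, 3], [1.0, 2, 3])
    assert res.p_value == 1.0 and res.no_evidence


def test_six_positive_distinct_differences():
    a = np.array([1.0, 2, 3, 4, 5, 6])
    res = wilcoxon_signed_rank(a + np.arange(1, 7) * 0.1, a)
    assert res.p_value == pytest.approx(2 / 64)
    assert res.direction == 1
    assert res.significant  # 0.03125 < 0.05


@pytest.mark.parametrize("n", range(5, 13))
def test_exact_path_matches_enumeration(n):
    rng = np.random.default_rng(n)
    for trial in range(5):
        d = np.round(rng.standard_normal(n), 1)  # rounding induces ties
        if np.all(d == 0):
            continue
        got = wilcoxon_signed_rank(d, np.zeros(n)).p_value
        assert got == pytest.approx(wilcoxon_brute_force(d), abs=1e-12)


def test_exact_path_matches_scipy_without_ties():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        got = wilcoxon_signed_rank(a, b).p_value
        ref = scipy.stats.wilcoxon(a, b, mode="exact").pvalue
        assert got == pytest.approx(ref, rel=1e-10)


def test_large_sample_normal_approximation_close_to_scipy():
    rng = np.random.default_rng(1)
    a = rng.standard_normal(60) + 0.3
    b = rng.standard_normal(60)
    got = wilcoxon_signed_rank(a, b).p_value
    ref = scipy.stats.wilcoxon(a, b, mode="approx", correction=True).pvalue
    assert got == pytest.approx(ref, rel=1e-6)


# -- method comparison and sweep --------------------------------------------

def test_single_method_table_has_no_pvalues():
    fm = onehot_features(noise=0.05)
    cfg = EvalConfig(n_repetitions=2, train_windows_per_movement=40,
                     test_windows_per_movement=20, rng_seed=0)
    table, pairwise = compare_methods(fm, [MethodSpec("lda")], cfg)
    assert len(table) == 1 and pairwise == {}
    assert {"method", "output_type", "acc", "sd", "train_seconds"} <= set(table.columns)


def test_sweep_selects_smallest_hu_when_accuracy_flat():
    fm = onehot_features(noise=0.05)
    cfg = EvalConfig(n_repetitions=5, train_windows_per_movement=40,
                     test_windows_per_movement=20, rng_seed=2)
    res = hidden_unit_sweep(fm, "single", hidden_range=[2, 4, 8],
                            nets_per_hu=5, config=cfg)
    assert res.accuracies.shape == (3, 5)
    assert res.selected == 2  # trivially separable: no size is worse
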