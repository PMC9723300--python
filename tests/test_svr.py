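"""Nested cross-validation machinery: folds, metrics, grid search vs a
brute-force oracle, leakage audit, and repetition averaging."""

import numpy as np
import pytest
from sklearn.svm import SVR

from neglectwmh import (
    CvConfig,
    RandomStream,
    inner_cv_select,
    make_folds,
    mae,
    nested_cv_predict,
    r_squared,
    run_repetitions,
)
from neglectwmh.streams import CV
from neglectwmh.svr import CvError


class TestFolds:
    def test_fold_sizes_103_by_10(self, rng):
        folds = make_folds(103, 10, rng)
        sizes = sorted(np.bincount(folds))
        assert sizes == [10] * 7 + [11] * 3

    def test_n_equals_k_singleton_folds(self, rng):
        folds = make_folds(5, 5, rng)
        assert sorted(np.bincount(folds)) == [1] * 5

    def test_same_stream_identical_folds(self):
        s = RandomStream(3)
        f1 = make_folds(50, 10, s.substream(CV, 0, 0))
        f2 = make_folds(50, 10, s.substream(CV, 0, 0))
        assert np.array_equal(f1, f2)

    def test_too_few_rows(self, rng):
        with pytest.raises(CvError):
            make_folds(3, 5, rng)


class TestMetrics:
    def test_mae_hand_values(self):
        assert mae([1, 2], [1, 2]) == 0
        assert mae(np.arange(4) + 0.5, np.arange(4)) == pytest.approx(0.5)
        assert mae([0, 1], [1, 0]) == pytest.approx(1.0)

    def test_r_squared_hand_values(self):
        y = np.array([0.0, 1.0, 2.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(np.full(3, y.mean()), y) == pytest.approx(0.0)
        assert r_squared(np.array([0.0, 1.0, 1.0]), y) == pytest.approx(0.5)

    def test_r_squared_constant_truth_rejected(self):
        with pytest.raises(CvError):
            r_squared([1.0, 2.0], [3.0, 3.0])


def brute_force_grid_search(X, y, config, rng):
    """Independent enumeration of the inner-CV grid search."""
    folds = make_folds(len(y), config.inner_k, rng)
    results = {}
    for C in config.C_grid:
        for gamma in config.gamma_grid:
            errs = []
            for j in range(config.inner_k):
                tr, va = folds != j, folds == j
                m = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=config.epsilon)
                m.fit(X[tr], y[tr])
                errs.append(np.abs(m.predict(X[va]) - y[va]).mean())
            results[(float(C), float(gamma))] = float(np.mean(errs))
    best_mae = min(results.values())
    candidates = [k for k, v in results.items() if v <= best_mae + 1e-15]
    return sorted(candidates)[0]  # smallest C, then smallest gamma


class TestInnerSelect:
    def test_matches_brute_force_oracle(self, rng):
        X = rng.random((20, 5))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        config = CvConfig(
            C_grid=[0.5, 4.0, 32.0], gamma_grid=[0.03125, 0.25, 2.0], n_repetitions=1
        )
        s = RandomStream(5)
        got = inner_cv_select(X, y, config, s.substream(CV, 0, 1))
        want = brute_force_grid_search(X, y, config, s.substream(CV, 0, 1))
        assert got == want

    def test_single_pair_grid(self, rng):
        config = CvConfig(C_grid=[1.0], gamma_grid=[0.5])
        X, y = rng.random((12, 3)), rng.random(12)
        assert inner_cv_select(X, y, config, rng) == (1.0, 0.5)

    def test_constant_targets_grid_minimum(self, rng):
        config = CvConfig(C_grid=[0.25, 4.0], gamma_grid=[0.125, 1.0])
        assert inner_cv_select(rng.random((10, 2)), np.ones(10), config, rng) == (0.25, 0.125)


class TestNestedCv:
    def test_leakage_audit_and_coverage(self, rng):
        X = rng.random((40, 6))
        y = rng.random(40)
        config = CvConfig(C_grid=[1.0], gamma_grid=[0.5], n_repetitions=2)
        s = RandomStream(7)
        preds, chosen, folds = nested_cv_predict(X, y, config, s, repetition=0)
        assert len(preds) == 40 and len(chosen) == config.outer_k
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1
        for j in range(config.outer_k):
            assert not (set(np.flatnonzero(folds == j)) & set(np.flatnonzero(folds != j)))

    def test_noise_targets_low_r2(self):
        r2s = []
        config = CvConfig.reduced(n_repetitions=2)
        for seed in range(10):
            g = np.random.default_rng(seed)
            X = g.random((60, 8))
            y = g.random(60)
            fit = run_repetitions(X, y, config, RandomStream(seed))
            r2s.append(fit.r2_averaged)
        assert np.mean(r2s) <= 0.1

    def test_strong_signal_high_r2(self):
        g = np.random.default_rng(0)
        X = g.random((60, 5))
        y = 2 * X[:, 0] + 0.05 * g.normal(size=60)
        fit = run_repetitions(X, y, CvConfig.reduced(n_repetitions=2), RandomStream(1))
        assert fit.r2_averaged >= 0.5


class TestRepetitions:
    def test_single_repetition_average_identity(self, rng):
        X, y = rng.random((30, 4)), rng.random(30)
        fit = run_repetitions(X, y, CvConfig(C_grid=[1.0], gamma_grid=[0.5], n_repetitions=1),
                              RandomStream(2))
        assert np.array_equal(fit.averaged_predictions, fit.predictions[0])

    def test_fold_assignments_identical_across_model_versions(self, rng):
        y = rng.random(30)
        config = CvConfig(C_grid=[1.0], gamma_grid=[0.5], n_repetitions=3)
        fit_a = run_repetitions(rng.random((30, 4)), y, config, RandomStream(9))
        fit_b = run_repetitions(rng.random((30, 7)), y, config, RandomStream(9))
        assert np.array_equal(fit_a.fold_assignments, fit_b.fold_assignments)

    def test_full_rerun_bit_identical(self, rng):
        X, y = rng.random((25, 3)), rng.random(25)
        config = CvConfig(C_grid=[0.5, 2.0], gamma_grid=[0.25, 1.0], n_repetitions=2)
        f1 = run_repetitions(X, y, config, RandomStream(4))
        f2 = run_repetitions(X, y, config, RandomStream(4))
        assert np.array_equal(f1.predictions, f2.predictions)
        assert f1.chosen_params == f2.chosen_params

    def test_averaged_prediction_is_mean_over_repetitions(self, rng):
        X, y = rng.random((24, 3)), rng.random(24)
        fit = run_repetitions(X, y, CvConfig(C_grid=[1.0], gamma_grid=[0.5], n_repetitions=4),
                              RandomStream(6))
        assert np.allclose(fit.averaged_predictions, fit.predictions.mean(axis=0))
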