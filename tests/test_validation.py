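import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mbopls as m
from mbopls.validation import FoldKernelCache


class TestDq2:
    def test_truncation_of_both_overshooting_residuals_gives_one(self):
        assert m.dq2(np.array([0.0, 1.0]), np.array([-0.2, 1.3])) == 1.0

    def test_uninformative_midpoint_predictions_give_zero(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert m.dq2(y, np.full(4, 0.5)) == pytest.approx(0.0)

    def test_perfect_predictions_give_one(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert m.dq2(y, y) == 1.0

    def test_one_sided_truncation_hand_example(self):
        # residual kept for the class-0 sample (0.4), truncated for class 1
        y = np.array([0.0, 1.0])
        yhat = np.array([0.4, 1.2])
        assert m.dq2(y, yhat) == pytest.approx(1 - 0.4**2 / 0.5)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            m.dq2(np.ones(4), np.ones(4))

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_never_below_untruncated_q2(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        y = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n - n // 2)])
        if y.min() == y.max():
            return
        yhat = rng.normal(0.5, 1.0, n)
        q2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        d = m.dq2(y, yhat)
        assert q2 <= d <= 1.0


class TestPredictionAccuracy:
    def test_exact_midpoint_counts_as_incorrect_for_both_classes(self):
        y = np.array([0.0, 1.0])
        assert m.prediction_accuracy(y, np.array([0.5, 0.5])) == 0.0

    def test_all_correct(self):
        y = np.array([0.0, 1.0, 0.0])
        assert m.prediction_accuracy(y, np.array([0.2, 0.8, 0.49])) == 100.0


class TestLoocv:
    def test_separable_data_reaches_full_accuracy(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0.0, 1.0], 8)
        X = rng.normal(scale=0.3, size=(16, 8)) + np.outer(y, np.ones(8) * 4)
        rep = m.loocv([X], y, max_n_orthogonal=1)
        assert rep.pa_percent == 100.0
        assert rep.dq2_by_size[rep.chosen_n_orthogonal] > 0.8

    def test_null_data_accuracy_near_majority_rate(self):
        # Monte-Carlo over 60 seeds: permuted labels on pure noise give PA
        # scattered around the 50% majority rate
        pas = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 10))
            y = rng.permutation(np.repeat([0.0, 1.0], 10))
            pas.append(m.loocv([X], y, max_n_orthogonal=1).pa_percent)
        assert 40.0 < np.mean(pas) < 60.0

    def test_chosen_size_is_first_dq2_maximum(self, screen, indicators):
        rep = m.loocv(screen["raw_arrays"], indicators["KNO3"].to_numpy(),
                      max_n_orthogonal=2, cache=screen["cache"])
        chosen = rep.chosen_n_orthogonal
        best = max(rep.dq2_by_size.values())
        assert rep.dq2_by_size[chosen] == best
        assert all(rep.dq2_by_size[a] < best for a in rep.dq2_by_size
                   if a < chosen)

    def test_imbalanced_tiny_class_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        y = np.r_[np.zeros(9), np.ones(1)]
        with pytest.raises(ValueError, match="per class"):
            m.loocv([X], y)

    def test_fold_scaling_refit_prevents_leakage(self):
        # the cache must Pareto-scale each training fold independently:
        # inflating the held-out sample must not change the fold's kernels
        rng = np.random.default_rng(2)
        X = rng.lognormal(size=(12, 5))
        X2 = X.copy()
        X2[0] *= 100.0
        c1 = FoldKernelCache([X], scale=True)
        c2 = FoldKernelCache([X2], scale=True)
        K1 = c1.folds[0][0][0][0]
        K2 = c2.folds[0][0][0][0]
        assert K1 == pytest.approx(K2)


class TestPermutationTest:
    def test_batch_path_identical_to_per_column_path(self, screen, indicators):
        cache = screen["cache"]
        y = indicators["NH4NO3"].to_numpy()
        rng = np.random.default_rng(5)
        perms = np.column_stack([rng.permutation(y) for _ in range(6)])
        loop = np.column_stack(
            [cache.loocv_pass(perms[:, b], 2) for b in range(6)]
        )
        batch = cache.loocv_pass_batch(perms, 2)
        assert batch == pytest.approx(loop, abs=1e-10)

    def test_add_one_p_value_formula_edge_cases(self):
        # n_perm=1: a null PA at least as good as observed gives (1+1)/(1+1)=1
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        y = np.repeat([0.0, 1.0], 6)
        rep = m.permutation_test([X], y, n_perm=1, seed=0, max_n_orthogonal=0)
        expected = (1 + np.sum(rep.null_pa >= rep.pa_percent)) / 2
        assert rep.p_value == pytest.approx(expected)

    def test_strong_effect_beats_every_permutation(self, screen, indicators):
        rep = m.permutation_test(
            screen["raw_arrays"], indicators["KNO3"].to_numpy(),
            n_perm=99, seed=1, max_n_orthogonal=2, cache=screen["cache"],
        )
        assert rep.pa_percent >= 95.0
        assert (rep.null_pa < rep.pa_percent).all()
        assert rep.p_value == pytest.approx(1.0 / 100.0)

    def test_null_factor_not_significant(self, screen, indicators):
        rep = m.permutation_test(
            screen["raw_arrays"], indicators["MgSO4"].to_numpy(),
            n_perm=99, seed=1, max_n_orthogonal=2, cache=screen["cache"],
        )
        assert rep.p_value > 0.05
        # accuracy must not sit meaningfully above the majority baseline
        # (LOOCV on null data is, if anything, biased below it)
        assert rep.pa_percent <= rep.majority_baseline_percent + 10

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(14, 6))
        y = np.repeat([0.0, 1.0], 7)
        r1 = m.permutation_test([X], y, n_perm=20, seed=9, max_n_orthogonal=0)
        r2 = m.permutation_test([X], y, n_perm=20, seed=9, max_n_orthogonal=0)
        assert r1.null_pa == pytest.approx(r2.null_pa)
        assert r1.p_value == r2.p_value

    def test_hormone_indicator_reports_majority_baseline(self, indicators):
        y = indicators["IAA"].to_numpy()
        rng = np.random.default_rng(6)
        X = rng.normal(size=(96, 10))
        rep = m.loocv([X], y, max_n_orthogonal=0)
        assert rep.majority_baseline_percent == pytest.approx(75.0)
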