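"""Softmax classification of blinking statistics: normalisation, fitting,
probability thresholding, and cross-validated evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression

from blinkmux.classifier import (
    BlinkClassifier,
    cross_validate,
    find_threshold,
    fit_mlr,
    threshold_curve,
    zscore_fit_apply,
)
from blinkmux.synth import simulate_stat_vectors


def two_class_stats(shift_sd, n=150, seed=0):
    mu_b = np.zeros(10)
    mu_b[0] = shift_sd
    return simulate_stat_vectors(
        {"A": np.zeros(10), "B": mu_b},
        {"A": np.ones(10), "B": np.ones(10)},
        n,
        rng_seed=seed,
    )


class TestZScore:
    def test_self_normalisation(self, rng):
        X = rng.normal(5, 3, size=(50, 4))
        Z, Zt, rec = zscore_fit_apply(X, X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-12)
        assert np.allclose(Z, Zt)

    def test_constant_column_dropped_with_record(self, rng):
        X = pd.DataFrame(
            {"a": rng.normal(size=30), "b": np.full(30, 7.0), "c": rng.normal(size=30)}
        )
        Z, _, rec = zscore_fit_apply(X)
        assert Z.shape[1] == 2
        assert rec.dropped == ("b",)

    def test_shifted_test_set(self, rng):
        X = rng.normal(0, 2, size=(500, 3))
        shift = X.std(axis=0)
        _, Zt, _ = zscore_fit_apply(X, X + shift)
        assert np.allclose(Zt.mean(axis=0), 1.0, atol=0.01)


class TestFitMLR:
    def test_no_signal_gives_null_coefficients(self):
        X, y = two_class_stats(0.0, n=300, seed=1)
        model = fit_mlr(X, y)
        assert np.all(np.abs(model.coef_) < 0.25)

    def test_1d_boundary_and_sign(self, rng):
        x = np.concatenate([rng.normal(3, 1, 500), rng.normal(-3, 1, 500)])[:, None]
        y = np.array(["plus"] * 500 + ["minus"] * 500)
        model = fit_mlr(x, y)
        # classes sorted: ['minus', 'plus']; pivot = 'plus', so the 'minus'
        # coefficient is negative in x
        assert model.classes_.tolist() == ["minus", "plus"]
        assert model.coef_[0, 0] < 0
        # P('plus') crosses 0.5 near the raw midpoint 0
        grid = np.linspace(-2, 2, 2001)[:, None]
        p_plus = model.predict_proba(grid)[:, 1]
        boundary = grid[np.argmin(np.abs(p_plus - 0.5)), 0]
        assert abs(boundary) < 0.5

    def test_matches_sklearn_on_binary_problem(self):
        X, y = two_class_stats(1.5, n=200, seed=2)
        ridge = 1e-2
        ours = BlinkClassifier(ridge=ridge, normalize=False).fit(X, y)
        ref = LogisticRegression(C=1.0 / ridge, tol=1e-10, max_iter=5000).fit(
            X.to_numpy(), y
        )
        p_ours = ours.predict_proba(X)
        p_ref = ref.predict_proba(X.to_numpy())
        assert np.allclose(p_ours, p_ref, atol=1e-3)

    def test_single_class_rejected(self):
        X, y = two_class_stats(0.0, n=20, seed=0)
        with pytest.raises(ValueError):
            fit_mlr(X[y == "A"], y[y == "A"])

    def test_separable_problem_stays_finite(self, rng):
        x = np.concatenate([rng.normal(10, 0.1, 50), rng.normal(-10, 0.1, 50)])[:, None]
        y = np.array(["A"] * 50 + ["B"] * 50)
        model = fit_mlr(x, y)
        assert np.all(np.isfinite(model.coef_))


class TestPredictProba:
    def test_zero_coefficients_give_uniform(self):
        m = BlinkClassifier.from_coefficients(["A", "B"], np.zeros((1, 10)), [0.0])
        p = m.predict_proba(np.zeros((3, 10)))
        assert np.allclose(p, 0.5)

    def test_fitted_binary_discriminant_at_origin(self):
        # published binary discriminant: coefficient magnitudes per statistic
        # (I_min -2.7, N_off_seg -0.8, <I>_t -0.7, N_on_seg +0.6,
        #  <t_on,int> +0.4, I_max +0.4, N_I -0.4, <t_on,seg> -0.3,
        #  <t_off,int> +0.2, <t_off,seg> -0.2) and intercept -1.3; at the
        # z-score origin the score is the intercept, so
        # P = 1 / (1 + e^{1.3}) ~ 0.214
        coef = [[-0.4, -2.7, 0.4, -0.7, -0.3, -0.2, 0.4, 0.2, 0.6, -0.8]]
        m = BlinkClassifier.from_coefficients(["5ROX", "R6G"], coef, [-1.3])
        scores = m.decision_scores(np.zeros((1, 10)))
        assert scores[0, 0] == pytest.approx(-1.3)
        p = m.predict_proba(np.zeros((1, 10)))[0, 0]
        assert p == pytest.approx(1.0 / (1.0 + np.exp(1.3)), abs=1e-6)
        assert p == pytest.approx(0.214, abs=0.001)

    def test_probabilities_sum_to_one_three_class(self, rng):
        m = BlinkClassifier.from_coefficients(
            ["A", "B", "C"], rng.normal(size=(2, 10)), rng.normal(size=2)
        )
        p = m.predict_proba(rng.normal(size=(20, 10)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_pivot_choice_invariance(self):
        # relabelling classes permutes the pivot; predicted probabilities of
        # corresponding classes must agree
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(i, 1, size=(60, 3)) for i in range(3)]
        )
        y1 = np.repeat(["a", "b", "c"], 60)  # pivot = 'c'
        y2 = np.repeat(["c", "b", "a"], 60)  # pivot = 'c' is now the first group
        m1 = BlinkClassifier(ridge=1e-3).fit(X, y1)
        m2 = BlinkClassifier(ridge=1e-3).fit(X, y2)
        p1 = m1.predict_proba(X)  # columns a, b, c
        p2 = m2.predict_proba(X)  # columns a, b, c (sorted classes)
        assert np.allclose(p1[:, 1], p2[:, 1], atol=1e-4)  # class 'b'
        assert np.allclose(p1[:, 0], p2[:, 2], atol=1e-4)  # group 0 vs label

    def test_dimension_mismatch(self):
        m = BlinkClassifier.from_coefficients(["A", "B"], np.zeros((1, 10)), [0.0])
        with pytest.raises(ValueError):
            m.predict_proba(np.zeros((2, 7)))


class TestCrossValidate:
    def test_null_problem_near_chance(self):
        accs = []
        for seed in range(3):
            X, y = two_class_stats(0.0, n=150, seed=seed)
            accs.append(cross_validate(X, y, folds=10, rng_seed=seed).accuracy)
        assert abs(np.median(accs) - 0.5) < 0.06

    def test_three_sd_separation_near_bayes_accuracy(self):
        # Bayes accuracy for equal Normals 3 sd apart is Phi(1.5) ~ 0.933
        X, y = two_class_stats(3.0, n=300, seed=3)
        rep = cross_validate(X, y, folds=10, rng_seed=3)
        assert rep.accuracy > 0.88
        assert abs(rep.accuracy - norm.cdf(1.5)) < 0.05
        assert rep.tpr is not None and rep.fpr is not None
        assert rep.min_class_accuracy <= rep.accuracy + 1e-12

    def test_permuted_labels_near_chance(self, rng):
        X, y = two_class_stats(3.0, n=150, seed=4)
        y_perm = rng.permutation(y)
        rep = cross_validate(X, y_perm, folds=10, rng_seed=4)
        assert abs(rep.accuracy - 0.5) < 0.1

    def test_small_class_warns_and_flags(self):
        X, y = two_class_stats(1.0, n=9, seed=5)
        with pytest.warns(UserWarning, match="n <= 10"):
            rep = cross_validate(X, y, folds=3, rng_seed=5)
        assert rep.small_sample

    def test_class_smaller_than_folds_rejected(self):
        X, y = two_class_stats(1.0, n=5, seed=6)
        with pytest.raises(ValueError, match="at least"):
            cross_validate(X, y, folds=10)

    def test_confusion_rows_sum_to_class_counts(self):
        X, y = two_class_stats(2.0, n=80, seed=7)
        rep = cross_validate(X, y, folds=10, rng_seed=7)
        assert rep.confusion.loc["A"].sum() == 80
        assert rep.confusion.loc["B"].sum() == 80

    def test_no_leakage_between_folds(self, monkeypatch):
        # mark every row by a unique value in one feature and record which
        # rows each fold's fit and scoring see: they must never overlap
        X, y = two_class_stats(1.0, n=50, seed=8)
        X = X.copy()
        X["N_I"] = np.arange(len(X), dtype=float)  # unique row marker
        seen = []
        orig_fit = BlinkClassifier.fit
        orig_proba = BlinkClassifier.predict_proba

        def spy_fit(self, Xf, yf):
            self._train_marks = set(np.asarray(Xf)[:, 0].tolist())
            return orig_fit(self, Xf, yf)

        def spy_proba(self, Xt):
            Xt_arr = np.asarray(Xt, dtype=float)
            if hasattr(self, "_train_marks") and Xt_arr.ndim == 2:
                seen.append((self._train_marks, set(Xt_arr[:, 0].tolist())))
            return orig_proba(self, Xt)

        monkeypatch.setattr(BlinkClassifier, "fit", spy_fit)
        monkeypatch.setattr(BlinkClassifier, "predict_proba", spy_proba)
        cross_validate(X, y, folds=5, rng_seed=8)
        assert len(seen) >= 5
        for train_marks, test_marks in seen:
            assert not (train_marks & test_marks)

    def test_separation_sweep_monotone(self):
        # BBM improves as blinking statistics grow more distinct
        shifts = [0.0, 1.0, 2.0, 3.0, 4.0]
        med = []
        for shift in shifts:
            accs = [
                cross_validate(*two_class_stats(shift, n=150, seed=s), folds=10,
                               rng_seed=s).accuracy
                for s in range(5)
            ]
            med.append(np.median(accs))
        assert np.all(np.diff(med) > -0.015)
        assert med[0] < 0.58 and med[-1] > 0.95


class TestThresholding:
    def test_binary_half_threshold_retains_all(self):
        P = np.column_stack([np.linspace(0.01, 0.99, 50)] * 1)
        P = np.column_stack([P, 1 - P])
        y = np.where(P[:, 0] > 0.5, "A", "B")
        curve = threshold_curve(P, y, [0.5])
        assert curve["retention"].iloc[0] == 1.0

    def test_retention_non_increasing(self):
        X, y = two_class_stats(1.0, n=150, seed=9)
        rep = cross_validate(X, y, folds=10, rng_seed=9)
        assert np.all(np.diff(rep.threshold_curve["retention"]) <= 1e-12)

    def test_high_confidence_subset_more_accurate(self):
        diffs = []
        for seed in range(10):
            X, y = two_class_stats(1.5, n=150, seed=seed)
            rep = cross_validate(X, y, folds=10, rng_seed=seed)
            curve = threshold_curve(rep.probabilities, rep.labels, [0.5, 0.9])
            diffs.append(curve["accuracy"].iloc[1] - curve["accuracy"].iloc[0])
        assert np.median(diffs) >= 0.0

    def test_per_class_retention_columns(self):
        X, y = two_class_stats(1.0, n=60, seed=10)
        rep = cross_validate(X, y, folds=10, rng_seed=10)
        assert {"retention_A", "retention_B"} <= set(rep.threshold_curve.columns)

    def test_empty_retained_set_flagged(self):
        P = np.full((10, 2), 0.5)
        y = np.array(["A", "B"] * 5)
        curve = threshold_curve(P, y, [0.99])
        assert not curve["accuracy_defined"].iloc[0]
        assert np.isnan(curve["accuracy"].iloc[0])

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            threshold_curve(np.full((5, 2), 0.4), np.array(["A"] * 5), [0.5])


class TestFindThreshold:
    def test_unreachable_target_returns_none(self):
        X, y = two_class_stats(0.0, n=100, seed=11)
        rep = cross_validate(X, y, folds=10, rng_seed=11)
        assert find_threshold(rep.threshold_curve, 0.999) is None

    def test_perfect_separation_minimal_threshold(self):
        X, y = two_class_stats(20.0, n=60, seed=12)
        rep = cross_validate(X, y, folds=10, rng_seed=12)
        res = find_threshold(rep.threshold_curve, 0.95)
        assert res.threshold == pytest.approx(0.5)
        assert res.retention == 1.0

    def test_returned_threshold_is_minimal(self):
        X, y = two_class_stats(2.0, n=200, seed=13)
        rep = cross_validate(X, y, folds=10, rng_seed=13)
        target = 0.93
        res = find_threshold(rep.threshold_curve, target)
        if res is not None:
            curve = rep.threshold_curve
            below = curve[curve["threshold"] < res.threshold]
            assert np.all(below["accuracy"] < target)
            assert res.accuracy >= target
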