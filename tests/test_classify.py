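"""LS-SVM and binary logistic regression: fitting, evaluation, tuning."""

import numpy as np
import pytest
import statsmodels.api as sm

from skinspeckle import (
    BinaryLogisticRegression,
    LSSVMClassifier,
    PatchSimParams,
    color_features,
    fit_blr,
    fit_lssvm,
    generate_dataset,
    split_evaluate,
    tune_lssvm,
)


def _color_dataset(con: float, seed: int, n_per_class: int = 20):
    samples = generate_dataset(
        n_per_class, "rgb", params=PatchSimParams(con=con), seed=seed
    )
    X = np.array([color_features(s.data).values for s in samples])
    y = np.array([s.label for s in samples])
    return X, y


class TestLSSVM:
    def test_separable_one_dimensional_classes(self):
        X = np.array([[-5.0], [-4.0], [4.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_lssvm(X, y, gamma=1.0, sigma=1.0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_kkt_residual_bound_on_random_fits(self, rng):
        """The returned dual solution satisfies its defining linear system."""
        for _ in range(5):
            X = rng.normal(size=(30, 4))
            y = (X[:, 0] + 0.3 * rng.normal(size=30) > 0).astype(int)
            if len(np.unique(y)) < 2:
                continue
            model = fit_lssvm(X, y, gamma=5.0, sigma=1.5)
            assert model.kkt_residual_ < 1e-8

    def test_rbf_kernel_resolves_xor(self, rng):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]] * 5, dtype=float)
        X += rng.normal(0, 0.05, X.shape)
        y = np.array([0, 0, 1, 1] * 5)
        model = LSSVMClassifier(gamma=100.0, sigma=0.5).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_rejects_single_class_and_bad_hyperparameters(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            LSSVMClassifier().fit(X, np.zeros(4))
        with pytest.raises(ValueError):
            LSSVMClassifier(gamma=-1.0).fit(X, np.array([0, 0, 1, 1]))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = LSSVMClassifier(gamma=3.0, sigma=0.7)
        assert clone(est).get_params() == est.get_params()


class TestBLR:
    def test_symmetric_data_boundary_at_midpoint(self):
        """Symmetric classes around m: fitted 0.5-probability point near m."""
        m = 4.0
        x = np.concatenate([m - np.array([3.0, 2.0, 1.0]), m + np.array([1.0, 2.0, 3.0])])
        y = np.array([0, 0, 0, 1, 1, 1])
        # jitter the pattern to avoid complete separation
        x = np.concatenate([x, [m + 0.5, m - 0.5]])
        y = np.concatenate([y, [0, 1]])
        model = fit_blr(x[:, None], y)
        boundary = -model.intercept_ / model.coef_[0]
        assert boundary == pytest.approx(m, abs=0.2)

    def test_complete_separation_flagged_and_still_perfect(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])[:, None]
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_blr(x, y)
        assert model.separated_
        assert np.mean(model.predict(x) == y) == 1.0

    def test_loglikelihood_monotone_nondecreasing(self, rng):
        x = rng.normal(size=(200, 2))
        y = (x @ [1.0, -0.5] + rng.normal(size=200) > 0).astype(int)
        model = fit_blr(x, y)
        assert np.all(np.diff(model.loglik_path_) >= -1e-12)

    def test_parameter_recovery_within_3_se(self):
        """n=500 logistic-simulated data, true intercept -2 and slope 0.8."""
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 2.0, 500)
        eta = -2.0 + 0.8 * x
        y = (rng.random(500) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        model = fit_blr(x[:, None], y)
        assert model.converged_
        assert abs(model.intercept_ - (-2.0)) <= 3 * model.bse_[0]
        assert abs(model.coef_[0] - 0.8) <= 3 * model.bse_[1]

    def test_matches_statsmodels_mle(self):
        """Independent oracle: same MLE and standard errors as statsmodels."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1.0 / (1.0 + np.exp(-(0.5 + 1.2 * x)))).astype(int)
        mine = fit_blr(x[:, None], y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert mine.intercept_ == pytest.approx(ref.params[0], rel=1e-6)
        assert mine.coef_[0] == pytest.approx(ref.params[1], rel=1e-6)
        np.testing.assert_allclose(mine.bse_, ref.bse, rtol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_blr(np.arange(4.0)[:, None], np.zeros(4))


class TestSplitEvaluate:
    def test_separable_color_task_high_accuracy(self):
        X, y = _color_dataset(con=30.0, seed=11)
        report = split_evaluate(
            X, y, LSSVMClassifier(gamma=10.0, sigma=2.0), n_repeats=25, seed=1
        )
        assert report.accuracy >= 0.90
        assert report.n_train == 26 and report.n_test == 14  # 2:1 of 40

    def test_confusion_tallies_sum_to_tested_samples(self):
        X, y = _color_dataset(con=30.0, seed=11, n_per_class=6)
        report = split_evaluate(X, y, LSSVMClassifier(gamma=10.0, sigma=2.0), n_repeats=10, seed=0)
        assert sum(report.confusion.values()) == report.n_test * 10

    def test_iid_random_labels_give_chance_accuracy(self):
        """Exact null: labels independent of everything give 50% on average."""
        X, _ = _color_dataset(con=30.0, seed=11)
        rng = np.random.default_rng(0)
        n = len(X)
        train = np.arange(0, 2 * n // 3)
        test = np.arange(2 * n // 3, n)
        accs = []
        for _ in range(40):
            y = rng.integers(0, 2, n)
            if len(np.unique(y[train])) < 2:
                continue
            model = LSSVMClassifier(gamma=10.0, sigma=2.0).fit(X[train], y[train])
            accs.append(np.mean(model.predict(X[test]) == y[test]))
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) <= 3 * se

    def test_single_shuffle_within_dispersion_of_chance(self):
        X, y = _color_dataset(con=30.0, seed=11)
        y_shuffled = np.random.default_rng(5).permutation(y)
        report = split_evaluate(
            X, y_shuffled, LSSVMClassifier(gamma=10.0, sigma=2.0), n_repeats=30, seed=2
        )
        assert abs(report.accuracy - 0.5) <= 3 * report.accuracy_sd

    def test_accuracy_nondecreasing_in_contrast(self):
        """Harder-to-easier regimes: accuracy should not degrade as |Con| grows.

        Lenticels are disabled so mean-gray contrast is the only class signal.
        """
        accs = []
        for con in (0.0, 10.0, 20.0, 30.0):
            samples = generate_dataset(
                20, "rgb", params=PatchSimParams(con=con, n_lenticels=0), seed=21
            )
            X = np.array([color_features(s.data).values for s in samples])
            y = np.array([s.label for s in samples])
            rep = split_evaluate(X, y, LSSVMClassifier(gamma=10.0, sigma=2.0), n_repeats=20, seed=3)
            accs.append(rep.accuracy)
        assert all(b >= a - 0.05 for a, b in zip(accs, accs[1:]))
        assert accs[-1] > accs[0]

    def test_invalid_train_fraction_rejected(self):
        X, y = _color_dataset(con=30.0, seed=11, n_per_class=4)
        with pytest.raises(ValueError):
            split_evaluate(X, y, train_fraction=1.5)


class TestTuneLSSVM:
    def test_single_point_grid_returned(self):
        X, y = _color_dataset(con=30.0, seed=31, n_per_class=8)
        assert tune_lssvm(X, y, gamma_grid=[2.0], sigma_grid=[1.5], k_folds=2) == (2.0, 1.5)

    def test_separable_task_reaches_perfect_cv_somewhere(self):
        X, y = _color_dataset(con=30.0, seed=31, n_per_class=9)
        g, s = tune_lssvm(X, y, gamma_grid=[0.1, 10.0], sigma_grid=[0.5, 2.0], k_folds=3, seed=0)
        model = LSSVMClassifier(gamma=g, sigma=s).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_ties_break_toward_smallest_gamma_then_sigma(self):
        # constant features: every configuration scores identically
        X = np.zeros((12, 2))
        X[:6, 0] = 1.0
        y = np.array([0] * 6 + [1] * 6)
        g, s = tune_lssvm(X, y, gamma_grid=[5.0, 1.0], sigma_grid=[2.0, 0.5], k_folds=2, seed=0)
        assert (g, s) == (1.0, 0.5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_lssvm(np.zeros((4, 1)), np.array([0, 0, 1, 1]), gamma_grid=[], sigma_grid=[1.0])
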