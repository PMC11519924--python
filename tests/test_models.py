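"""Training machinery: Lasso/PR SGD, SVR, CART, MLP, logistic, K-fold."""

import numpy as np
import pytest

from scqp import models as md

FULL_BATCH = dict(batch_size=None, epochs=8000, learning_rate=0.1,
                  lr_decay=1e-5)


def standardized(rng, n, m):
    X = rng.normal(size=(n, m))
    return (X - X.mean(axis=0)) / X.std(axis=0)


class TestSGDLasso:
    def test_alpha_zero_matches_normal_equations(self, rng):
        X = standardized(rng, 60, 3)
        y = X @ np.array([2.0, -1.0, 0.5]) + 3.0 + rng.normal(0, 0.1, 60)
        fit = md.SGDLassoRegressor(alpha=0.0, **FULL_BATCH).fit(X, y)
        ols = np.linalg.lstsq(np.column_stack([X, np.ones(60)]), y,
                              rcond=None)[0]
        assert np.abs(fit.coef_ - ols[:3]).max() < 1e-6
        assert fit.intercept_ == pytest.approx(ols[3], abs=1e-6)

    def test_matches_soft_threshold_closed_form(self, rng):
        """1-D standardized Lasso has the closed form
        w = S(cov(x, y), alpha) for unit-variance x."""
        x = rng.normal(size=300)
        x = (x - x.mean()) / x.std()
        y = 0.7 * x + rng.normal(0, 0.1, 300)
        rho = float(x @ (y - y.mean()) / len(x))
        expected = np.sign(rho) * max(abs(rho) - 0.1, 0.0)
        fit = md.SGDLassoRegressor(alpha=0.1, batch_size=None, epochs=5000,
                                   learning_rate=0.1, lr_decay=1e-4).fit(
            x[:, None], y)
        assert fit.coef_[0] == pytest.approx(expected, abs=1e-4)

    def test_constant_target_gives_zero_weights(self, rng):
        X = standardized(rng, 40, 2)
        fit = md.SGDLassoRegressor(alpha=0.1, **FULL_BATCH).fit(
            X, np.full(40, 7.0))
        assert np.abs(fit.coef_).max() < 1e-6
        assert fit.intercept_ == pytest.approx(7.0, abs=1e-6)

    def test_loss_monotone_nonincreasing_full_batch(self, rng):
        X = standardized(rng, 50, 4)
        y = X @ np.array([1.0, 0.5, -2.0, 0.0]) + rng.normal(0, 0.3, 50)
        fit = md.SGDLassoRegressor(alpha=0.1, **FULL_BATCH).fit(X, y)
        diffs = np.diff(fit.loss_curve_)
        assert (diffs <= 1e-8).all()

    def test_reproducible_bit_for_bit(self, rng):
        X = standardized(rng, 64, 3)
        y = X @ np.array([1.0, -1.0, 0.2]) + rng.normal(0, 0.5, 64)
        a = md.SGDLassoRegressor(seed=7).fit(X, y)
        b = md.SGDLassoRegressor(seed=7).fit(X, y)
        assert np.array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            md.SGDLassoRegressor().fit(np.array([[np.nan], [1.0], [2.0],
                                                 [3.0]]),
                                       np.array([0.0, 1, 2, 3]))

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            md.SGDLassoRegressor().fit(X, np.zeros(3))


class TestPolynomialLasso:
    def test_recovers_pure_quadratic(self, rng):
        q = np.linspace(-1.5, 1.5, 80)[:, None]
        y = 2.0 + 3.0 * q.ravel() ** 2
        fit = md.PolynomialLassoRegressor(alpha=0.0, batch_size=None,
                                          epochs=8000, learning_rate=0.1,
                                          lr_decay=1e-5).fit(q, y)
        assert fit.coef_square_[0] == pytest.approx(3.0, abs=1e-3)
        assert abs(fit.coef_linear_[0]) < 1e-3

    def test_square_weights_shrink_for_linear_truth(self, rng):
        x = standardized(rng, 100, 1)
        y = 2.0 * x.ravel() + rng.normal(0, 0.05, 100)
        fit = md.PolynomialLassoRegressor(alpha=0.1, **FULL_BATCH).fit(x, y)
        assert abs(fit.coef_square_[0]) < 0.1 * abs(fit.coef_linear_[0])

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            md.PolynomialLassoRegressor().fit(np.empty((5, 0)), np.zeros(5))


class TestLinearSVR:
    ORACLE = dict(batch_size=None, epochs=10000)

    def test_inside_tube_data_has_zero_slack(self):
        x = np.linspace(-2, 2, 30)[:, None]
        y = 1.5 * x.ravel() + 0.3  # all residuals < epsilon from the line
        fit = md.LinearSVRScratch(**self.ORACLE).fit(x, y)
        assert fit.final_slack_penalty_ == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_wide_range_slope(self):
        x = np.linspace(-25, 25, 50)[:, None]
        fit = md.LinearSVRScratch(**self.ORACLE).fit(x, 5.0 * x.ravel())
        assert fit.coef_[0] == pytest.approx(5.0, abs=0.05)

    def test_agrees_with_reference_implementation(self, rng):
        """Same objective as libsvm's epsilon-SVR with a linear kernel."""
        from sklearn.svm import SVR

        X = rng.uniform(-3, 3, size=(50, 2))
        y = 4 * X[:, 0] - 2 * X[:, 1] + 1 + rng.normal(0, 0.5, 50)
        ref = SVR(kernel="linear", C=1.5, epsilon=1.0).fit(X, y)
        fit = md.LinearSVRScratch(**self.ORACLE).fit(X, y)
        rms = np.sqrt(np.mean((fit.predict(X) - ref.predict(X)) ** 2))
        assert rms <= 0.05

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            md.LinearSVRScratch(C=-1.0).fit(np.ones((4, 1)), np.ones(4))


class TestCart:
    def test_constant_target_single_leaf(self):
        X = np.arange(10.0)[:, None]
        fit = md.CartRegressor().fit(X, np.full(10, 4.2))
        assert fit.depth_ == 0
        assert np.allclose(fit.predict(X), 4.2)

    def test_two_step_function_recovered_exactly(self):
        x = np.linspace(0, 1, 40)[:, None]
        y = np.where(x.ravel() < 0.3, 1.0,
                     np.where(x.ravel() < 0.7, 5.0, 2.0))
        fit = md.CartRegressor(max_depth=3).fit(x, y)
        assert np.array_equal(fit.predict(x), y)

    def test_depth_never_exceeds_limit(self, rng):
        X = rng.normal(size=(200, 3))
        y = rng.normal(size=200)
        fit = md.CartRegressor(max_depth=3).fit(X, y)
        assert fit.depth_ <= 3

    def test_invariant_to_monotone_feature_rescale(self, rng):
        X = rng.uniform(0.1, 4.0, size=(80, 2))
        y = np.sin(X[:, 0]) + X[:, 1]
        base = md.CartRegressor().fit(X, y).predict(X)
        Xm = X.copy()
        Xm[:, 0] = np.log(Xm[:, 0])  # strictly monotone rescale
        warped = md.CartRegressor().fit(Xm, y).predict(Xm)
        assert np.allclose(base, warped)

    def test_tie_breaks_to_lowest_feature_and_threshold(self):
        # duplicated feature: both columns give identical reductions
        x = np.array([0.0, 1.0, 2.0, 3.0])
        X = np.column_stack([x, x])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = md.CartRegressor(max_depth=1).fit(X, y)
        assert fit.tree_["feature"] == 0
        assert fit.tree_["threshold"] == pytest.approx(1.5)


class TestTinyMLP:
    CFG = dict(epochs=1500, learning_rate=0.05, lr_decay=1e-5)

    def test_learns_linear_target(self):
        gen = np.random.default_rng(0)
        X = gen.normal(size=(600, 5))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5, 0.0]) + 3.0
        fit = md.TinyMLPRegressor(**self.CFG).fit(X, y)
        # val curve is on the unit-variance internal target scale
        assert np.sqrt(min(fit.val_loss_curve_)) < 0.1

    def test_early_stopping_at_patience(self):
        gen = np.random.default_rng(1)
        X = gen.normal(size=(200, 5))
        y = gen.normal(size=200)  # pure noise: validation plateaus fast
        fit = md.TinyMLPRegressor(epochs=500, patience=15).fit(X, y)
        assert fit.converged_
        best_epoch = int(np.argmin(fit.val_loss_curve_))
        assert fit.stopped_epoch_ == best_epoch + 1 + 15

    def test_permuted_targets_no_signal(self):
        gen = np.random.default_rng(2)
        X = gen.normal(size=(400, 5))
        y = gen.permutation(X @ np.ones(5))
        fit = md.TinyMLPRegressor(**self.CFG).fit(X, y)
        assert np.sqrt(min(fit.val_loss_curve_)) > 0.7  # ~std(y) scaled

    def test_feature_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="features"):
            md.TinyMLPRegressor().fit(np.ones((20, 3)), np.ones(20))


class TestLogistic:
    def test_separable_data_reaches_full_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 1, (50, 2)), rng.normal(3, 1, (50, 2))])
        y = np.repeat([0, 1], 50)
        fit = md.SGDLogisticClassifier(epochs=600).fit(X, y)
        assert (fit.predict(X) == y).mean() == 1.0

    def test_random_labels_give_half_probability(self, rng):
        X = rng.normal(size=(400, 3))
        y = np.repeat([0, 1], 200)
        fit = md.SGDLogisticClassifier(epochs=200).fit(X, y)
        p = fit.predict_proba(X)[:, 1]
        assert abs(p.mean() - 0.5) < 0.05

    def test_probabilities_clipped_away_from_zero_one(self, rng):
        X = np.vstack([rng.normal(-50, 1, (20, 1)), rng.normal(50, 1, (20, 1))])
        y = np.repeat([0, 1], 20)
        fit = md.SGDLogisticClassifier(epochs=500, learning_rate=1.0).fit(X, y)
        p1 = fit.predict_proba(X)[:, 1]
        assert p1.min() >= 1e-12 and p1.max() <= 1 - 1e-12
        assert np.isfinite(fit.loss_curve_).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            md.SGDLogisticClassifier().fit(np.ones((10, 1)), np.zeros(10))


class TestKFold:
    def test_twenty_samples_ten_folds_of_two(self):
        folds = md.kfold_indices(20, 10, seed=1)
        assert [len(v) for _, v in folds] == [2] * 10

    def test_disjoint_cover_and_size_balance(self):
        folds = md.kfold_indices(47, 10, seed=3)
        all_val = np.concatenate([v for _, v in folds])
        assert sorted(all_val.tolist()) == list(range(47))
        sizes = [len(v) for _, v in folds]
        assert max(sizes) - min(sizes) <= 1
        for train, val in folds:
            assert np.intersect1d(train, val).size == 0

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            md.kfold_indices(5, 10)

    def test_true_model_beats_intercept_only(self, rng):
        X = rng.normal(size=(100, 2))
        y = X @ np.array([3.0, -1.0]) + rng.normal(0, 0.5, 100)
        good = md.cross_validate(
            md.SGDLassoRegressor(alpha=0.0, **FULL_BATCH), X, y, k=10)
        base = md.cross_validate(
            md.CartRegressor(max_depth=0), X, y, k=10)
        assert good["cv_rmse"].mean() < base["cv_rmse"].mean()
        assert len(good["cv_rmse"]) == 10


def test_make_model_factory_kinds():
    assert isinstance(md.make_model("svr", C=2.0), md.LinearSVRScratch)
    with pytest.raises(ValueError):
        md.make_model("boost")
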