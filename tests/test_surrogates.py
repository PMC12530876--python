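"""Surrogate metrics and the five regression families."""

import numpy as np
import pytest

import smaopt as sm
from smaopt.errors import ContractError, TrainingError
from smaopt.surrogates import evaluate, mape, r2, train


def _dataset(name, X, y):
    return sm.DensityDataset.from_arrays(name, X, y)


class TestMetrics:
    def test_mape_hand_example(self):
        # |100-110|/100 = 0.1, |200-190|/200 = 0.05 -> mean 0.075
        assert mape([100.0, 200.0], [110.0, 190.0]) == pytest.approx(0.075, rel=1e-12)

    def test_mape_brute_force_loop(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(100, 1000, 40)
        yhat = y + rng.normal(0, 50, 40)
        expected = sum(abs(a - b) / abs(a) for a, b in zip(y, yhat)) / 40
        assert mape(y, yhat) == pytest.approx(expected, rel=1e-12)

    def test_mape_zero_target_rejected(self):
        with pytest.raises(ContractError):
            mape([0.0, 1.0], [1.0, 1.0])

    def test_r2_hand_example(self):
        # y = [1,2,3], yhat = [1,2,2]: SS_res=1, SS_tot=2 -> 0.5
        assert r2([1.0, 2.0, 3.0], [1.0, 2.0, 2.0]) == pytest.approx(0.5, rel=1e-12)

    def test_r2_perfect_and_mean_predictor(self):
        y = np.array([3.0, 5.0, 9.0, 11.0])
        assert r2(y, y) == pytest.approx(1.0)
        assert r2(y, np.full(4, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_r2_brute_force_loop(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(100, 1000, 30)
        yhat = y + rng.normal(0, 80, 30)
        ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
        ss_tot = sum((a - y.mean()) ** 2 for a in y)
        assert r2(y, yhat) == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    @pytest.mark.parametrize("fn", [mape, r2])
    def test_length_mismatch_rejected(self, fn):
        with pytest.raises(ContractError):
            fn([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_r2_constant_target_rejected(self):
        with pytest.raises(ContractError):
            r2([5.0, 5.0], [4.0, 6.0])


class TestModelSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ContractError):
            sm.ModelSpec.make("spline")

    def test_wrong_hyperparameter_rejected(self):
        with pytest.raises(ContractError):
            sm.ModelSpec.make("linear", degree=3)

    def test_label_stable(self):
        a = sm.ModelSpec.make("polynomial", degree=3)
        b = sm.ModelSpec.make("polynomial", degree=3)
        assert a.label() == b.label() == 'polynomial{"degree": 3}'


class TestTraining:
    def test_empty_dataset_rejected(self):
        ds = _dataset("e", np.empty((0, 4)), np.empty(0))
        with pytest.raises(TrainingError):
            train(sm.ModelSpec.make("linear"), ds)

    def test_invalid_records_rejected(self, space):
        pts = sm.make_sobol(space, 3)
        ds = sm.DensityDataset.from_arrays("x", pts, np.full(8, 700.0),
                                           valid=[True] * 7 + [False])
        with pytest.raises(TrainingError):
            train(sm.ModelSpec.make("linear"), ds)

    def test_polynomial_needs_enough_samples(self, space):
        pts = sm.make_sobol(space, 3)  # 8 points; cubic in 4-D needs 35
        ds = _dataset("x", pts, np.linspace(600, 800, 8))
        with pytest.raises(TrainingError):
            train(sm.ModelSpec.make("polynomial", degree=3), ds)

    def test_linear_recovers_affine_function(self, space):
        rng = np.random.default_rng(2)
        X = space.denormalize(rng.uniform(0, 1, size=(60, 4)))
        y = 650.0 + X @ np.array([100.0, -200.0, 40.0, 10.0])
        model = train(sm.ModelSpec.make("linear"), _dataset("aff", X, y))
        rep = evaluate(model, _dataset("aff", X, y), "IST")
        assert rep.mape < 1e-10 and rep.r2 > 1 - 1e-12

    def test_polynomial_recovers_quadratic_exactly(self, space):
        rng = np.random.default_rng(3)
        X = space.denormalize(rng.uniform(0, 1, size=(120, 4)))
        y = 700.0 + 50 * X[:, 0] ** 2 - 30 * X[:, 1] * X[:, 2] + 20 * X[:, 3]
        model = train(sm.ModelSpec.make("polynomial", degree=2), _dataset("q", X, y))
        # exact on unseen points, not just the training set
        Xnew = space.denormalize(rng.uniform(0, 1, size=(40, 4)))
        ynew = 700.0 + 50 * Xnew[:, 0] ** 2 - 30 * Xnew[:, 1] * Xnew[:, 2] + 20 * Xnew[:, 3]
        assert mape(ynew, model.predict(Xnew)) < 1e-9

    def test_gp_interpolates_noiseless_data(self, small_dataset, space):
        model = train(sm.ModelSpec.make("gaussian_process", kernel="rq"),
                      small_dataset, input_space=space)
        rep = evaluate(model, small_dataset, "IST")
        assert rep.mape < 1e-5

    def test_random_forest_predictions_within_training_range(self, small_dataset, space):
        model = train(sm.ModelSpec.make("random_forest", n_trees=50), small_dataset)
        rng = np.random.default_rng(4)
        preds = model.predict(space.denormalize(rng.uniform(0, 1, size=(100, 4))))
        lo, hi = small_dataset.densities.min(), small_dataset.densities.max()
        assert np.all(preds >= lo - 1e-9) and np.all(preds <= hi + 1e-9)

    @pytest.mark.parametrize("family,hp", [
        ("random_forest", {"n_trees": 30}),
        ("gaussian_process", {"kernel": "rbf"}),
        ("fnn", {"epochs": 200}),
    ])
    def test_training_deterministic_given_seed(self, small_dataset, space, family, hp):
        spec = sm.ModelSpec.make(family, train_seed=11, **hp)
        rng = np.random.default_rng(5)
        probe = space.denormalize(rng.uniform(0, 1, size=(20, 4)))
        a = train(spec, small_dataset).predict(probe)
        b = train(spec, small_dataset).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_vectorized_matches_pointwise(self, small_dataset, space):
        model = train(sm.ModelSpec.make("gaussian_process", kernel="matern"),
                      small_dataset)
        rng = np.random.default_rng(6)
        probe = space.denormalize(rng.uniform(0, 1, size=(15, 4)))
        batch = model.predict(probe)
        single = np.array([model.predict(sm.LJParamSet.from_array(row)) for row in probe])
        np.testing.assert_allclose(batch, single, rtol=1e-12)

    def test_out_of_space_prediction_warns(self, small_dataset, space):
        model = train(sm.ModelSpec.make("linear"), small_dataset, input_space=space)
        outside = space.upper_array() * 2
        with pytest.warns(RuntimeWarning):
            model.predict(sm.LJParamSet.from_array(outside))


class TestFamilyFidelity:
    """Each family reaches small in-sample error on its own model class."""

    def _fit_ist(self, spec, X, y):
        ds = _dataset("fid", X, y)
        return evaluate(train(spec, ds), ds, "IST").mape

    def test_each_family_on_matched_target(self, space):
        rng = np.random.default_rng(7)
        X = space.denormalize(rng.uniform(0, 1, size=(300, 4)))
        affine = 700.0 + X @ np.array([80.0, -60.0, 30.0, 15.0])
        cubic = 650.0 + 100 * X[:, 0] ** 3 - 40 * X[:, 1] * X[:, 2] + 25 * X[:, 3] ** 2
        # piecewise constant in the first coordinate: easy for trees
        steps = 600.0 + 50.0 * np.floor(4 * space.normalize(X)[:, 0])
        smooth = 700.0 + 100 * np.sin(3 * X[:, 0]) * np.cos(2 * X[:, 1]) + 50 * X[:, 2]
        cases = [
            (sm.ModelSpec.make("linear"), affine),
            (sm.ModelSpec.make("polynomial", degree=3), cubic),
            (sm.ModelSpec.make("random_forest", n_trees=200), steps),
            (sm.ModelSpec.make("gaussian_process", kernel="rbf"), smooth),
            (sm.ModelSpec.make("fnn", epochs=1500), smooth),
        ]
        for spec, y in cases:
            assert self._fit_ist(spec, X, y) < 0.02, spec.family

    def test_overfitting_gap_grows_with_degree(self, space):
        """Train/holdout MAPE gap on noisy data increases from degree 2 to a
        high degree, averaged over seeds: the classic overfitting signature."""
        gaps = {2: [], 6: []}
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            X = space.denormalize(rng.uniform(0, 1, size=(360, 4)))
            y = 700.0 + 200 * X[:, 0] - 150 * X[:, 1] + rng.normal(0, 20, 360)
            train_ds = _dataset("t", X[:280], y[:280])
            hold_ds = _dataset("h", X[280:], y[280:])
            for deg in gaps:
                model = train(sm.ModelSpec.make("polynomial", degree=deg), train_ds)
                ist = evaluate(model, train_ds, "IST").mape
                ost = evaluate(model, hold_ds, "OST").mape
                gaps[deg].append(ost - ist)
        assert np.mean(gaps[6]) > np.mean(gaps[2])
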