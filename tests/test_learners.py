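"""Learner registry, grid search, and out-of-fold training discipline."""

import numpy as np
import pytest

from dynawa.learners import (
    LearnerRegistry,
    LearnerSpec,
    build_estimator,
    default_registry,
    fit_predict_all,
    fold_assignments,
    grid_search,
)

from .conftest import make_spectra


def linear_spectra(n, p, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, p))
    beta = rng.normal(0, 1, p)
    y = X @ beta + rng.normal(0, noise, n)
    return make_spectra(X, y)


class TestRegistry:
    def test_structure(self):
        reg = default_registry()
        assert len(reg) == 34
        assert reg.family_counts() == {"TM": 9, "DL": 15, "LRM": 10}
        assert len(set(reg.names())) == 34

    def test_ars_regularization_grid_present(self):
        spec = next(s for s in default_registry() if s.name == "ARS")
        assert spec.grid["alpha"] == [0.0001, 0.001, 0.01, 0.1]

    def test_every_spec_builds(self):
        for spec in default_registry():
            est = build_estimator(spec, fast=True, seed=0)
            assert hasattr(est, "fit") and hasattr(est, "predict")

    def test_duplicate_names_rejected(self):
        spec = LearnerSpec("X", "TM", "rt")
        with pytest.raises(ValueError, match="unique"):
            LearnerRegistry((spec, spec))

    def test_bad_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            LearnerSpec("X", "??", "rt")


class TestGridSearch:
    def test_single_combination_returned(self):
        cal = linear_spectra(30, 3, 0)
        spec = LearnerSpec("R", "LRM", "ridge", {"alpha": 99.0}, grid={"alpha": [0.5]})
        tuned = grid_search(spec, cal, folds=3)
        assert tuned.hyperparams["alpha"] == 0.5

    def test_small_penalty_wins_on_noiseless_linear_data(self):
        cal = linear_spectra(60, 4, 1, noise=0.0)
        spec = LearnerSpec("R", "LRM", "ridge", {}, grid={"alpha": [1e-6, 50.0]})
        tuned = grid_search(spec, cal, folds=3)
        assert tuned.hyperparams["alpha"] == 1e-6

    def test_empty_grid_errors(self):
        cal = linear_spectra(20, 3, 2)
        with pytest.raises(ValueError, match="empty grid"):
            grid_search(LearnerSpec("R", "LRM", "ridge"), cal, folds=3)


class TestFoldAssignments:
    def test_balanced_and_deterministic(self):
        f = fold_assignments(23, 5, seed=3)
        counts = np.bincount(f, minlength=5)
        assert counts.max() - counts.min() <= 1
        assert np.array_equal(f, fold_assignments(23, 5, seed=3))
        assert not np.array_equal(f, fold_assignments(23, 5, seed=4))


class TestFitPredictAll:
    def test_shapes_single_learner(self):
        cal = linear_spectra(20, 3, 4)
        val = linear_spectra(7, 3, 5)
        reg = LearnerRegistry((LearnerSpec("Ridge", "LRM", "ridge", {"alpha": 1.0}),))
        P_oof, P_val, trace = fit_predict_all(reg, cal, val, folds=4, seed=0)
        assert P_oof.values.shape == (20, 1)
        assert P_val.values.shape == (7, 1)
        assert "Ridge" in trace.records

    def test_mean_predictor_stub_yields_fold_means(self):
        cal = linear_spectra(12, 2, 6)
        val = linear_spectra(4, 2, 7)
        reg = LearnerRegistry((LearnerSpec("Mean", "LRM", "dummy"),))
        P_oof, P_val, trace = fit_predict_all(reg, cal, val, folds=3, seed=1)
        y = cal.target
        for f in np.unique(trace.fold_of):
            expect = y[trace.fold_of != f].mean()
            assert np.allclose(P_oof.values[trace.fold_of == f, 0], expect)
        assert np.allclose(P_val.values[:, 0], y.mean())

    def test_ridge_recovers_noiseless_linear_map(self):
        cal = linear_spectra(60, 5, 8, noise=0.0)
        val = linear_spectra(30, 5, 9, noise=0.0)
        # same generating coefficients for cal and val
        rng = np.random.default_rng(8)
        X = rng.random((90, 5))
        beta = rng.normal(0, 1, 5)
        y = X @ beta
        cal = make_spectra(X[:60], y[:60])
        val = make_spectra(X[60:], y[60:])
        reg = LearnerRegistry((LearnerSpec("Ridge", "LRM", "ridge", {"alpha": 1e-8}),))
        _, P_val, _ = fit_predict_all(reg, cal, val, folds=5, seed=0)
        resid = P_val.values[:, 0] - val.target
        r2 = 1 - np.sum(resid ** 2) / np.sum((val.target - val.target.mean()) ** 2)
        assert r2 >= 0.99

    def test_validation_rows_permute_with_input(self):
        rng = np.random.default_rng(10)
        X = rng.random((40, 4))
        y = X.sum(axis=1)
        cal = make_spectra(X[:30], y[:30])
        val = make_spectra(X[30:], y[30:])
        perm = rng.permutation(10)
        val_p = make_spectra(X[30:][perm], y[30:][perm])
        reg = LearnerRegistry((LearnerSpec("KNR", "LRM", "knr", {"n_neighbors": 3}),))
        _, P_val, _ = fit_predict_all(reg, cal, val, folds=3, seed=0)
        _, P_val_p, _ = fit_predict_all(reg, cal, val_p, folds=3, seed=0)
        assert np.allclose(P_val_p.values, P_val.values[perm])

    def test_failing_learner_is_kept_with_fallback(self):
        cal = linear_spectra(15, 2, 11)
        val = linear_spectra(5, 2, 12)
        # PLS with an impossible component count triggers the failure path
        reg = LearnerRegistry((
            LearnerSpec("Broken", "LRM", "svr", {"kernel": "nope"}),
            LearnerSpec("Ridge", "LRM", "ridge", {"alpha": 1.0}),
        ))
        with pytest.warns(UserWarning, match="Broken"):
            P_oof, P_val, trace = fit_predict_all(reg, cal, val, folds=3, seed=0)
        assert trace.records["Broken"]["failed"]
        assert not trace.records["Ridge"]["failed"]
        assert np.isfinite(P_oof.values).all() and np.isfinite(P_val.values).all()

    def test_reproducible_end_to_end(self):
        cal = linear_spectra(30, 4, 13, noise=0.1)
        val = linear_spectra(10, 4, 14, noise=0.1)
        reg = default_registry().subset(["RF", "ELM", "LSTM-S", "GAN"])
        a = fit_predict_all(reg, cal, val, folds=3, fast=True, seed=5)
        b = fit_predict_all(reg, cal, val, folds=3, fast=True, seed=5)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_full_registry_smoke(self):
        """All 34 learners train on a small set and produce finite predictions."""
        rng = np.random.default_rng(15)
        X = rng.random((60, 24))
        y = 20 * X[:, 3] ** 1.5 + 5 * X[:, 10] + rng.normal(0, 0.2, 60)
        cal = make_spectra(X[:45], y[:45])
        val = make_spectra(X[45:], y[45:])
        P_oof, P_val, trace = fit_predict_all(default_registry(), cal, val,
                                              folds=3, fast=True, seed=2)
        assert P_oof.values.shape == (45, 34)
        assert P_val.values.shape == (15, 34)
        assert np.isfinite(P_oof.values).all() and np.isfinite(P_val.values).all()
        failed = [n for n, r in trace.records.items() if r["failed"]]
        assert failed == []
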