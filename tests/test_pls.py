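import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fingerpls.pls import (
    CVResult,
    kfold_cv,
    load_model,
    metrics,
    pls1_fit,
    pls_predict,
    save_model,
    select_n_latent,
)

from .conftest import random_xy
from .oracles import (
    centered_ols_fitted,
    manual_kfold_rmsecv,
    rmse_r2,
    simpls1_predictor,
)


class TestPls1Fit:
    def test_univariate_proportional_response_is_exact(self):
        x = np.arange(1.0, 9.0).reshape(-1, 1)
        y = 2.0 * x.ravel()
        model = pls1_fit(x, y, 1)
        assert np.allclose(model.fitted_values, y, atol=1e-12)
        m = metrics(y, model.fitted_values, context="calibration")
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_rank_fit_equals_centered_ols(self, seed):
        X, y = random_xy(seed)
        model = pls1_fit(X, y, 10)
        assert np.allclose(model.fitted_values, centered_ols_fitted(X, y), atol=1e-8)

    @pytest.mark.parametrize("seed", [3, 4])
    @pytest.mark.parametrize("n_components", [1, 2, 4, 7, 10])
    def test_nipals_agrees_with_simpls(self, seed, n_components):
        X, y = random_xy(seed)
        model = pls1_fit(X, y, n_components)
        oracle = simpls1_predictor(X, y, n_components)
        assert np.allclose(model.fitted_values, oracle(X), atol=1e-8)

    def test_agrees_with_sklearn_pls(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_xy(7)
        model = pls1_fit(X, y, 5)
        sk = sklearn.PLSRegression(n_components=5, scale=False).fit(X, y)
        assert np.allclose(model.fitted_values, sk.predict(X).ravel(), atol=1e-8)

    def test_scores_are_orthogonal(self):
        X, y = random_xy(11)
        T = pls1_fit(X, y, 8).scores
        gram = T.T @ T
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_score_loading_route_matches_regression_vector_route(self):
        X, y = random_xy(12)
        model = pls1_fit(X, y, 6)
        via_scores = model.scores @ model.y_loadings + model.y_mean
        assert np.allclose(model.fitted_values, via_scores, atol=1e-8)

    def test_rmsec_is_non_increasing_in_component_count(self):
        X, y = random_xy(13)
        errs = [
            metrics(y, pls1_fit(X, y, a).fitted_values).rmsec for a in range(1, 11)
        ]
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errs, errs[1:]))

    def test_rejects_bad_component_counts_and_constant_response(self):
        X, y = random_xy(1)
        with pytest.raises(ValueError):
            pls1_fit(X, y, 0)
        with pytest.raises(ValueError):
            pls1_fit(X, y, 20)
        with pytest.raises(ValueError, match="zero variance"):
            pls1_fit(X, np.ones(20), 2)


class TestPredict:
    def test_training_matrix_reproduces_fitted_values(self):
        X, y = random_xy(21)
        model = pls1_fit(X, y, 4)
        assert np.allclose(pls_predict(model, X), model.fitted_values, atol=1e-12)

    def test_mean_row_predicts_mean_response(self):
        X, y = random_xy(22)
        model = pls1_fit(X, y, 4)
        assert pls_predict(model, model.x_means)[0] == pytest.approx(
            model.y_mean, abs=1e-10
        )

    def test_matches_explicit_affine_map(self, rng):
        X, y = random_xy(23)
        model = pls1_fit(X, y, 4)
        X_new = rng.standard_normal((5, 10))
        expected = (X_new - model.x_means) @ model.coef + model.y_mean
        assert np.allclose(pls_predict(model, X_new), expected, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        X, y = random_xy(24)
        model = pls1_fit(X, y, 2)
        with pytest.raises(ValueError, match="variables"):
            pls_predict(model, np.ones((3, 4)))


class TestMetrics:
    def test_perfect_and_mean_predictors(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = metrics(y, y, context="calibration")
        assert m.rmsec == 0.0 and m.r_squared == pytest.approx(1.0)
        m0 = metrics(y, np.full(4, y.mean()), context="calibration")
        assert m0.r_squared == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_matches_textbook_formulas(self, seed):
        r = np.random.default_rng(seed)
        y_true = r.normal(size=15)
        y_pred = r.normal(size=15)
        err, det = rmse_r2(y_true, y_pred)
        m = metrics(y_true, y_pred, context="calibration")
        assert m.rmsec == pytest.approx(err, abs=1e-12)
        assert m.r_squared == pytest.approx(det, abs=1e-12)

    def test_validation_uses_supplied_reference_mean(self):
        r = np.random.default_rng(34)
        y_true, y_pred = r.normal(size=10), r.normal(size=10)
        m = metrics(y_true, y_pred, context="validation", reference_mean=0.5)
        _, det = rmse_r2(y_true, y_pred, ref_mean=0.5)
        assert m.q_squared == pytest.approx(det, abs=1e-12)

    def test_constant_reference_set_raises(self):
        with pytest.raises(ValueError):
            metrics(np.ones(5), np.zeros(5), context="calibration")


class TestKfoldCV:
    def test_folds_partition_the_samples_evenly(self):
        X, y = random_xy(41)
        cv = kfold_cv(X, y, k=10, seed=0)
        sizes = np.bincount(cv.fold_assignment)
        assert sizes.sum() == 20 and set(sizes) == {2}

    def test_rmsecv_matches_manual_refit_loop(self):
        X, y = random_xy(42)
        cv = kfold_cv(X, y, n_components_max=5, k=5, seed=3)
        for i, a in enumerate(cv.candidates):
            manual = manual_kfold_rmsecv(
                X, y, cv.fold_assignment, int(a), pls1_fit, pls_predict
            )
            assert cv.rmsecv[i] == pytest.approx(manual, abs=1e-10)

    def test_selects_known_latent_rank(self):
        # three latent factors with distinct X-variance scales, high SNR
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            T = r.standard_normal((40, 3))
            P = np.linalg.qr(r.standard_normal((20, 3)))[0]
            X = T @ np.diag([3.0, 2.0, 1.0]) @ P.T + 0.1 * r.standard_normal((40, 20))
            y = T @ np.ones(3)
            y = y + r.normal(0.0, 0.1 * np.std(y), 40)
            hits += select_n_latent(kfold_cv(X, y, k=10, seed=seed)) in (3, 4)
        assert hits >= 18

    def test_too_many_folds_raises(self):
        X, y = random_xy(43, n=5)
        with pytest.raises(ValueError):
            kfold_cv(X, y, k=6)


@pytest.mark.parametrize(
    "rmsecv, expected",
    [([5.0, 3.0, 3.0], 2), ([5.0, 4.0, 3.0], 3), ([2.0, 9.0, 9.0], 1)],
)
def test_select_n_latent_prefers_fewest_components_on_ties(rmsecv, expected):
    cv = CVResult(
        candidates=np.arange(1, len(rmsecv) + 1),
        rmsecv=np.array(rmsecv),
        fold_assignment=np.zeros(1, dtype=int),
        k=10,
        seed=0,
    )
    assert select_n_latent(cv) == expected


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_model_serialisation_round_trip(seed):
    X, y = random_xy(seed, n=12, p=6)
    model = pls1_fit(X, y, 3)
    path = "scratch_model.txt"
    import os, tempfile

    with tempfile.TemporaryDirectory() as d:
        fn = os.path.join(d, path)
        save_model(model, fn)
        back = load_model(fn)
    assert np.allclose(back.coef, model.coef)
    assert np.allclose(back.x_means, model.x_means)
    X_new = np.random.default_rng(seed).standard_normal((4, 6))
    assert np.allclose(pls_predict(back, X_new), pls_predict(model, X_new))
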