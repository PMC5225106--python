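"""UV scaling, PCA, and NIPALS PLS-DA against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from metabnet.multivariate import (
    ScaledMatrix,
    _nipals,
    _pls_coefficients,
    run_pca,
    run_plsda,
    uv_scale,
    vip_scores,
)


def _frame(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


class TestUVScale:
    def test_unit_sd_column(self):
        scaled = uv_scale(_frame([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(scaled.x["f0"], [-1.0, 0.0, 1.0])

    def test_constant_column_excluded(self, caplog):
        with caplog.at_level("WARNING", logger="metabnet.multivariate"):
            scaled = uv_scale(_frame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert scaled.excluded == ("f1",)
        assert list(scaled.x.columns) == ["f0"]
        assert "zero-variance" in caplog.text

    def test_random_matrix_centered_and_unit(self):
        rng = np.random.default_rng(0)
        scaled = uv_scale(_frame(rng.standard_normal((10, 5))))
        assert np.abs(scaled.x.mean(axis=0)).max() < 1e-9
        assert np.abs(scaled.x.std(axis=0, ddof=1) - 1).max() < 1e-9

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            uv_scale(_frame([[1.0, 2.0]]))


class TestPCA:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(8)
        x = np.outer(t, [1.0, -2.0, 0.5])
        frame = _frame(x)
        scaled = ScaledMatrix(x=frame, means=frame.mean(), sds=frame.std(ddof=1))
        result = run_pca(scaled, 1)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_uncorrelated_and_reconstruction(self):
        rng = np.random.default_rng(2)
        scaled = uv_scale(_frame(rng.standard_normal((6, 4))))
        result = run_pca(scaled)
        cov = np.cov(result.scores.to_numpy(), rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8
        recon = result.scores.to_numpy() @ result.loadings.to_numpy().T
        np.testing.assert_allclose(recon, scaled.x.to_numpy(), atol=1e-8)

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(3)
        scaled = uv_scale(_frame(rng.standard_normal((9, 5))))
        result = run_pca(scaled)
        assert np.all(np.diff(result.explained_variance_ratio) <= 1e-12)
        assert result.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        scaled = uv_scale(_frame(rng.standard_normal((7, 4))))
        a, b = run_pca(scaled), run_pca(scaled)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        for col in a.loadings:
            v = a.loadings[col]
            assert v.iloc[int(np.argmax(np.abs(v)))] > 0

    def test_component_range_checked(self):
        scaled = uv_scale(_frame(np.random.default_rng(5).standard_normal((4, 3))))
        with pytest.raises(ValueError):
            run_pca(scaled, 4)


class TestNIPALS:
    def test_single_component_matches_closed_form(self):
        """One PLS component on centered data has weight X'y/||X'y||."""
        rng = np.random.default_rng(6)
        x = rng.standard_normal((12, 2))
        y = rng.standard_normal((12, 1))
        xc, yc = x - x.mean(0), y - y.mean(0)
        W, T, P, Q = _nipals(xc, yc, 1)
        w_ref = xc.T @ yc[:, 0]
        w_ref /= np.linalg.norm(w_ref)
        np.testing.assert_allclose(np.abs(W[:, 0]), np.abs(w_ref), atol=1e-8)

    def test_full_rank_equals_ols(self):
        """With all components retained, PLS reproduces the OLS fit."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal((10, 4))
        y = rng.standard_normal((10, 1))
        xc, yc = x - x.mean(0), y - y.mean(0)
        W, T, P, Q = _nipals(xc, yc, 4)
        fitted = xc @ _pls_coefficients(W, P, Q)
        ols = xc @ np.linalg.lstsq(xc, yc, rcond=None)[0]
        np.testing.assert_allclose(fitted, ols, atol=1e-6)

    def test_matches_sklearn_pls(self):
        """Scores and coefficients agree with an independent implementation."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(8)
        x = rng.standard_normal((20, 6))
        y = rng.standard_normal((20, 1))
        xc, yc = x - x.mean(0), y - y.mean(0)
        W, T, P, Q = _nipals(xc, yc, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(xc, yc)
        np.testing.assert_allclose(np.abs(T), np.abs(ref.x_scores_), atol=1e-10)
        np.testing.assert_allclose(_pls_coefficients(W, P, Q), ref.coef_.T, atol=1e-10)


def _separable_model(n_perm=100, n_components=None, seed=11):
    rng = np.random.default_rng(0)
    n = 28
    classes = np.repeat(["a", "b"], n // 2)
    x = rng.standard_normal((n, 10))
    x[:, 0] = np.where(classes == "a", -3.0, 3.0)
    scaled = uv_scale(_frame(x))
    return run_plsda(scaled, classes, n_components=n_components,
                     n_perm=n_perm, seed=seed), classes


class TestPLSDA:
    def test_separable_classes_high_q2_and_min_permutation_p(self):
        model, _ = _separable_model()
        assert model.q2_cum > 0.9
        assert model.permutation_p == pytest.approx(1 / 101)
        assert model.vip.idxmax() == "f0"

    def test_null_labels_give_non_positive_mean_q2(self):
        """Random class labels carry no predictable signal: Q2 <= 0 on
        average over 50 replicate datasets."""
        q2 = []
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            x = rng.standard_normal((24, 10))
            classes = rng.permutation(np.repeat(["a", "b"], 12))
            model = run_plsda(uv_scale(_frame(x)), classes,
                              n_components=2, n_perm=0, seed=rep)
            q2.append(model.q2_cum)
        assert np.mean(q2) <= 0

    def test_r2y_non_decreasing(self):
        model, _ = _separable_model(n_perm=0, n_components=4)
        assert np.all(np.diff(model.r2y) >= -1e-12)

    def test_permutation_p_stable_across_seeds(self):
        """At large n_perm the permutation p is seed-insensitive."""
        m1, _ = _separable_model(n_perm=1000, n_components=2, seed=1)
        m2, _ = _separable_model(n_perm=1000, n_components=2, seed=2)
        assert abs(m1.permutation_p - m2.permutation_p) < 0.03

    def test_requires_two_classes(self):
        scaled = uv_scale(_frame(np.random.default_rng(9).standard_normal((6, 3))))
        with pytest.raises(ValueError, match="2 classes"):
            run_plsda(scaled, ["a"] * 6, n_components=1, n_perm=0)


class TestVIP:
    def test_mean_square_is_one(self):
        model, _ = _separable_model(n_perm=0, n_components=3)
        assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_features_all_unit_vip(self):
        """When every feature carries the class signal identically, the
        mean-square-1 constraint forces VIP = 1 everywhere."""
        classes = np.repeat(["a", "b"], 6)
        base = np.where(classes == "a", -1.0, 1.0)
        jitter = np.random.default_rng(10).standard_normal(12) * 0.1
        x = np.column_stack([base + jitter] * 4)
        model = run_plsda(uv_scale(_frame(x)), classes,
                          n_components=1, n_perm=0)
        np.testing.assert_allclose(model.vip, 1.0, atol=1e-8)

    def test_planted_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(11)
        classes = np.repeat(["a", "b"], 10)
        x = rng.standard_normal((20, 10))
        x[:, 3] += np.where(classes == "a", -2.0, 2.0)
        model = run_plsda(uv_scale(_frame(x)), classes,
                          n_components=2, n_perm=0)
        assert model.vip.idxmax() == "f3"
        assert model.vip["f3"] > 1.0

    def test_unfitted_model_rejected(self):
        model, _ = _separable_model(n_perm=0, n_components=1)
        model.n_components = 0
        with pytest.raises(ValueError):
            vip_scores(model)
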