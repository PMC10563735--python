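"""PLS/PLSDA/SV model families, feature fusion, PCA summaries."""

import numpy as np
import pandas as pd
import pytest

from kiwifusion.models import (
    CVPLSRegressor,
    GridPolySVR,
    PLSDAClassifier,
    dummy_rmse,
    fit_plsda,
    fit_plsr,
    fit_sv,
    fuse_features,
    one_hot,
    pca_summary,
)


class TestCVPLSRegressor:
    def test_noiseless_two_latent_directions(self, rng):
        # y depends on two orthogonal latent directions only
        T = rng.normal(size=(60, 2))
        loadings = rng.normal(size=(2, 15))
        X = T @ loadings
        y = T @ np.array([2.0, -1.0])
        model = fit_plsr(X, y, max_lv=8, seed=0)
        assert model.n_components_ <= 3
        pred = model.predict(X)
        ss = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss > 0.999

    def test_full_rank_matches_least_squares(self, rng):
        X = rng.normal(size=(25, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=25)
        model = CVPLSRegressor(n_components=6).fit(X, y)
        lhs = np.column_stack([np.ones(25), X])
        beta, *_ = np.linalg.lstsq(lhs, y, rcond=None)
        np.testing.assert_allclose(model.predict(X), lhs @ beta, atol=1e-6)

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_plsr(rng.normal(size=(30, 5)), np.full(30, 3.0))

    def test_max_lv_capped_with_warning(self, rng):
        X = rng.normal(size=(15, 3))
        y = X @ np.array([1.0, 2.0, 3.0]) + rng.normal(size=15)
        with pytest.warns(UserWarning, match="capped"):
            model = fit_plsr(X, y, max_lv=50, seed=0)
        assert model.n_components_ <= 3


class TestPLSDA:
    def test_dummy_coding_is_unit_vectors(self):
        classes = np.array([0, 2, 5, 8, 11, 14, 17, 20])
        Y = one_hot(np.array([5]), classes)
        assert Y.shape == (1, 8)
        np.testing.assert_array_equal(Y[0], [0, 0, 1, 0, 0, 0, 0, 0])

    def test_separable_clouds_reach_full_calibration_accuracy(self, rng):
        X = np.vstack([rng.normal(size=(20, 4)) + 8, rng.normal(size=(20, 4)) - 8])
        labels = np.array([0] * 20 + [1] * 20)
        model = fit_plsda(X, labels, max_lv=4, seed=0)
        assert (model.predict(X) == labels).mean() == 1.0

    def test_one_lv_on_two_separated_classes(self, rng):
        X = np.vstack([rng.normal(size=(25, 6)) + 5, rng.normal(size=(25, 6)) - 5])
        labels = np.array(["early"] * 25 + ["late"] * 25)
        model = PLSDAClassifier(n_components=1).fit(X, labels)
        assert (model.predict(X) == labels).mean() >= 0.95

    def test_row_permutation_invariance(self, rng):
        X = rng.normal(size=(40, 5))
        labels = np.repeat([0, 1, 2, 3], 10)
        perm = rng.permutation(40)
        a = PLSDAClassifier(n_components=3).fit(X, labels)
        b = PLSDAClassifier(n_components=3).fit(X[perm], labels[perm])
        np.testing.assert_allclose(
            a.decision_function(X), b.decision_function(X), atol=1e-8)

    def test_single_member_class_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="single member"):
            fit_plsda(X, np.array([0, 0, 1, 1, 2]))


class TestGridSV:
    def test_default_grid_evaluates_25_pairs(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + 0.05 * rng.normal(size=40)
        model = fit_sv(X, y, "regression", seed=0)
        assert len(model.grid_record_) == 25
        assert model.best_rmse_val_ == min(r.rmse_val for r in model.grid_record_)

    def test_single_pair_grid_is_chosen(self, rng):
        X = rng.normal(size=(30, 3))
        y = X.sum(axis=1)
        model = GridPolySVR(c_grid=[10.0], gamma_grid=[0.1], folds=5).fit(X, y)
        assert (model.best_c_, model.best_gamma_) == (10.0, 0.1)

    def test_interpolation_at_large_c(self, rng):
        # duplicated rows with consistent targets: training RMSE -> ~epsilon
        X = np.repeat(rng.normal(size=(10, 3)), 3, axis=0)
        y = np.repeat(rng.normal(size=10), 3)
        model = GridPolySVR(c_grid=[100.0], gamma_grid=[1.0], folds=5,
                            epsilon=1e-4).fit(X, y)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 0.05 * y.std()

    def test_classifier_grid_and_prediction(self, rng):
        X = np.vstack([rng.normal(size=(25, 4)) + 4, rng.normal(size=(25, 4)) - 4])
        labels = np.array([0] * 25 + [1] * 25)
        model = fit_sv(X, labels, "classification", seed=0)
        assert len(model.grid_record_) == 25
        assert (model.predict(X) == labels).mean() >= 0.95

    def test_unknown_task_rejected(self, rng):
        with pytest.raises(ValueError, match="task"):
            fit_sv(rng.normal(size=(10, 2)), rng.normal(size=10), "ranking")

    def test_non_finite_features_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            GridPolySVR().fit(X, rng.normal(size=30))

    def test_dummy_rmse_of_hard_labels(self):
        classes = np.array([0, 1])
        # one of four misclassified: squared error 2 over 8 dummy entries
        assert dummy_rmse([0, 0, 1, 1], [0, 0, 1, 0], classes) == pytest.approx(0.5)


def _tables(rng, n=12, n_bands=60):
    ids = [f"f{i:02d}" for i in range(n)]
    enose = pd.DataFrame(rng.normal(size=(n, 39)),
                         index=ids, columns=[f"e{i}" for i in range(39)])
    wl = np.linspace(450, 900, n_bands)
    spectral = pd.DataFrame(rng.normal(size=(n, n_bands)), index=ids, columns=wl)
    return enose, spectral, ids


class TestFusion:
    def test_39_plus_51_makes_90_columns(self, rng):
        enose, spectral, ids = _tables(rng)
        fused = fuse_features(enose, spectral, list(spectral.columns[:51]), ids[:8])
        assert fused.X.shape[1] == 90
        assert fused.provenance[:39] == ("enose",) * 39
        assert set(fused.provenance[39:]) == {"spectral"}

    def test_empty_selection_degenerates_with_warning(self, rng):
        enose, spectral, ids = _tables(rng)
        with pytest.warns(UserWarning, match="empty"):
            fused = fuse_features(enose, spectral, [], ids[:8])
        assert fused.X.shape[1] == 39

    def test_calibration_columns_standardized(self, rng):
        enose, spectral, ids = _tables(rng)
        cal = ids[:8]
        fused = fuse_features(enose, spectral, list(spectral.columns[:5]), cal)
        cal_block = fused.X.loc[cal]
        np.testing.assert_allclose(cal_block.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(cal_block.std(axis=0, ddof=0), 1.0, atol=1e-10)

    def test_id_mismatch_reported(self, rng):
        enose, spectral, ids = _tables(rng)
        with pytest.raises(KeyError, match="f00"):
            fuse_features(enose.drop(index="f00"), spectral, [], ids[:4])


class TestPcaSummary:
    def test_rank_one_block_concentrates_on_pc1(self, rng):
        t = rng.normal(size=20)
        block = np.outer(t, [1.0, 2.0, 3.0])
        summary = pca_summary(block, "MSR")
        assert summary.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        summary = pca_summary(rng.normal(size=(30, 6)))
        assert summary.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_equal_variance_columns_share_fractions(self, rng):
        n = 4000
        X = np.random.default_rng(0).normal(size=(n, 3))
        summary = pca_summary(X)
        assert np.allclose(summary.explained_variance_ratio, 1 / 3, atol=0.05)

    def test_loadings_unit_norm(self, rng):
        summary = pca_summary(rng.normal(size=(25, 5)))
        np.testing.assert_allclose(
            np.linalg.norm(summary.loadings, axis=1), 1.0, atol=1e-10)

    def test_degenerate_block_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            pca_summary(np.ones((5, 4)))
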