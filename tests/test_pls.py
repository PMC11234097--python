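"""NIPALS PLS against OLS / reference-implementation / brute-force oracles,
plus split and metric behavior."""

import numpy as np
import pytest

from driftfa import (
    NipalsPLS, PLSModelBundle, loo_cv_select, prediction_metrics,
    split_calibration_validation,
)
from driftfa.spectra import SpectraError


def random_problem(rng, n=30, m=80, k_true=3, noise=0.05):
    T = rng.normal(size=(n, k_true))
    P = rng.normal(size=(k_true, m))
    X = T @ P + 0.01 * rng.normal(size=(n, m))
    y = T @ rng.normal(size=k_true) + noise * rng.normal(size=n)
    return X, y


class TestNipalsFit:
    def test_single_column_response_recovered_with_one_component(self):
        # orthonormal predictor columns: one NIPALS factor fits y = 5*x_j
        # exactly and the coefficient concentrates on column j
        rng = np.random.default_rng(0)
        A = rng.normal(size=(25, 10))
        X, _ = np.linalg.qr(A - A.mean(axis=0))  # centered orthonormal columns
        y = 5.0 * X[:, 3]
        m = NipalsPLS(n_components=1).fit(X, y)
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)
        assert np.argmax(np.abs(m.coef_)) == 3

    def test_full_component_pls_equals_ols_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        m = NipalsPLS(n_components=6).fit(X, y)
        Xd = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)  # normal-equations OLS
        np.testing.assert_allclose(m.predict(X), Xd @ beta, atol=1e-8)

    def test_matches_reference_pls_implementation(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        X, y = random_problem(rng)
        mine = NipalsPLS(n_components=3).fit(X, y)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            mine.predict(X), ref.predict(X).ravel(), atol=1e-6
        )

    def test_factorization_and_collapsed_coef_agree(self):
        rng = np.random.default_rng(3)
        X, y = random_problem(rng, n=25, m=40, k_true=4)
        m = NipalsPLS(n_components=4).fit(X, y)
        # rebuild predictions from the factorization itself
        Xc = X - m.x_mean_
        T = np.empty((X.shape[0], 4))
        Xd = Xc.copy()
        for a in range(4):
            T[:, a] = Xd @ m.x_weights_[:, a]
            Xd -= np.outer(T[:, a], m.x_loadings_[:, a])
        from_factors = T @ m.y_loadings_ + m.y_mean_
        np.testing.assert_allclose(from_factors, m.predict(X), atol=1e-10)

    def test_predict_on_mean_spectrum_returns_y_mean(self):
        rng = np.random.default_rng(4)
        X, y = random_problem(rng)
        m = NipalsPLS(n_components=3).fit(X, y)
        assert m.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(
            m.y_mean_, abs=1e-10
        )

    def test_constant_shift_changes_prediction_by_c_sum_coef(self):
        rng = np.random.default_rng(5)
        X, y = random_problem(rng)
        m = NipalsPLS(n_components=3).fit(X, y)
        c = 0.37
        np.testing.assert_allclose(
            m.predict(X + c), m.predict(X) + c * m.coef_.sum(), atol=1e-8
        )

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 5))
        with pytest.raises(ValueError, match="n_components"):
            NipalsPLS(n_components=10).fit(X, rng.normal(size=10))
        with pytest.raises(ValueError, match="zero variance"):
            NipalsPLS(n_components=2).fit(X, np.ones(10))


class TestLooCvSelect:
    def brute_force_rmsecv(self, X, y, k_max):
        n = y.size
        curves = np.empty((n, k_max))
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            for k in range(1, k_max + 1):
                m = NipalsPLS(n_components=k).fit(X[keep], y[keep])
                curves[i, k - 1] = m.predict(X[i][None, :])[0]
        return np.sqrt(np.mean((curves - y[:, None]) ** 2, axis=0))

    @pytest.mark.parametrize("n,m,k_max", [(15, 12, 4), (25, 40, 6)])
    def test_matches_brute_force_refit_oracle(self, n, m, k_max):
        rng = np.random.default_rng(7)
        X, y = random_problem(rng, n=n, m=m)
        cv = loo_cv_select(X, y, k_max)
        np.testing.assert_allclose(
            cv.rmsecv_by_k, self.brute_force_rmsecv(X, y, k_max), atol=1e-10
        )
        assert cv.chosen_k == int(np.argmin(cv.rmsecv_by_k)) + 1

    def test_one_component_structure_selects_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 15))
        y = X @ rng.normal(size=15)
        # make y exactly rank-one in X-space: y = 3 * first latent direction
        u = rng.normal(size=15)
        X = np.outer(rng.normal(size=20), u)
        X += 1e-9 * rng.normal(size=X.shape)  # break exact degeneracy
        y = 3.0 * (X @ u)
        cv = loo_cv_select(X, y, 5)
        assert cv.chosen_k == 1

    def test_chosen_k_minimizes_curve_on_synthetic_data(self, processed_combined):
        proc, ref = processed_combined
        (cal, y_cal), _ = split_calibration_validation(proc, ref, 0.75, seed=1)
        cv = loo_cv_select(cal.absorbance, y_cal, 10)
        assert cv.rmsecv_by_k[cv.chosen_k - 1] == cv.rmsecv_by_k.min()
        assert 1 <= cv.chosen_k <= 10


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        m = prediction_metrics([1, 2, 3], [1, 2, 3])
        assert m.rmsep == 0.0 and m.re == 0.0 and m.r2 == 1.0

    def test_hand_arithmetic_offset_by_one(self):
        m = prediction_metrics([1, 2, 3, 4], [2, 3, 4, 5])
        assert m.rmsep == pytest.approx(1.0)
        assert m.re == pytest.approx(0.4)
        assert m.r2 == pytest.approx(1.0)
        assert m.n_val == 4

    def test_constant_prediction_gives_zero_r2(self):
        m = prediction_metrics([1, 2, 3, 4], [2.5, 2.5, 2.5, 2.5])
        assert m.r2 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prediction_metrics([1, 2, 3], [1, 2])


class TestSplit:
    def test_101_samples_split_76_25(self, processed_combined):
        proc, ref = processed_combined
        (cal, y_cal), (val, y_val) = split_calibration_validation(
            proc, ref, 0.75, seed=3
        )
        assert cal.n_samples == 76 and val.n_samples == 25
        assert y_cal.size == 76 and y_val.size == 25
        # calibration range covers validation range (stratification)
        assert y_cal.min() <= y_val.min() and y_cal.max() >= y_val.max()

    def test_same_seed_identical_partition(self, processed_combined):
        proc, ref = processed_combined
        a = split_calibration_validation(proc, ref, 0.75, seed=9)
        b = split_calibration_validation(proc, ref, 0.75, seed=9)
        assert a[0][0].sample_ids == b[0][0].sample_ids
        assert a[1][0].sample_ids == b[1][0].sample_ids

    def test_quartiles_contribute_evenly_to_validation(self):
        import pandas as pd

        from driftfa import ReferenceTable, SpectraSet, WavenumberGrid

        n = 100
        y = np.arange(1.0, n + 1.0)
        grid = WavenumberGrid(np.array([0.0, 1.0]))
        ids = [f"s{i}" for i in range(n)]
        s = SpectraSet(grid, np.zeros((n, 2)), ids)
        ref = ReferenceTable(pd.Series(y, index=ids))
        _, (val, y_val) = split_calibration_validation(s, ref, 0.75, seed=0)
        counts = [
            np.sum((y_val > lo) & (y_val <= hi))
            for lo, hi in [(0, 25), (25, 50), (50, 75), (75, 100)]
        ]
        assert all(abs(c - 25 * 0.25) <= 1 for c in counts)

    def test_invalid_fraction_rejected(self, processed_combined):
        proc, ref = processed_combined
        with pytest.raises(ValueError):
            split_calibration_validation(proc, ref, 0.3, seed=0)


class TestModelBundle:
    def test_json_round_trip_preserves_predictions(
        self, processed_combined, tmp_path
    ):
        proc, ref = processed_combined
        (cal, y_cal), (val, _) = split_calibration_validation(proc, ref, 0.75, 1)
        m = NipalsPLS(n_components=4).fit(cal.absorbance, y_cal)
        bundle = PLSModelBundle(m, proc.grid.values, 4, seed=1)
        path = tmp_path / "model.json"
        bundle.to_json(path)
        back = PLSModelBundle.from_json(path)
        np.testing.assert_allclose(
            back.predict_spectra(val), bundle.predict_spectra(val), rtol=1e-12
        )

    def test_grid_mismatch_rejected(self, processed_combined, combined_dataset):
        proc, ref = processed_combined
        raw, _, _ = combined_dataset
        (cal, y_cal), _ = split_calibration_validation(proc, ref, 0.75, 1)
        m = NipalsPLS(n_components=2).fit(cal.absorbance, y_cal)
        bundle = PLSModelBundle(m, proc.grid.values, 2)
        with pytest.raises(SpectraError, match="grid"):
            bundle.predict_spectra(raw)
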