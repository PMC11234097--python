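"""Fingerprint cut, AsLS baseline (against a dense-matrix oracle) and area
normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftfa import (
    PreprocessConfig, SpectraSet, WavenumberGrid, area_normalize,
    asls_baseline, cut_region, preprocess_pipeline,
)
from driftfa.spectra import SpectraError


def asls_dense_oracle(y, lam, p, max_iter=50):
    """Independent AsLS: dense second-difference penalty, generic linear
    solve of (W + lam * D'D) z = W y at every reweighting."""
    y = np.asarray(y, dtype=float)
    n = y.size
    D = np.diff(np.eye(n), n=2, axis=0)
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max_iter):
        z_new = np.linalg.solve(np.diag(w) + penalty, w * y)
        w_new = np.where(y > z_new, p, 1.0 - p)
        change = np.max(np.abs(z_new - z)) / max(np.max(np.abs(z_new)), 1e-300)
        z = z_new
        if np.array_equal(w_new, w) or change < 1e-6:
            break
        w = w_new
    return z


def band_on_slope(n=501, center=250, width=20, slope=0.001, offset=0.2):
    nu = np.arange(n, dtype=float)
    y = slope * nu + offset
    lo, hi = center - width // 2, center + width // 2
    y[lo:hi] += 1.0 - np.abs(np.linspace(-1, 1, hi - lo))
    return y


class TestCutRegion:
    def test_fingerprint_cut_retains_251_points(self, default_grid):
        s = SpectraSet(default_grid, np.ones((2, 901)), ["a", "b"])
        out = cut_region(s, 800.0, 1800.0)
        assert len(out.grid) == 251
        assert out.grid.values[0] == 800.0 and out.grid.values[-1] == 1800.0
        assert out.sample_ids == ["a", "b"]

    def test_full_range_cut_is_identity(self, small_spectra):
        out = cut_region(small_spectra, small_spectra.grid.values[0],
                         small_spectra.grid.values[-1])
        np.testing.assert_array_equal(out.absorbance, small_spectra.absorbance)

    def test_disjoint_region_errors(self, small_spectra):
        with pytest.raises(SpectraError, match="outside grid"):
            cut_region(small_spectra, 5000.0, 6000.0)


class TestAslsBaseline:
    def test_affine_signal_is_fixed_point(self):
        nu = np.arange(301, dtype=float)
        y = 0.3 + 0.002 * nu
        baseline, corrected = asls_baseline(y, 20_000.0, 0.001)
        np.testing.assert_allclose(baseline, y, atol=1e-8)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-8)

    def test_zero_signal_gives_zero_baseline(self):
        baseline, corrected = asls_baseline(np.zeros(100))
        np.testing.assert_allclose(baseline, 0.0, atol=1e-12)
        np.testing.assert_allclose(corrected, 0.0, atol=1e-12)

    def test_band_on_slope_matches_dense_oracle(self):
        y = band_on_slope()
        baseline, _ = asls_baseline(y, 20_000.0, 0.001)
        np.testing.assert_allclose(baseline, asls_dense_oracle(y, 20_000.0, 0.001),
                                   atol=1e-8)

    def test_oracle_equivalence_on_random_smooth_signals(self):
        rng = np.random.default_rng(42)
        nu = np.linspace(0, 1, 301)
        for _ in range(10):
            y = (rng.normal(0, 0.1) + rng.normal(0, 0.5) * nu
                 + rng.normal(0, 0.5) * nu**2)
            for _ in range(rng.integers(1, 4)):
                c, w, a = rng.uniform(0.1, 0.9), rng.uniform(0.01, 0.05), rng.uniform(0.2, 1.0)
                y = y + a * np.exp(-0.5 * ((nu - c) / w) ** 2)
            np.testing.assert_allclose(
                asls_baseline(y)[0], asls_dense_oracle(y, 20_000.0, 0.001),
                atol=1e-8,
            )

    @given(a=st.floats(-1.0, 1.0), b=st.floats(-0.01, 0.01))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_shift_moves_baseline_affinely(self, a, b):
        # second-difference penalty annihilates affine terms
        y = band_on_slope(n=201, center=100, width=16)
        nu = np.arange(201, dtype=float)
        base0, _ = asls_baseline(y)
        base1, _ = asls_baseline(y + a + b * nu)
        np.testing.assert_allclose(base1, base0 + a + b * nu, atol=1e-6)

    def test_larger_lambda_gives_smoother_baseline(self):
        y = band_on_slope()
        rough = asls_baseline(y, lam=100.0)[0]
        smooth = asls_baseline(y, lam=1e6)[0]
        assert np.sum(np.diff(smooth, 2) ** 2) < np.sum(np.diff(rough, 2) ** 2)

    @pytest.mark.parametrize(
        "kwargs", [{"lam": 0.0}, {"lam": -1.0}, {"p": 0.0}, {"p": 1.0}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            asls_baseline(np.ones(10), **{"lam": 1.0, "p": 0.5, **kwargs})

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            asls_baseline(np.array([1.0, np.inf, 2.0, 1.0]))


class TestAreaNormalize:
    def test_unit_trapezoidal_area(self, small_spectra):
        out = area_normalize(small_spectra)
        areas = np.trapezoid(out.absorbance, out.grid.values, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-10)

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        grid = WavenumberGrid(np.array([0.0, 1.0, 2.0, 3.0]))
        y = np.array([[0.1, 0.5, 0.4, 0.2]])
        a = area_normalize(SpectraSet(grid, y, ["s"]))
        b = area_normalize(SpectraSet(grid, c * y, ["s"]))
        np.testing.assert_allclose(a.absorbance, b.absorbance, rtol=1e-12)

    def test_hand_trapezoid_example(self):
        grid = WavenumberGrid(np.array([0.0, 1.0, 2.0]))
        s = SpectraSet(grid, np.array([[0.0, 2.0, 0.0]]), ["x"])
        out = area_normalize(s)  # trapezoidal area 2
        np.testing.assert_allclose(out.absorbance, [[0.0, 1.0, 0.0]])

    def test_non_positive_area_names_sample(self):
        grid = WavenumberGrid(np.array([0.0, 1.0, 2.0]))
        s = SpectraSet(grid, np.array([[0.1, 0.2, 0.1], [0.0, 0.0, 0.0]]),
                       ["ok", "flat"])
        with pytest.raises(SpectraError, match="flat"):
            area_normalize(s)

    def test_band_height_ordering_preserved(self, small_spectra):
        out = area_normalize(small_spectra)
        for before, after in zip(small_spectra.absorbance, out.absorbance):
            np.testing.assert_array_equal(np.argsort(before), np.argsort(after))


class TestPreprocessPipeline:
    def test_default_pipeline_output_shape_and_area(self, combined_dataset):
        spectra, _, _ = combined_dataset
        out = preprocess_pipeline(spectra.select(range(3)))
        assert out.absorbance.shape == (3, 251)
        areas = np.trapezoid(out.absorbance, out.grid.values, axis=1)
        np.testing.assert_allclose(areas, 1.0, atol=1e-10)

    def test_provenance_records_single_application(self, combined_dataset):
        spectra, _, _ = combined_dataset
        out = preprocess_pipeline(spectra.select(range(2)))
        steps = [p["step"] for p in out.provenance]
        assert steps.count("preprocess_pipeline") == 1
        # a second application is a distinct event, recorded as such
        again = preprocess_pipeline(out)
        assert [p["step"] for p in again.provenance].count("preprocess_pipeline") == 2

    def test_wider_region_runs(self, combined_dataset):
        spectra, _, _ = combined_dataset
        cfg = PreprocessConfig(region_lo=500.0, region_hi=3500.0)
        out = preprocess_pipeline(spectra.select(range(2)), cfg)
        assert out.grid.values[0] == 500.0 and out.grid.values[-1] == 3500.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(region_lo=1800.0, region_hi=800.0)
        with pytest.raises(ValueError):
            PreprocessConfig(asls_p=1.5)
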