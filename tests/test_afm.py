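"""Height-field analysis: background, detection, mixture deconvolution."""

import numpy as np
import pytest

from membmode.afm import (
    analyze_field,
    analyze_fields,
    background_plane,
    detect_particles,
    fit_gaussian_mixture,
    fit_gaussian_sum_histogram,
    mixture_k_sweep,
)
from membmode.errors import FitError, UsageError
from membmode.structio import HeightField
from membmode.synthetic_data import default_mixture_spec, sample_mixture, simulate_afm_field


def gaussian_bump_field(centers, heights, n_px=100, pixel=1.0, sd=1.5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    axis = (np.arange(n_px) + 0.5) * pixel
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    grid = np.zeros((n_px, n_px))
    for (cx, cy), h in zip(centers, heights):
        grid += h * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sd**2))
    if noise > 0:
        grid += rng.normal(0, noise, grid.shape)
    return HeightField(grid, pixel)


class TestBackground:
    def test_exact_flat_field(self):
        field = HeightField(np.full((20, 20), 4.0), 1.0)
        assert background_plane(field) == pytest.approx(4.0)

    def test_flat_with_sparse_bumps(self):
        field = gaussian_bump_field([(20.5, 20.5), (70.5, 70.5)], [2.0, 2.5], noise=0.03, seed=2)
        assert abs(background_plane(field)) < 0.03

    def test_synthetic_field_closure(self):
        field, _ = simulate_afm_field(default_mixture_spec(), 40, field_nm=200.0,
                                      noise_sd_nm=0.05, seed=3)
        assert abs(background_plane(field)) < 0.02


class TestDetection:
    def test_flat_noisy_field_no_particles(self):
        rng = np.random.default_rng(0)
        field = HeightField(rng.normal(0, 0.05, (60, 60)), 1.0)
        assert detect_particles(field) == []

    def test_planted_bumps_recovered_exactly(self):
        field, truth = simulate_afm_field(default_mixture_spec(), 50, field_nm=300.0,
                                          noise_sd_nm=0.0, seed=9)
        found = detect_particles(field)
        assert len(found) == 50
        planted = np.array([[t.x_nm, t.y_nm] for t in truth])
        got = np.array([m.position for m in found])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(planted).query(got)
        assert np.max(d) <= field.pixel_size
        # peak altitudes match the planted peak heights on-grid
        h_planted = np.sort([t.peak_height_nm for t in truth])
        h_got = np.sort([m.peak_altitude_nm for m in found])
        assert np.allclose(h_planted, h_got, atol=0.02)

    def test_close_pair_collapses_to_taller_peak(self):
        field = gaussian_bump_field([(40.5, 40.5), (43.5, 40.5)], [2.0, 1.5])
        found = detect_particles(field, min_separation_nm=8.0)
        assert len(found) == 1
        assert found[0].peak_altitude_nm == pytest.approx(
            field.heights.max(), abs=1e-9
        )

    def test_translation_and_rotation_invariant_count(self):
        field, _ = simulate_afm_field(default_mixture_spec(), 30, field_nm=200.0,
                                      noise_sd_nm=0.02, seed=4)
        n0 = len(detect_particles(field))
        rotated = HeightField(np.rot90(field.heights).copy(), field.pixel_size)
        translated = HeightField(field.heights + 0.0, field.pixel_size, origin=[50.0, -10.0])
        assert len(detect_particles(rotated)) == n0
        assert len(detect_particles(translated)) == n0

    def test_threshold_must_be_positive(self):
        field = HeightField(np.zeros((4, 4)), 1.0)
        with pytest.raises(UsageError):
            detect_particles(field, min_altitude_nm=0.0)


class TestMixtureFit:
    def test_single_component_mle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 0.1, 10000)
        fit = fit_gaussian_mixture(x, K=1, n_restarts=3, seed=0)
        assert fit.means_nm[0] == pytest.approx(2.0, abs=0.003)
        assert fit.sds_nm[0] == pytest.approx(0.1, abs=0.003)
        assert fit.converged

    def test_three_component_parameter_recovery(self):
        spec = default_mixture_spec()
        x = sample_mixture(spec, 2000, seed=7)
        fit = fit_gaussian_mixture(x, K=3, n_restarts=10, seed=1)
        assert np.allclose(fit.means_nm, spec.means_nm, atol=0.05)
        assert np.allclose(fit.weights, spec.weights, atol=0.04)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.mixture import GaussianMixture

        spec = default_mixture_spec()
        x = sample_mixture(spec, 1500, seed=11)
        ours = fit_gaussian_mixture(x, K=3, n_restarts=10, seed=2)
        ref = GaussianMixture(3, n_init=5, random_state=0, tol=1e-6).fit(x.reshape(-1, 1))
        order = np.argsort(ref.means_.ravel())
        assert np.allclose(ours.means_nm, ref.means_.ravel()[order], atol=0.02)
        assert np.allclose(ours.weights, ref.weights_[order], atol=0.02)

    def test_histogram_backend_agrees_on_planted_fixture(self):
        spec = default_mixture_spec()
        x = sample_mixture(spec, 3000, seed=13)
        em = fit_gaussian_mixture(x, K=3, n_restarts=10, seed=3)
        hist = fit_gaussian_sum_histogram(x, K=3)
        assert np.allclose(em.means_nm, hist.means_nm, atol=0.05)
        assert np.allclose(em.weights, hist.weights, atol=0.05)

    def test_location_equivariance(self):
        x = sample_mixture(default_mixture_spec(), 800, seed=5)
        a = fit_gaussian_mixture(x, K=3, n_restarts=5, seed=4)
        b = fit_gaussian_mixture(x + 10.0, K=3, n_restarts=5, seed=4)
        assert np.allclose(b.means_nm, a.means_nm + 10.0, atol=1e-6)
        assert np.allclose(b.weights, a.weights, atol=1e-6)

    def test_means_always_ascending(self):
        x = sample_mixture(default_mixture_spec(), 600, seed=6)
        for seed in range(5):
            fit = fit_gaussian_mixture(x, K=3, n_restarts=2, seed=seed)
            assert np.all(np.diff(fit.means_nm) >= 0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(UsageError):
            fit_gaussian_mixture([1.0, 2.0, 3.0], K=2)

    def test_identical_samples_degenerate(self):
        with pytest.raises(FitError):
            fit_gaussian_mixture(np.full(30, 2.0), K=2, n_restarts=3, seed=0)

    def test_k_sweep_prefers_three_components(self):
        x = sample_mixture(default_mixture_spec(), 1200, seed=9)
        sweep = mixture_k_sweep(x, k_range=range(1, 5), seed=0, n_restarts=3)
        best = min(sweep, key=lambda k: sweep[k][1])
        assert best == 3


class TestAnalyzeField:
    def test_empty_field_no_fit(self):
        field = HeightField(np.zeros((30, 30)), 1.0)
        with pytest.warns(UserWarning):
            measurements, fit = analyze_field(field, K=3)
        assert measurements == []
        assert fit is None

    def test_batch_closure_recovers_planted_means(self):
        from membmode.synthetic_data import simulate_afm_batch

        spec = default_mixture_spec()
        fields, truth = simulate_afm_batch(spec, 600, 6, seed=5, field_nm=400.0)
        measurements, fit = analyze_fields(fields, K=3, seed=2)
        assert len(measurements) == 600
        assert np.all(np.diff(fit.means_nm) > 0)
        assert np.allclose(fit.means_nm, [1.74, 2.37, 2.90], atol=0.05)
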