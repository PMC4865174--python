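"""Indicator-function decomposition and Gaussian smoothing."""

import numpy as np
import pytest

from oisi import denoising as dn
from oisi import preprocessing as pp


def maps_from_rows(rows, shape):
    return [pp.ResponseMap(values=r.reshape(shape)) for r in rows]


def white_noise_maps(rng, n, shape, sd=1.0):
    return maps_from_rows(rng.normal(0.0, sd, size=(n, shape[0] * shape[1])), shape)


class TestGifFit:
    def test_planted_pattern_recovered(self):
        """A fixed spatial pattern at varying amplitude dominates white noise."""
        rng = np.random.default_rng(0)
        shape = (10, 10)
        q = rng.normal(size=100)
        q /= np.linalg.norm(q)
        amplitudes = np.linspace(-2, 2, 12)
        signal = maps_from_rows(np.outer(amplitudes, q), shape)
        noise = white_noise_maps(rng, 40, shape)
        basis = dn.gif_fit(signal, noise)
        assert basis.n_retained >= 1
        # the activation pattern (metric image of the leading filter) is what
        # the component looks like in image space
        lead = basis.metric_patterns[0].ravel()
        r = np.corrcoef(lead, q)[0, 1]
        assert abs(r) >= 0.99

    def test_identity_noise_metric_reduces_to_pca(self):
        """With C_N = I the generalized problem is plain PCA of the signal ensemble."""
        rng = np.random.default_rng(1)
        shape = (5, 5)
        p = 25
        signal_rows = rng.normal(size=(8, p))
        signal = maps_from_rows(signal_rows, shape)
        # centered noise ensemble with sample covariance exactly I:
        # rows {c e_i, -c e_i} give C_N = 2 c^2 / (2p - 1) I
        c = np.sqrt((2 * p - 1) / 2.0)
        noise_rows = np.concatenate([c * np.eye(p), -c * np.eye(p)])
        noise = maps_from_rows(noise_rows, shape)
        basis = dn.gif_fit(signal, noise, eps_scale=0.0, retain_threshold=0.0)

        centered = signal_rows - signal_rows.mean(axis=0)
        cov = centered.T @ centered / (len(signal_rows) - 1)
        pca_vals, pca_vecs = np.linalg.eigh(cov)
        pca_vals, pca_vecs = pca_vals[::-1], pca_vecs[:, ::-1]
        k = 7  # rank of the centered 8-sample ensemble
        np.testing.assert_allclose(basis.eigenvalues[:k], pca_vals[:k], atol=1e-8)
        for i in range(basis.n_retained):
            cos = abs(basis.patterns[i].ravel() @ pca_vecs[:, i])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_identical_signal_maps_retain_nothing(self):
        rng = np.random.default_rng(2)
        shape = (4, 4)
        m = pp.ResponseMap(values=rng.normal(size=shape))
        signal = [pp.ResponseMap(values=m.values.copy()) for _ in range(5)]
        noise = white_noise_maps(rng, 20, shape)
        basis = dn.gif_fit(signal, noise)
        assert basis.n_retained == 0
        out = dn.gif_filter(signal[0], basis)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)  # ensemble mean

    def test_too_few_maps_rejected(self):
        rng = np.random.default_rng(3)
        one = white_noise_maps(rng, 1, (3, 3))
        many = white_noise_maps(rng, 5, (3, 3))
        with pytest.raises(ValueError, match="at least 2"):
            dn.gif_fit(one, many)
        with pytest.raises(ValueError, match="at least 2"):
            dn.gif_fit(many, one)

    def test_eigen_residuals_within_tolerance(self):
        """Every retained pair solves C_S v = lambda (C_N + eps I) v to <= 1e-6."""
        rng = np.random.default_rng(4)
        shape = (8, 8)
        signal = white_noise_maps(rng, 10, shape, sd=2.0)
        noise = white_noise_maps(rng, 30, shape)
        basis = dn.gif_fit(signal, noise, retain_threshold=0.0)
        assert basis.n_retained > 0
        assert np.all(basis.residuals <= 1e-6)

    def test_snapshot_and_dense_solutions_agree(self):
        """Exact agreement of the two solvers on a problem small enough for both."""
        rng = np.random.default_rng(5)
        shape = (20, 20)  # 400 pixels
        q = rng.normal(size=400)
        signal_rows = np.outer(np.linspace(-1, 1, 10), q) + 0.05 * rng.normal(size=(10, 400))
        signal = maps_from_rows(signal_rows, shape)
        noise = white_noise_maps(rng, 80, shape)
        snap = dn.gif_fit(signal, noise, method="snapshot", retain_threshold=0.0)
        dense = dn.gif_fit(signal, noise, method="dense", retain_threshold=0.0)
        k = 3
        np.testing.assert_allclose(
            snap.eigenvalues[:k], dense.eigenvalues[:k], rtol=1e-8
        )
        for i in range(min(k, snap.n_retained, dense.n_retained)):
            v_s = snap.patterns[i].ravel()
            v_d = dense.patterns[i].ravel()
            cos = abs(v_s @ v_d) / (np.linalg.norm(v_s) * np.linalg.norm(v_d))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_basis_io_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        signal = white_noise_maps(rng, 6, (5, 5), sd=3.0)
        noise = white_noise_maps(rng, 20, (5, 5))
        basis = dn.gif_fit(signal, noise, retain_threshold=0.0)
        path = tmp_path / "basis.h5"
        dn.save_gif_basis(basis, path)
        loaded = dn.load_gif_basis(path)
        np.testing.assert_array_equal(loaded.eigenvalues, basis.eigenvalues)
        np.testing.assert_array_equal(loaded.patterns, basis.patterns)
        assert loaded.eps == basis.eps


class TestGifFilter:
    def _fitted_basis(self):
        rng = np.random.default_rng(7)
        shape = (6, 6)
        q1 = rng.normal(size=36)
        q2 = rng.normal(size=36)
        rows = np.outer(np.linspace(-1, 1, 8), q1) + np.outer(
            np.sin(np.arange(8)), q2
        )
        signal = maps_from_rows(rows, shape)
        noise = white_noise_maps(rng, 30, shape)
        return dn.gif_fit(signal, noise, retain_threshold=0.0), signal, shape

    def test_map_in_retained_pattern_span_reproduced(self):
        basis, signal, shape = self._fitted_basis()
        assert basis.n_retained >= 2
        A = basis.metric_patterns.reshape(basis.n_retained, -1)
        x = 0.7 * A[0] + 1.3 * A[1]
        m = pp.ResponseMap(values=basis.mean_map + x.reshape(shape))
        out = dn.gif_filter(m, basis)
        np.testing.assert_allclose(out.values, m.values, atol=1e-8)
        assert out.stage == pp.STAGE_DENOISED

    def test_component_free_map_returns_ensemble_mean(self):
        """A map no retained filter responds to is replaced by the ensemble mean."""
        basis, signal, shape = self._fitted_basis()
        V = basis.patterns.reshape(basis.n_retained, -1)
        rng = np.random.default_rng(8)
        x = rng.normal(size=V.shape[1])
        # remove every filter's response (Gram matrix solve keeps x unchanged otherwise)
        coeffs = np.linalg.solve(V @ V.T, V @ x)
        x -= V.T @ coeffs
        assert np.allclose(V @ x, 0.0, atol=1e-10)
        m = pp.ResponseMap(values=basis.mean_map + x.reshape(shape))
        out = dn.gif_filter(m, basis)
        np.testing.assert_allclose(out.values, basis.mean_map, atol=1e-8)

    def test_idempotent(self):
        basis, signal, shape = self._fitted_basis()
        m = signal[3]
        once = dn.gif_filter(m, basis)
        twice = dn.gif_filter(once, basis)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        basis, _, _ = self._fitted_basis()
        with pytest.raises(ValueError, match="dimensions"):
            dn.gif_filter(pp.ResponseMap(values=np.ones((3, 3))), basis)

    def test_filtering_reduces_mse_on_planted_pattern(self):
        """At per-pixel SNR 0.5, projection beats the unfiltered map (10 seeds).

        The ensemble is sized so the snapshot count exceeds the pixel count
        over 2: the lambda > 1 rule then separates the planted component
        from sampling noise.
        """
        shape = (5, 5)
        p = shape[0] * shape[1]
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            q = rng.normal(size=p)
            q /= np.linalg.norm(q)
            amplitudes = rng.normal(0.0, np.sqrt(0.5 * p), size=16)
            clean_rows = np.outer(amplitudes, q)
            noisy_rows = clean_rows + rng.normal(size=(16, p))
            signal = maps_from_rows(noisy_rows, shape)
            noise = white_noise_maps(rng, 60, shape)
            basis = dn.gif_fit(signal, noise)
            i = 3
            filtered = dn.gif_filter(signal[i], basis)
            mse_f = np.mean((filtered.values.ravel() - clean_rows[i]) ** 2)
            mse_r = np.mean((noisy_rows[i] - clean_rows[i]) ** 2)
            wins += mse_f < mse_r
        assert wins >= 8


class TestPermutationNull:
    def test_null_level_flags_stimulus_locked_structure(self):
        """The true fit's leading eigenvalue clears the trial-shuffled null."""
        rng = np.random.default_rng(9)
        shape = (8, 8)
        p = 64
        q = rng.normal(size=p)
        q /= np.linalg.norm(q)
        n_cond, n_rep = 6, 8
        amps = np.linspace(0.5, 3.0, n_cond)
        trials = []
        for a in amps:
            rows = a * q + rng.normal(0.0, 0.4, size=(n_rep, p))
            trials.extend(maps_from_rows(rows, shape))
        means, residuals = [], []
        for c in range(n_cond):
            grp = trials[c * n_rep : (c + 1) * n_rep]
            mean = np.mean([m.values for m in grp], axis=0)
            means.append(pp.ResponseMap(values=mean))
            residuals.extend(pp.ResponseMap(values=m.values - mean) for m in grp)
        basis = dn.gif_fit(means, residuals)
        null = dn.permutation_null_lambda(trials, n_cond, np.random.default_rng(0))
        assert basis.eigenvalues[0] > null

    def test_uneven_groups_rejected(self):
        maps = white_noise_maps(np.random.default_rng(10), 10, (4, 4))
        with pytest.raises(ValueError, match="divide evenly"):
            dn.permutation_null_lambda(maps, 3, np.random.default_rng(0))


class TestGaussianSmooth:
    def test_constant_map_preserved(self):
        """A normalized kernel passes constants through (to rounding)."""
        m = pp.ResponseMap(values=np.full((16, 16), 0.998))
        out = dn.gaussian_smooth(m, 3.0)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-14)
        assert out.stage == pp.STAGE_SMOOTHED

    def test_impulse_peak_matches_continuous_gaussian(self):
        """Central impulse response peak = 1/(2 pi sd^2) within discretization error."""
        values = np.zeros((31, 31))
        values[15, 15] = 1.0
        out = dn.gaussian_smooth(pp.ResponseMap(values=values), 3.0)
        expected = 1.0 / (2.0 * np.pi * 9.0)
        assert out.values[15, 15] == pytest.approx(expected, rel=0.01)

    def test_tiny_sd_is_near_identity(self):
        rng = np.random.default_rng(11)
        m = pp.ResponseMap(values=rng.random((10, 10)))
        out = dn.gaussian_smooth(m, 0.1)
        np.testing.assert_allclose(out.values, m.values, atol=1e-6)

    def test_never_increases_max_norm_of_nonnegative_map(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            m = pp.ResponseMap(values=rng.random((12, 12)))
            out = dn.gaussian_smooth(m, 2.0)
            assert out.values.max() <= m.values.max() + 1e-12

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            dn.gaussian_smooth(pp.ResponseMap(values=np.ones((4, 4))), 0.0)
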