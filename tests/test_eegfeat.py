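"""Feature-family oracles: CSP algebra, wavelet energies, nonlinear measures."""

import numpy as np
import pytest

from neurointent.eegfeat import (EEGFeatureExtractor, csp_fit,
                                 default_filter_bank, fbcsp_features,
                                 fractal_dimension, nonlinear_features,
                                 regularized_covariance, sample_entropy,
                                 spectral_entropy, wpd_energy, wpd_leaf_bands)

FS = 250.0


def naive_sample_entropy(x, m, r):
    """Brute-force O(N^2) template counting (independent oracle)."""
    x = np.asarray(x, float)
    n = len(x)

    def count(mm):
        total = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + d] - x[j + d]) for d in range(mm)) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    return -np.log(a / b)


class TestCSP:
    def test_2x2_closed_form(self):
        # eigenvalues of C1 against C1+C2 for diag(2,1) vs diag(1,2): 2/3, 1/3
        C1, C2 = np.diag([2.0, 1.0]), np.diag([1.0, 2.0])
        W = csp_fit(C1, C2, k=2)
        lam = np.diag(W.T @ C1 @ W) / np.diag(W.T @ (C1 + C2) @ W)
        assert np.allclose(sorted(lam, reverse=True), [2 / 3, 1 / 3], atol=1e-12)
        assert abs(W[1, 0]) < 1e-12  # first filter along channel-1 axis

    def test_equal_covariances_give_half(self, rng):
        A = rng.standard_normal((4, 4))
        C = A @ A.T + np.eye(4)
        W = csp_fit(C, C, k=4)
        lam = np.diag(W.T @ C @ W) / np.diag(W.T @ (2 * C) @ W)
        assert np.allclose(lam, 0.5, atol=1e-10)

    def test_whitening_constraint(self, rng):
        # W'(C1+C2)W = I, checked by direct matrix product
        A, B = rng.standard_normal((5, 5)), rng.standard_normal((5, 5))
        C1 = A @ A.T + 0.1 * np.eye(5)
        C2 = B @ B.T + 0.1 * np.eye(5)
        W = csp_fit(C1, C2, k=5)
        assert np.allclose(W.T @ (C1 + C2) @ W, np.eye(5), atol=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            csp_fit(np.eye(3), np.eye(2))


class TestFBCSP:
    def test_default_bank_has_11_bands(self):
        bank = default_filter_bank()
        assert len(bank) == 11
        assert bank[0] == (8.0, 12.0) and bank[-1] == (28.0, 32.0)

    def test_output_dimension_44(self, rng):
        x = rng.standard_normal((24, 6, 500))
        y = np.arange(24) % 4
        feats, models = fbcsp_features(x, y, FS)
        assert feats.shape == (24, 44)
        assert len(models) == 11

    def test_per_band_normalization_identity(self, rng):
        x = rng.standard_normal((16, 5, 500))
        feats, _ = fbcsp_features(x, np.arange(16) % 4, FS)
        for b in range(11):
            band = feats[:, 4 * b:4 * (b + 1)]
            assert np.allclose(np.exp(band).sum(axis=1), 1.0, atol=1e-12)

    def test_scale_invariance_of_test_trials(self, rng):
        x = rng.standard_normal((16, 5, 500))
        y = np.arange(16) % 4
        _, models = fbcsp_features(x, y, FS)
        f1, _ = fbcsp_features(x, None, FS, models=models)
        f2, _ = fbcsp_features(3.7 * x, None, FS, models=models)
        assert np.allclose(f1, f2, atol=1e-9)


class TestWPD:
    def test_zero_signal_zero_energy(self):
        assert np.all(wpd_energy(np.zeros(256)) == 0)

    def test_parseval_energy_conservation(self, rng):
        x = rng.standard_normal(500)
        energies = wpd_energy(x, all_leaves=True)
        assert energies.shape == (1, 32)
        assert energies.sum() == pytest.approx(np.sum(x ** 2), rel=1e-6)

    def test_selected_energy_bounded_by_total(self, rng):
        x = rng.standard_normal((3, 500))
        sel = wpd_energy(x)
        assert sel.shape == (3, 6)
        assert np.all(sel.sum(axis=1) <= np.sum(x ** 2, axis=1) * (1 + 1e-9))

    def test_10hz_sine_lands_in_first_selected_leaf(self):
        # leaf band edges from the frequency-ordered decomposition
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 10 * t)
        energies = wpd_energy(x, all_leaves=True)[0]
        bands = wpd_leaf_bands(FS)
        lo, hi = bands[np.argmax(energies)]
        assert lo <= 10.0 <= hi
        assert (lo, hi) == (pytest.approx(125 / 16), pytest.approx(125 * 3 / 32))

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            wpd_energy(np.zeros(16), level=5)


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.ones(60), m=2, r=0.5) == 0.0

    def test_periodic_matches_bruteforce(self):
        x = np.tile([1.0, 2.0, 3.0], 33)
        r = 0.5 * np.std(x)
        assert sample_entropy(x, 2, r) == pytest.approx(
            naive_sample_entropy(x, 2, r), abs=1e-12)

    def test_noise_matches_bruteforce(self, rng):
        x = rng.uniform(size=200)
        r = 0.2 * np.std(x)
        assert sample_entropy(x, 2, r) == pytest.approx(
            naive_sample_entropy(x, 2, r), abs=1e-12)

    def test_noise_exceeds_sine(self, rng):
        t = np.arange(300) / FS
        sine = np.sin(2 * np.pi * 10 * t)
        noise = rng.standard_normal(300)
        noise *= sine.std() / noise.std()
        r = 0.2 * sine.std()
        assert sample_entropy(noise, 2, r) > sample_entropy(sine, 2, r)


class TestSpectralEntropy:
    def test_flat_eight_bin_spectrum_is_three_bits(self):
        # eight equal-power cosines at exact periodogram bins
        n = 64
        t = np.arange(n)
        x = sum(np.cos(2 * np.pi * k * t / n) for k in range(4, 12))
        assert spectral_entropy(x, FS) == pytest.approx(3.0, abs=1e-9)

    def test_single_bin_is_zero(self):
        t = np.arange(128)
        x = np.cos(2 * np.pi * 16 * t / 128)
        assert spectral_entropy(x, FS) == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_summation(self, rng):
        from scipy.signal import periodogram
        x = rng.standard_normal(400)
        _, pxx = periodogram(x, fs=FS)
        p = pxx / pxx.sum()
        expected = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert spectral_entropy(x, FS) == pytest.approx(expected, abs=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy(np.zeros(100), FS)


class TestFractalDimension:
    def test_line_has_dimension_one(self):
        assert fractal_dimension(np.arange(1000.0), 8) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_near_two(self, rng):
        assert fractal_dimension(rng.standard_normal(1000), 8) == pytest.approx(
            2.0, abs=0.1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.ones(100), 8)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    x = rng.standard_normal((32, 15, 500))
    y = np.arange(32) % 4
    ext = EEGFeatureExtractor(fs=FS).fit(x, y)
    return ext, x


class TestAssembly:

    def test_raw_width_179_at_defaults(self, fitted):
        ext, x = fitted
        assert ext.n_raw_features_ == 44 + 90 + 45
        blocks = ext.block_slices_
        assert blocks["fbcsp"] == slice(0, 44)
        assert blocks["wpd"] == slice(44, 134)
        assert blocks["nonlinear"] == slice(134, 179)

    def test_train_transform_standardized(self, fitted):
        ext, x = fitted
        z = ext.transform(x)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_pca_variance_retained(self, fitted):
        ext, _ = fitted
        assert ext.pca_.explained_variance_ratio_.sum() >= 0.95

    def test_unfitted_transform_rejected(self):
        with pytest.raises(Exception):
            EEGFeatureExtractor(fs=FS).transform(np.zeros((2, 15, 500)))

    def test_width_mismatch_rejected(self, fitted):
        ext, _ = fitted
        with pytest.raises(ValueError):
            ext.transform(np.random.default_rng(0).standard_normal((2, 9, 500)))

    def test_nonlinear_block_layout(self, rng):
        x = rng.standard_normal((4, 500))
        f = nonlinear_features(x, FS)
        assert f.shape == (12,)
        assert f[0] == pytest.approx(
            sample_entropy(x[0], 2, 0.2 * x[0].std()), abs=1e-12)
        assert f[4] == pytest.approx(spectral_entropy(x[0], FS), abs=1e-12)
        assert f[8] == pytest.approx(fractal_dimension(x[0], 8), abs=1e-12)

    def test_determinism(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((16, 5, 500))
        y = np.arange(16) % 4
        z1 = EEGFeatureExtractor(fs=FS).fit(x, y).transform(x)
        z2 = EEGFeatureExtractor(fs=FS).fit(x, y).transform(x)
        assert np.array_equal(z1, z2)
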