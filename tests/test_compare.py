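"""Similarity metrics, ROI spectra, wavelength matching, IQR summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hscompare import compare as cmp
from hscompare.cube import HyperCube

positive_spectra = hnp.arrays(
    float, (12,), elements=st.floats(0.01, 10.0, allow_nan=False))


class TestMinmaxNormalize:
    def test_simple_triple(self):
        out, deg = cmp.minmax_normalize(np.array([0.2, 0.4, 0.6]))
        assert np.allclose(out, [0.0, 0.5, 1.0])
        assert not deg

    def test_constant_spectrum_flagged_zero(self):
        out, deg = cmp.minmax_normalize(np.array([0.3, 0.3, 0.3]))
        assert np.allclose(out, 0.0)
        assert deg

    def test_idempotent(self):
        x = np.array([0.1, 0.9, 0.5, 0.4])
        once, _ = cmp.minmax_normalize(x)
        twice, _ = cmp.minmax_normalize(once)
        assert np.allclose(once, twice)

    def test_per_pixel_independence(self):
        px = np.array([[0.0, 1.0, 2.0], [10.0, 30.0, 20.0]])
        out, _ = cmp.minmax_normalize(px)
        assert np.allclose(out[0], [0.0, 0.5, 1.0])
        assert np.allclose(out[1], [0.0, 1.0, 0.5])

    def test_single_band_raises(self):
        with pytest.raises(ValueError):
            cmp.minmax_normalize(np.array([1.0]))


class TestRoiExtraction:
    @staticmethod
    def _cube():
        rng = np.random.default_rng(0)
        return HyperCube(rng.random((6, 7, 4)), np.arange(4.0))

    def test_values_match_coordinates(self):
        cube = self._cube()
        pixels = [(0, 0), (3, 2), (5, 6)]
        table = cmp.extract_roi_pixels(cube, pixels)
        assert table.shape == (3, 4)
        for i, (r, c) in enumerate(pixels):
            assert np.array_equal(table[i], cube.data[r, c])

    def test_empty_list(self):
        assert cmp.extract_roi_pixels(self._cube(), []).shape == (0, 4)

    def test_out_of_bounds_raises(self):
        with pytest.raises(IndexError):
            cmp.extract_roi_pixels(self._cube(), [(6, 0)])


class TestSubsample:
    def test_deterministic_given_seed(self):
        pool = [(i, j) for i in range(9) for j in range(9)]
        a = cmp.subsample_pixels(pool, 25, seed=5)
        b = cmp.subsample_pixels(pool, 25, seed=5)
        assert a == b
        assert len(set(a)) == 25
        assert set(a) <= set(pool)

    def test_full_sample(self):
        pool = [(0, i) for i in range(10)]
        assert sorted(cmp.subsample_pixels(pool, 10, seed=0)) == sorted(pool)

    def test_distinct_seeds_usually_differ(self):
        pool = [(i, j) for i in range(9) for j in range(9)]
        pairs = [(2 * k, 2 * k + 1) for k in range(10)]
        diffs = sum(cmp.subsample_pixels(pool, 25, a) != cmp.subsample_pixels(pool, 25, b)
                    for a, b in pairs)
        assert diffs >= 9

    def test_oversample_raises(self):
        with pytest.raises(ValueError):
            cmp.subsample_pixels([(0, 0)], 2, seed=0)


class TestMeanStdSpectrum:
    def test_single_pixel(self):
        px = np.array([[0.1, 0.2, 0.3]])
        s = cmp.mean_std_spectrum(px, np.arange(3.0))
        assert np.allclose(s.mean, px[0])
        assert np.allclose(s.sd, 0.0)

    def test_two_pixel_mean(self):
        px = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = cmp.mean_std_spectrum(px, np.arange(2.0))
        assert np.allclose(s.mean, [0.5, 0.5])

    def test_normalization_increases_sd_for_varying_brightness(self):
        """ROI pixels share one spectral shape of limited dynamic range at
        slightly different brightness; per-pixel min-max normalization
        stretches that small range onto [0, 1], amplifying the noise and
        raising the mean per-band SD."""
        rng = np.random.default_rng(0)
        shape = 0.3 + 0.1 * (1 + np.sin(np.arange(30) / 4))  # spans ~[0.3, 0.5]
        px = np.array([
            b * shape + rng.normal(0, 0.01, 30)
            for b in rng.uniform(0.9, 1.1, 25)
        ])
        raw = cmp.mean_std_spectrum(px, np.arange(30.0))
        norm = cmp.mean_std_spectrum(px, np.arange(30.0), normalize_first=True)
        assert norm.sd.mean() > raw.sd.mean()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cmp.mean_std_spectrum(np.empty((0, 3)), np.arange(3.0))


class TestMatchWavelengths:
    def test_snapshot_vs_linescan_gives_25_pairs(self):
        a = np.linspace(659.95, 951.42, 25)
        b = np.linspace(365.0, 1004.0, 394)
        pairing = cmp.match_wavelengths(a, b)
        assert len(pairing) == 25
        # every pair is the true nearest neighbour
        for i, (j, la) in enumerate(zip(pairing.index_b, a)):
            assert j == np.abs(b - la).argmin()

    def test_identical_grids_identity(self):
        g = np.linspace(400, 900, 20)
        pairing = cmp.match_wavelengths(g, g)
        assert np.array_equal(pairing.index_b, np.arange(20))
        assert np.allclose(pairing.delta, 0.0)

    def test_midpoint_tie_breaks_low(self):
        a = np.array([500.0])
        b = np.array([499.0, 501.0])
        pairing = cmp.match_wavelengths(a, b)
        assert pairing.index_b[0] == 0

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            cmp.match_wavelengths(np.array([]), np.array([1.0]))


class TestMetrics:
    def test_sam_closed_forms(self):
        assert cmp.sam([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0, abs=1e-7)
        assert cmp.sam([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)
        assert cmp.sam([1.0, 1.0], [1.0, 0.0]) == pytest.approx(0.5)

    def test_gfc_closed_forms(self):
        x = np.array([0.3, 0.7, 1.1])
        assert cmp.gfc(x, 3 * x) == pytest.approx(1.0)
        assert cmp.gfc([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_gfc_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(30), rng.random(30)
            direct = abs(sum(a * b for a, b in zip(x, y))) / (
                np.sqrt(sum(a * a for a in x)) * np.sqrt(sum(b * b for b in y)))
            assert abs(cmp.gfc(x, y) - direct) <= 1e-12

    def test_rmse_closed_forms_and_oracle(self):
        assert cmp.rmse([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert cmp.rmse([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        x, y = rng.random(50), rng.random(50)
        loop = np.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / 50)
        assert abs(cmp.rmse(x, y) - loop) <= 1e-12

    def test_pearson_closed_forms_and_oracle(self):
        x = np.arange(10.0)
        assert cmp.pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert cmp.pearson(x, -x) == pytest.approx(-1.0)
        rng = np.random.default_rng(2)
        a, b = rng.random(40), rng.random(40)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        direct = cov / (a.std() * b.std())
        assert cmp.pearson(a, b) == pytest.approx(direct, abs=1e-12)
        with pytest.raises(ValueError):
            cmp.pearson(np.ones(5), x[:5])

    def test_zero_vector_errors(self):
        with pytest.raises(ZeroDivisionError):
            cmp.sam([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ZeroDivisionError):
            cmp.gfc([0.0, 0.0], [1.0, 1.0])

    @settings(max_examples=50, derandomize=True)
    @given(x=positive_spectra, y=positive_spectra,
           alpha=st.floats(0.01, 100.0))
    def test_sam_gfc_symmetry_and_scale_invariance(self, x, y, alpha):
        assert cmp.sam(x, y) == pytest.approx(cmp.sam(y, x), abs=1e-10)
        assert cmp.sam(x, alpha * y) == pytest.approx(cmp.sam(x, y), abs=1e-7)
        assert cmp.gfc(x, y) == pytest.approx(cmp.gfc(y, x), abs=1e-10)
        assert cmp.gfc(x, alpha * y) == pytest.approx(cmp.gfc(x, y), abs=1e-7)

    @settings(max_examples=50, derandomize=True)
    @given(x=positive_spectra, y=positive_spectra, z=positive_spectra)
    def test_rmse_triangle_inequality(self, x, y, z):
        assert cmp.rmse(x, z) <= cmp.rmse(x, y) + cmp.rmse(y, z) + 1e-12


class TestCompareCameras:
    @staticmethod
    def _spectrum(mean, normalized=False, camera="snapshot"):
        mean = np.asarray(mean, dtype=float)
        return cmp.Spectrum(np.arange(mean.size, dtype=float), mean,
                            np.zeros_like(mean), n_pixels=25,
                            tissue="healthy", camera=camera, normalized=normalized)

    def test_identical_spectra(self):
        s = self._spectrum([0.2, 0.5, 0.9])
        pairing = cmp.match_wavelengths(s.wavelengths, s.wavelengths)
        rec = cmp.compare_cameras(s, s, pairing)
        assert rec.sam == pytest.approx(0.0, abs=1e-9)
        assert rec.gfc == pytest.approx(1.0)
        assert rec.rmse == pytest.approx(0.0)

    def test_scaled_spectrum_angular_vs_magnitude(self):
        a = self._spectrum([0.2, 0.5, 0.9])
        b = self._spectrum([0.4, 1.0, 1.8], camera="linescan")
        pairing = cmp.match_wavelengths(a.wavelengths, b.wavelengths)
        rec = cmp.compare_cameras(a, b, pairing)
        assert rec.sam == pytest.approx(0.0, abs=1e-9)
        assert rec.gfc == pytest.approx(1.0)
        assert rec.rmse > 0

    def test_mixed_normalization_rejected(self):
        a = self._spectrum([0.2, 0.5, 0.9])
        b = self._spectrum([0.2, 0.5, 0.9], normalized=True)
        pairing = cmp.match_wavelengths(a.wavelengths, b.wavelengths)
        with pytest.raises(ValueError):
            cmp.compare_cameras(a, b, pairing)


class TestSummarizeDistribution:
    def test_worked_example(self):
        s = cmp.summarize_distribution([1, 2, 3, 4, 5])
        assert s.q1 == pytest.approx(2.0)
        assert s.q3 == pytest.approx(4.0)
        assert s.iqr == pytest.approx(2.0)
        assert s.median == pytest.approx(3.0)

    def test_constant_distribution(self):
        s = cmp.summarize_distribution([7.0] * 10)
        assert s.iqr == 0.0

    def test_against_sorting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            v = rng.random(rng.integers(5, 50))
            s = cmp.summarize_distribution(v)
            srt = np.sort(v)

            def quantile(q):
                pos = q * (srt.size - 1)
                lo, hi = int(np.floor(pos)), int(np.ceil(pos))
                frac = pos - lo
                return srt[lo] * (1 - frac) + srt[hi] * frac

            assert s.q1 == pytest.approx(quantile(0.25), abs=1e-12)
            assert s.q3 == pytest.approx(quantile(0.75), abs=1e-12)
            assert s.iqr == pytest.approx(s.q3 - s.q1, abs=1e-12)
            assert s.q1 <= s.median <= s.q3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cmp.summarize_distribution([])
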