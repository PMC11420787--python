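"""Absorbance conversion, Beer–Lambert relations, peak-window matching."""

import math

import numpy as np
import pytest

from hscompare import chromophores as ch
from hscompare import scene as sc
from hscompare.errors import EmptySelectionError, InsufficientBandsError
from hscompare.pipeline import preprocess_linescan


class TestReflectanceToAbsorbance:
    @pytest.mark.parametrize("r, expected", [
        (1.0, 0.0),
        (0.1, 1.0),
        (0.5, math.log10(2.0)),
    ])
    def test_worked_values(self, r, expected):
        out = ch.reflectance_to_absorbance(np.array([r, r]))
        assert out.a[0] == pytest.approx(expected, abs=1e-12)

    def test_round_trip_with_beer_lambert(self):
        """A -> 10^(-A) -> A is the identity over A in [0, 6]."""
        a = np.linspace(0.0, 6.0, 200)
        r = 10.0 ** (-a)
        back = ch.reflectance_to_absorbance(r)
        assert np.abs(back.a - a).max() <= 1e-10

    def test_nonpositive_values_floored_and_flagged(self):
        out = ch.reflectance_to_absorbance(np.array([0.5, 0.0, -0.1]))
        assert out.clipped.tolist() == [False, True, True]
        assert out.a[1] == pytest.approx(6.0)  # -log10(1e-6)

    def test_all_nonpositive_raises(self):
        with pytest.raises(Exception):
            ch.reflectance_to_absorbance(np.array([0.0, -1.0]))


class TestExtinctionToAbsorption:
    def test_unit_extinction_whole_blood(self):
        """eps = 1, c = 150 g/L, M = 64500 g/mol -> mu_a = ln(10)*150/64500."""
        eps = ch.ChromophoreSpectrum("Hb", np.array([500.0, 600.0]),
                                     np.array([1.0, 1.0]),
                                     unit_kind="molar_extinction")
        mu = ch.extinction_to_absorption(eps, 150.0, 64500.0)
        assert mu.values[0] == pytest.approx(5.3549e-3, rel=1e-4)
        assert mu.unit_kind == "absorption_coefficient"

    def test_zero_extinction(self):
        eps = ch.ChromophoreSpectrum("x", np.array([500.0, 600.0]),
                                     np.zeros(2), unit_kind="molar_extinction")
        assert np.allclose(ch.extinction_to_absorption(eps).values, 0.0)

    def test_linearity_in_epsilon(self):
        wl = np.array([500.0, 600.0, 700.0])
        e1 = ch.ChromophoreSpectrum("a", wl, np.array([1.0, 2.0, 3.0]),
                                    unit_kind="molar_extinction")
        e3 = ch.ChromophoreSpectrum("a", wl, 3 * e1.values,
                                    unit_kind="molar_extinction")
        assert np.allclose(ch.extinction_to_absorption(e3).values,
                           3 * ch.extinction_to_absorption(e1).values)

    def test_invalid_constants_raise(self):
        eps = ch.ChromophoreSpectrum("x", np.array([500.0, 600.0]),
                                     np.ones(2), unit_kind="molar_extinction")
        with pytest.raises(ValueError):
            ch.extinction_to_absorption(eps, 0.0, 64500.0)
        with pytest.raises(ValueError):
            ch.extinction_to_absorption(eps, 150.0, -1.0)


class TestBeerLambertAbsorbance:
    def test_worked_value(self):
        mu = ch.ChromophoreSpectrum("x", np.array([700.0, 800.0]),
                                    np.array([2.0, 2.0]))
        out = ch.absorbance_from_beer_lambert(mu, 0.5)
        assert np.allclose(out.a, 1.0)

    def test_doubling_path_doubles_absorbance(self):
        mu = ch.ChromophoreSpectrum("x", np.array([700.0, 800.0]),
                                    np.array([1.3, 0.4]))
        a1 = ch.absorbance_from_beer_lambert(mu, 0.7)
        a2 = ch.absorbance_from_beer_lambert(mu, 1.4)
        assert np.allclose(a2.a, 2 * a1.a)

    def test_small_path_limit(self):
        mu = ch.ChromophoreSpectrum("x", np.array([700.0, 800.0]),
                                    np.array([5.0, 5.0]))
        assert ch.absorbance_from_beer_lambert(mu, 1e-9).a.max() < 1e-8

    def test_nonpositive_path_raises(self):
        mu = ch.ChromophoreSpectrum("x", np.array([700.0, 800.0]), np.ones(2))
        with pytest.raises(ValueError):
            ch.absorbance_from_beer_lambert(mu, 0.0)


class TestPeakWindow:
    def test_interior_peak_gives_31_bands(self, library):
        idx = ch.extract_peak_window(library["HbO2"], 576.0)
        assert idx.size == 31
        wl = library["HbO2"].wavelengths[idx]
        assert wl[0] <= 576.0 <= wl[-1]

    def test_edge_peak_truncated_one_sided(self):
        grid = np.arange(400.0, 500.0, 1.0)
        chrom = ch.ChromophoreSpectrum("x", grid, np.ones(grid.size))
        idx = ch.extract_peak_window(chrom, 400.0)
        assert idx.size == 16
        assert idx[0] == 0

    def test_window_contiguous_and_contains_peak(self, library):
        idx = ch.extract_peak_window(library["water"], 976.0)
        assert np.array_equal(np.diff(idx), np.ones(idx.size - 1, dtype=int))
        peak_idx = np.abs(library["water"].wavelengths - 976.0).argmin()
        assert peak_idx in idx

    def test_peak_outside_grid_raises(self, library):
        with pytest.raises(ValueError):
            ch.extract_peak_window(library["water"], 1200.0)


class TestMatchWindowToCamera:
    def test_coarse_camera_fewer_bands_pigeonhole(self):
        window = np.arange(700.0, 731.0, 1.0)  # 31 x 1 nm
        camera = np.arange(660.0, 960.0, 12.0)  # ~12 nm spacing
        idx = ch.match_window_to_camera(window, camera)
        assert idx.size < window.size
        assert np.array_equal(idx, np.unique(idx))

    def test_identity_grid_no_dedup_loss(self):
        grid = np.arange(700.0, 731.0, 1.0)
        idx = ch.match_window_to_camera(grid, grid)
        assert np.array_equal(idx, np.arange(grid.size))

    def test_narrow_nir_window_vs_snapshot_grid_brute_force(self, library):
        """A 31 nm fat-peak window maps to very few snapshot bands; the
        count must match a brute-force nearest-neighbour enumeration."""
        snap = sc.snapshot_camera()
        idx_win = ch.extract_peak_window(library["fat"], 756.0)
        window = library["fat"].wavelengths[idx_win]
        idx = ch.match_window_to_camera(window, snap.band_centers)
        brute = sorted({min(range(snap.band_centers.size),
                            key=lambda j: abs(snap.band_centers[j] - wl))
                        for wl in window})
        assert idx.tolist() == brute
        assert idx.size <= 4  # ~12 nm camera spacing over a 31 nm window

    def test_visible_window_unmeasurable_by_snapshot(self, library):
        snap = sc.snapshot_camera()
        idx_win = ch.extract_peak_window(library["cyt_b_red"], 555.0)
        with pytest.raises(EmptySelectionError):
            ch.match_window_to_camera(library["cyt_b_red"].wavelengths[idx_win],
                                      snap.band_centers)


class TestIdentifyPeak:
    def test_scale_invariance(self, library):
        chrom = library["HbO2"]
        grid = np.linspace(400.0, 1000.0, 369)
        window = ch.build_peak_window(chrom, 576.0, grid)
        base = chrom.interp(grid)
        r1 = ch.identify_peak(grid, 2.5 * base, chrom, window)
        r2 = ch.identify_peak(grid, 0.1 * base, chrom, window)
        assert r1.sam_value == pytest.approx(r2.sam_value, abs=1e-9)
        assert r1.sam_value <= 0.05  # matched shape

    def test_flat_spectrum_scores_worse_than_matched(self, library):
        chrom = library["HbO2"]
        grid = np.linspace(400.0, 1000.0, 369)
        window = ch.build_peak_window(chrom, 576.0, grid)
        matched = ch.identify_peak(grid, chrom.interp(grid), chrom, window)
        flat = ch.identify_peak(grid, np.ones(grid.size), chrom, window)
        assert flat.sam_value > matched.sam_value

    def test_too_few_bands_raises(self, library):
        chrom = library["HbO2"]
        grid = np.array([570.0, 580.0])
        window = ch.build_peak_window(chrom, 576.0, grid)
        window.camera_indices = window.camera_indices[:1]
        with pytest.raises(InsufficientBandsError):
            ch.identify_peak(grid, np.ones(2), chrom, window)

    def test_hbo2_phantom_beats_water_phantom_at_576(self, library):
        """Paired simulation: the 576 nm HbO2 peak is found (lower SAM) in
        a hemoglobin-dominated phantom but not in a water-dominated one,
        using the linescan camera."""
        line = sc.linescan_camera(line_length=64)
        sams = {}
        for label, comp in [("hbo2", {"HbO2": 0.02}), ("water", {"water": 2.0})]:
            geom = sc.PhantomGeometry(
                compositions={t: dict(comp) for t in
                              ("healthy", "pathological", "background")},
                flat_mu_a={t: 0.1 for t in ("healthy", "pathological", "background")},
                heterogeneity=0.0, path_length_jitter=0.0)
            scene = sc.generate_phantom(80, 64, geometry=geom, seed=0)
            cap = sc.simulate_linescan_capture(
                scene, line, sc.NoiseModel(seed=0, dark_level=400.0))
            cube = preprocess_linescan(cap)
            mean_refl = cube.data[30:35, 30:35, :].reshape(-1, cube.bands).mean(0)
            absorb = ch.reflectance_to_absorbance(mean_refl, cube.wavelengths)
            window = ch.build_peak_window(library["HbO2"], 576.0, cube.wavelengths)
            sams[label] = ch.identify_peak(
                cube.wavelengths, absorb.a, library["HbO2"], window).sam_value
        assert sams["hbo2"] < sams["water"]


class TestRunChromophoreAnalysis:
    @staticmethod
    def _conditions(library):
        snap = sc.snapshot_camera()
        line_wl = np.linspace(400.0, 1000.0, 369)
        snap_a = np.ones(snap.band_centers.size) * 0.5
        line_a = np.ones(line_wl.size) * 0.5
        out = []
        for tissue in ("healthy", "pathological"):
            for normalized in (False, True):
                out.append(("snapshot", tissue, normalized, snap.band_centers, snap_a))
                out.append(("linescan", tissue, normalized, line_wl, line_a))
        return out

    def test_row_bookkeeping(self, library):
        table = ch.run_chromophore_analysis(self._conditions(library), library)
        # cameras x tissues x normalizations x 21 peaks, unmeasurable kept
        assert len(table) == 2 * 2 * 2 * len(ch.DEFAULT_PEAKS)
        assert len(ch.DEFAULT_PEAKS) == 21

    def test_snapshot_visible_peaks_marked_unmeasurable(self, library):
        """Of the 21 peaks only five lie inside the snapshot range; the
        visible-range peaks (e.g. 422, 542, 576 nm) and the 976 nm water
        peak are flagged unmeasurable rather than dropped."""
        table = ch.run_chromophore_analysis(self._conditions(library), library)
        snap = table[(table.camera == "snapshot") & (table.tissue == "healthy")
                     & (~table.normalized)]
        measurable = snap[snap.measurable]
        assert len(measurable) == 5
        assert set(measurable.peak_nm) == {695.0, 756.0, 830.0, 930.0}
        for peak in (422.0, 542.0, 576.0, 976.0):
            sub = snap[snap.peak_nm == peak]
            assert not sub.measurable.any()
            assert sub.sam.isna().all()

    def test_empty_peak_list(self, library):
        table = ch.run_chromophore_analysis(self._conditions(library), library,
                                            peak_list=[])
        assert len(table) == 0

    def test_unknown_chromophore_raises(self, library):
        with pytest.raises(KeyError):
            ch.run_chromophore_analysis(self._conditions(library), library,
                                        peak_list=[("unobtainium", 500.0)])


class TestCsvRoundTrip:
    def test_library_round_trip(self, tmp_path, library):
        path = tmp_path / "chromophores.csv"
        ch.write_chromophore_csv(library, path)
        back = ch.read_chromophore_csv(path)
        assert set(back) == set(library)
        for name in library:
            assert np.allclose(back[name].values, library[name].values)
            assert back[name].unit_kind == library[name].unit_kind
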