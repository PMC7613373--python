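"""Band grids, Gaussian SRF resampling and the spectral cleaning chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cncmap.bands import (
    BandGrid,
    CoverageError,
    FWHM_TO_SIGMA,
    MaskedSpectrum,
    Spectrum,
    gaussian_resample,
    harmonized_grid,
    harmonized_mask,
    load_sensor_grid,
)
from cncmap.preprocess import (
    ExclusionWindows,
    NOISY_WINDOWS_NM,
    PreprocessConfig,
    despike,
    exclude_windows,
    preprocess_pixel,
    spline_gapfill,
)


class TestBandGrid:
    def test_validation(self):
        with pytest.raises(ValueError):
            BandGrid([500.0, 500.0], [10.0, 10.0])  # not strictly increasing
        with pytest.raises(ValueError):
            BandGrid([500.0, 510.0], [10.0, -1.0])

    def test_csv_roundtrip(self, tmp_path, sensor_grid):
        path = tmp_path / "grid.csv"
        sensor_grid.to_csv(path)
        assert BandGrid.from_csv(path) == sensor_grid

    def test_shipped_table_shape(self, sensor_grid):
        assert len(sensor_grid) == 239
        assert np.all(np.diff(sensor_grid.centers) > 0)


class TestGaussianResample:
    def test_constant_preserved_exactly(self, sensor_grid):
        fine = Spectrum(BandGrid.fine(), np.full(2101, 0.30))
        out = gaussian_resample(fine, sensor_grid)
        np.testing.assert_allclose(out.values, 0.30, rtol=1e-14)

    def test_identity_limit(self):
        centers = np.arange(500.0, 600.0, 1.0)
        fine = Spectrum(
            BandGrid.fine(500, 599, 1.0), np.sin(centers / 17.0) * 0.2 + 0.3
        )
        target = BandGrid(centers, np.full(centers.size, 0.1))
        out = gaussian_resample(fine, target)
        assert np.max(np.abs(out.values - fine.values)) < 1e-6

    def test_spike_weight_matches_quadrature(self):
        """A unit spike at a band center receives exactly its SRF weight."""
        fine_grid = BandGrid.fine(400, 2500, 1.0)
        values = np.zeros(2101)
        center, fwhm = 1000.0, 10.0
        values[600] = 1.0  # 1000 nm
        target = BandGrid([center], [fwhm])
        out = gaussian_resample(Spectrum(fine_grid, values), target)
        sigma = fwhm / FWHM_TO_SIGMA
        w = np.exp(-0.5 * ((fine_grid.centers - center) / sigma) ** 2)
        assert out.values[0] == pytest.approx(1.0 / w.sum(), rel=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(-2, 2), b=st.floats(-2, 2))
    def test_linearity(self, a, b):
        fine_grid = BandGrid.fine(400, 700, 1.0)
        x = fine_grid.centers
        s1 = np.sin(x / 23.0)
        s2 = np.cos(x / 31.0)
        target = BandGrid([450.0, 500.0, 600.0], [12.0, 12.0, 12.0])
        lhs = gaussian_resample(Spectrum(fine_grid, a * s1 + b * s2), target).values
        rhs = (
            a * gaussian_resample(Spectrum(fine_grid, s1), target).values
            + b * gaussian_resample(Spectrum(fine_grid, s2), target).values
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_out_of_coverage_rejected(self):
        fine = Spectrum(BandGrid.fine(400, 1000, 1.0), np.zeros(601))
        with pytest.raises(CoverageError):
            gaussian_resample(fine, BandGrid([1200.0], [10.0]))


class TestHarmonizedGrid:
    def test_shipped_table_retains_207(self, sensor_grid):
        assert len(harmonized_grid(sensor_grid)) == 207

    def test_matches_brute_force_interval_filter(self, sensor_grid):
        c = sensor_grid.centers
        brute = np.array(
            [
                (470 <= w <= 2143)
                and not (1345 <= w <= 1510)
                and not (1795 <= w <= 2000)
                for w in c
            ]
        )
        assert np.array_equal(harmonized_mask(sensor_grid), brute)

    def test_idempotent(self, sensor_grid):
        once = harmonized_grid(sensor_grid)
        assert harmonized_grid(once) == once

    def test_synthetic_regular_grid(self):
        grid = BandGrid(np.arange(400.0, 2501.0, 10.0), np.full(211, 10.0))
        kept = harmonized_grid(grid).centers
        assert kept.min() >= 470 and kept.max() <= 2143
        for lo, hi in ((1345, 1510), (1795, 2000)):
            assert not np.any((kept >= lo) & (kept <= hi))


class TestDespike:
    def test_monotone_untouched(self, sensor_grid):
        ramp = np.linspace(0.05, 0.5, len(sensor_grid))
        assert despike(Spectrum(sensor_grid, ramp)).valid_mask.all()

    def test_spike_above_threshold_masked(self, sensor_grid):
        base = np.linspace(0.1, 0.4, len(sensor_grid))
        v = base.copy()
        v[100] += 0.05
        masked = np.flatnonzero(~despike(Spectrum(sensor_grid, v)).valid_mask)
        assert masked.tolist() == [100]

    def test_dip_masked_too(self, sensor_grid):
        base = np.linspace(0.1, 0.4, len(sensor_grid))
        v = base.copy()
        v[60] -= 0.05
        masked = np.flatnonzero(~despike(Spectrum(sensor_grid, v)).valid_mask)
        assert masked.tolist() == [60]

    def test_below_threshold_retained(self, sensor_grid):
        base = np.linspace(0.1, 0.4, len(sensor_grid))
        v = base.copy()
        v[100] += 0.01
        assert despike(Spectrum(sensor_grid, v)).valid_mask.all()

    def test_needs_three_bands(self):
        with pytest.raises(ValueError):
            despike(Spectrum(BandGrid([500.0, 510.0], [10.0, 10.0]), np.zeros(2)))


class TestExcludeWindows:
    def test_empty_list_is_identity(self, sensor_grid):
        s = Spectrum(sensor_grid, np.linspace(0, 1, len(sensor_grid)))
        assert exclude_windows(s, ()).valid_mask.all()

    def test_window_normalization(self):
        w = ExclusionWindows(((600.0, 700.0), (650.0, 800.0), (900.0, 950.0)))
        assert w.intervals == ((600.0, 800.0), (900.0, 950.0))
        with pytest.raises(ValueError):
            ExclusionWindows(((700.0, 600.0),))

    def test_idempotent(self, sensor_grid):
        s = Spectrum(sensor_grid, np.linspace(0, 1, len(sensor_grid)))
        once = exclude_windows(s, NOISY_WINDOWS_NM)
        twice = exclude_windows(once, NOISY_WINDOWS_NM)
        assert np.array_equal(once.valid_mask, twice.valid_mask)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force_membership(self, seed):
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.uniform(400, 2500, 60))
        centers += np.arange(60) * 1e-3  # enforce strict increase
        grid = BandGrid(centers, np.full(60, 10.0))
        s = Spectrum(grid, rng.uniform(0, 1, 60))
        out = exclude_windows(s, NOISY_WINDOWS_NM)
        brute = np.array(
            [any(lo <= w <= hi for lo, hi in NOISY_WINDOWS_NM) for w in centers]
        )
        assert np.array_equal(~out.valid_mask, brute)


class TestSplineGapfill:
    def test_reproduces_linear_data_in_gap(self, sensor_grid):
        line = 0.1 + 1e-4 * (sensor_grid.centers - 400.0)
        mask = np.ones(len(sensor_grid), dtype=bool)
        mask[100:105] = False
        out = spline_gapfill(MaskedSpectrum(sensor_grid, line, mask), lam=0.0)
        assert np.max(np.abs(out.values - line)) < 1e-8

    def test_zero_smoothing_interpolates(self, clean_sensor_spectrum):
        ms = MaskedSpectrum(clean_sensor_spectrum.grid, clean_sensor_spectrum.values)
        out = spline_gapfill(ms, lam=0.0)
        np.testing.assert_allclose(out.values, clean_sensor_spectrum.values, atol=1e-9)

    def test_too_few_valid_bands(self, sensor_grid):
        mask = np.zeros(len(sensor_grid), dtype=bool)
        mask[:3] = True
        with pytest.raises(ValueError):
            spline_gapfill(MaskedSpectrum(sensor_grid, np.zeros(len(sensor_grid)), mask))


class TestPreprocessPixel:
    def test_smoothing_only_distortion_below_1pct(self, clean_sensor_spectrum):
        """An artifact-free spectrum passes the chain essentially unchanged."""
        cfg = PreprocessConfig(windows=(), smooth_valid_bands=True)
        out = preprocess_pixel(clean_sensor_spectrum, cfg)
        keep = harmonized_mask(clean_sensor_spectrum.grid)
        ref = clean_sensor_spectrum.values[keep]
        rel = np.abs(out.values - ref) / np.maximum(np.abs(ref), 1e-6)
        assert rel.max() < 0.01

    def test_corruption_recovery(self, clean_sensor_spectrum):
        """Spikes plus window noise are repaired: cleaned RMSE < corrupted RMSE."""
        grid = clean_sensor_spectrum.grid
        rng = np.random.default_rng(5)
        corrupt = clean_sensor_spectrum.values.copy()
        corrupt[[30, 80, 150]] += 0.05
        win = ((grid.centers >= 1330) & (grid.centers <= 1490)) | (
            (grid.centers >= 1780) & (grid.centers <= 1960)
        )
        corrupt[win] += rng.normal(0, 0.05, win.sum())
        out = preprocess_pixel(Spectrum(grid, corrupt))
        keep = harmonized_mask(grid)
        ref = clean_sensor_spectrum.values[keep]
        assert len(out.values) == 207
        rmse_clean = np.sqrt(np.mean((out.values - ref) ** 2))
        rmse_corrupt = np.sqrt(np.mean((corrupt[keep] - ref) ** 2))
        assert rmse_clean < rmse_corrupt

    def test_idempotent_on_own_output(self, clean_sensor_spectrum):
        out1 = preprocess_pixel(clean_sensor_spectrum)
        out2 = preprocess_pixel(Spectrum(out1.grid, out1.values))
        assert np.max(np.abs(out2.values - out1.values)) <= 1e-9

    def test_deterministic(self, clean_sensor_spectrum):
        a = preprocess_pixel(clean_sensor_spectrum)
        b = preprocess_pixel(clean_sensor_spectrum)
        assert np.array_equal(a.values, b.values)

    def test_config_roundtrip(self):
        cfg = PreprocessConfig(despike_threshold=0.02, spline_lam=1.5)
        assert PreprocessConfig.from_dict(cfg.to_dict()) == cfg
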