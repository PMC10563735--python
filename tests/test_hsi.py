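"""Hypercube calibration, ROI extraction, band trimming, pretreatments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kiwifusion.hsi import (
    CalibrationError,
    CalibrationPair,
    Hypercube,
    MovingWindowSmoother,
    PreprocessingError,
    ReflectanceSpectrum,
    SamplingError,
    SavitzkyGolayDerivative,
    SpectralGrid,
    StandardNormalVariate,
    calibrate_hypercube,
    extract_roi_spectrum,
    preprocess_spectra,
    read_envi,
    trim_bands,
    trim_spectra_table,
    write_envi,
)


def _small_cube(value=0.5, shape=(12, 12), n_bands=20):
    grid = SpectralGrid(np.linspace(450, 900, n_bands))
    return Hypercube(np.full(shape + (n_bands,), value), grid)


class TestGrid:
    def test_default_grid_has_568_bands_over_400_950(self):
        grid = SpectralGrid.default()
        assert grid.n_bands == 568
        assert grid.wavelengths[0] == 400.0
        assert grid.wavelengths[-1] < 950.0          # half-open upper endpoint

    def test_trim_to_working_range_keeps_465_bands(self):
        assert SpectralGrid.default().trimmed(450, 900).n_bands == 465

    def test_full_range_trim_is_identity(self):
        grid = SpectralGrid.default()
        assert grid.trimmed(0, 1e4).n_bands == grid.n_bands

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            SpectralGrid.default().trimmed(900, 450)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            SpectralGrid(np.array([500.0, 500.0, 510.0]))


class TestCalibration:
    def test_white_target_gives_ones(self):
        cube = _small_cube(0.8)
        refs = CalibrationPair(np.zeros_like(cube.data), cube.data.copy())
        out = calibrate_hypercube(Hypercube(cube.data.copy(), cube.grid), refs)
        np.testing.assert_allclose(out.data, 1.0)
        assert out.calibrated

    def test_dark_target_gives_zeros(self):
        cube = _small_cube(0.2)
        refs = CalibrationPair(cube.data.copy(), cube.data + 1.0)
        out = calibrate_hypercube(Hypercube(cube.data.copy(), cube.grid), refs)
        np.testing.assert_allclose(out.data, 0.0)

    def test_coinciding_references_name_the_pixel(self):
        cube = _small_cube()
        white = cube.data + 1.0
        white[3, 4, 5] = 0.0
        refs = CalibrationPair(np.zeros_like(cube.data), white)
        refs.dark[3, 4, 5] = 0.0
        with pytest.raises(CalibrationError, match=r"\(3, 4, 5\)"):
            calibrate_hypercube(cube, refs)

    def test_calibrate_then_trim_equals_trim_then_calibrate(self):
        rng = np.random.default_rng(0)
        grid = SpectralGrid.default()
        raw = Hypercube(rng.uniform(0.2, 0.8, (4, 4, 568)), grid)
        refs = CalibrationPair(np.full(raw.data.shape, 0.05),
                               np.full(raw.data.shape, 0.95))
        a = trim_bands(calibrate_hypercube(raw, refs))
        mask = grid.trim_mask(450, 900)
        refs_t = CalibrationPair(refs.dark[:, :, mask], refs.white[:, :, mask])
        b = calibrate_hypercube(trim_bands(raw), refs_t)
        np.testing.assert_allclose(a.data, b.data)


class TestRoiExtraction:
    def test_constant_cube_gives_constant_spectrum_any_seed(self):
        cube = _small_cube(0.37)
        mask = np.ones((12, 12), dtype=bool)
        for seed in (0, 1, 99):
            spec = extract_roi_spectrum(cube, mask, seed=seed)
            np.testing.assert_allclose(spec.values, 0.37)

    def test_mean_over_100_pixels(self):
        # one band; value = row index: blocks average exactly their pixels
        grid = SpectralGrid(np.array([500.0, 600.0]))
        data = np.tile(np.arange(12.0)[:, None, None], (1, 12, 2))
        cube = Hypercube(data, grid)
        spec = extract_roi_spectrum(cube, np.ones((12, 12), bool), seed=5)
        # manually recompute from the same seeded placement
        spec2 = extract_roi_spectrum(cube, np.ones((12, 12), bool), seed=5)
        np.testing.assert_array_equal(spec.values, spec2.values)
        assert 0 <= spec.values[0] <= 11

    def test_same_seed_same_placement(self):
        rng = np.random.default_rng(3)
        cube = Hypercube(rng.uniform(size=(15, 15, 5)),
                         SpectralGrid(np.linspace(450, 900, 5)))
        mask = np.ones((15, 15), bool)
        a = extract_roi_spectrum(cube, mask, seed=21)
        b = extract_roi_spectrum(cube, mask, seed=21)
        np.testing.assert_array_equal(a.values, b.values)

    def test_mask_too_small_raises(self):
        cube = _small_cube(shape=(6, 6))
        mask = np.zeros((6, 6), bool)
        mask[:5, :5] = True                     # room for one block only
        with pytest.raises(SamplingError):
            extract_roi_spectrum(cube, mask, n_blocks=4)

    def test_blocks_do_not_overlap(self):
        # 10x10 mask fits exactly four non-overlapping 5x5 blocks
        cube = _small_cube(shape=(10, 10))
        mask = np.ones((10, 10), bool)
        spec = extract_roi_spectrum(cube, mask, n_blocks=4, seed=0)
        assert spec.values.shape == (20,)


class TestPretreatments:
    def test_snv_of_1_2_3(self):
        out = StandardNormalVariate().fit_transform(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out[0], [-1.0, 0.0, 1.0])

    def test_sg1d_of_linear_ramp_is_slope_everywhere(self):
        m = 0.37
        x = m * np.arange(50.0) + 2.0
        out = SavitzkyGolayDerivative().fit_transform(x[None, :])
        np.testing.assert_allclose(out, m, atol=1e-10)

    def test_mws_of_constant_is_identity(self):
        x = np.full((3, 30), 1.7)
        np.testing.assert_allclose(MovingWindowSmoother().fit_transform(x), 1.7)

    def test_snv_constant_row_names_fruit(self):
        df = pd.DataFrame(np.vstack([np.arange(10.0), np.full(10, 2.0)]),
                          index=["good", "flat"])
        with pytest.raises(PreprocessingError, match="flat"):
            preprocess_spectra(df, "SNV")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            preprocess_spectra(np.ones((2, 10)), "MSC")

    def test_dataframe_keeps_index_and_columns(self, small_bundle):
        out = preprocess_spectra(small_bundle.spectra, "MWS")
        assert out.index.equals(small_bundle.spectra.index)
        assert out.columns.equals(small_bundle.spectra.columns)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_snv_rows_have_zero_mean_unit_sample_sd(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 30)) * rng.uniform(0.5, 3) + rng.uniform(-2, 2)
        out = StandardNormalVariate().fit_transform(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_mws_never_increases_variance_of_noise(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 100))
        out = MovingWindowSmoother().fit_transform(X)
        assert (out.var(axis=1) <= X.var(axis=1)).all()

    def test_too_few_bands_rejected(self):
        with pytest.raises(PreprocessingError):
            MovingWindowSmoother().fit_transform(np.ones((2, 3)))


class TestTables:
    def test_trim_spectra_table_to_465(self, small_bundle):
        trimmed = trim_spectra_table(small_bundle.spectra)
        assert trimmed.shape[1] == 465

    def test_trim_spectrum_object(self):
        grid = SpectralGrid.default()
        spec = ReflectanceSpectrum(np.linspace(0, 1, 568), grid)
        assert trim_bands(spec).values.shape == (465,)


def test_envi_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    cube = Hypercube(rng.uniform(size=(6, 5, 12)),
                     SpectralGrid(np.linspace(450, 890, 12)))
    write_envi(tmp_path / "fruit", cube)
    back = read_envi(tmp_path / "fruit.hdr")
    assert back.data.shape == cube.data.shape
    np.testing.assert_allclose(back.data, cube.data, atol=1e-6)
    np.testing.assert_allclose(back.grid.wavelengths, cube.grid.wavelengths, atol=1e-5)
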