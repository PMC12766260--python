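"""Spectrum cleaning, normalization identities, and KDE peak alignment."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msistrat import (
    AlignmentConfig,
    KDEPeakAligner,
    PixelSpectrum,
    SceneDataset,
    kde_align,
    lockmass_recalibrate,
    median_normalize,
    snr_filter,
    tic_normalize,
)

positive_floats = st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False)


def spectrum_from_intensities(intensities, snrs=None):
    n = len(intensities)
    mz = 200.0 + np.arange(n) * 1.7
    snrs = np.full(n, 10.0) if snrs is None else np.asarray(snrs, dtype=float)
    return PixelSpectrum(0, 0, mz, np.asarray(intensities, dtype=float), snrs)


class TestSNRFilter:
    def test_threshold_boundary_inclusive(self):
        s = spectrum_from_intensities([1, 1, 1], snrs=[3.9, 4.0, 10.0])
        out = snr_filter(s, 4.0)
        assert out.n_peaks == 2
        assert out.snr.tolist() == [4.0, 10.0]

    def test_zero_threshold_is_identity(self, simple_spectrum):
        out = snr_filter(simple_spectrum, 0.0)
        np.testing.assert_array_equal(out.mz, simple_spectrum.mz)

    @given(snrs=st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_matches_brute_force_count(self, snrs):
        s = spectrum_from_intensities(np.ones(len(snrs)), snrs=snrs)
        out = snr_filter(s, 4.0)
        assert out.n_peaks == sum(1 for v in snrs if v >= 4.0)


class TestLockMass:
    def test_calibrant_lands_exactly(self):
        s = PixelSpectrum(0, 0, np.array([500.0050]), np.array([1.0]), np.array([9.0]))
        out, ok = lockmass_recalibrate(s, 500.0, search_ppm=20)
        assert ok
        assert out.mz[0] == pytest.approx(500.0, abs=1e-12)

    def test_no_candidate_returns_unchanged_flagged(self, simple_spectrum):
        out, ok = lockmass_recalibrate(simple_spectrum, 640.0, search_ppm=5)
        assert not ok
        np.testing.assert_array_equal(out.mz, simple_spectrum.mz)

    def test_uniform_scale_error_fully_corrected(self):
        """A multiplicative axis error is removed exactly for every peak."""
        delta = 5e-6
        true = np.array([400.0, 800.0])
        s = PixelSpectrum(0, 0, true * (1 + delta), np.array([1.0, 1.0]), np.array([9.0, 9.0]))
        out, ok = lockmass_recalibrate(s, 400.0, search_ppm=20)
        assert ok
        assert out.mz[1] == pytest.approx(800.0, rel=1e-9)


class TestNormalization:
    def test_median_normalize_example(self):
        out = median_normalize(spectrum_from_intensities([2, 4, 6]))
        np.testing.assert_allclose(out.intensity, [0.5, 1.0, 1.5])

    def test_median_single_peak(self):
        out = median_normalize(spectrum_from_intensities([7]))
        assert out.intensity.tolist() == [1.0]

    def test_median_even_count_uses_central_pair_mean(self):
        out = median_normalize(spectrum_from_intensities([1, 3]))
        np.testing.assert_allclose(out.intensity, [0.5, 1.5])

    def test_tic_normalize_example(self):
        out = tic_normalize(spectrum_from_intensities([2, 4, 6]))
        np.testing.assert_allclose(out.intensity, [1 / 6, 1 / 3, 1 / 2])

    def test_empty_spectrum_skipped_with_warning(self):
        empty = PixelSpectrum(0, 0, np.array([]), np.array([]), np.array([]))
        with pytest.warns(UserWarning):
            out = median_normalize(empty)
        assert out.n_peaks == 0

    @given(st.lists(positive_floats, min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100)
    def test_normalization_identities(self, intensities):
        """Median of median-normalized is 1; sum of TIC-normalized is 1."""
        s = spectrum_from_intensities(intensities)
        assert np.median(median_normalize(s).intensity) == pytest.approx(1.0, abs=1e-12)
        assert tic_normalize(s).intensity.sum() == pytest.approx(1.0, abs=1e-12)


def make_scene(species, n_pixels, jitter_ppm, seed, intensity=1.0):
    """Pixels that each carry every species once, with Gaussian ppm jitter."""
    rng = np.random.default_rng(seed)
    species = np.asarray(species, dtype=float)
    spectra = []
    for p in range(n_pixels):
        mz = species * (1 + rng.normal(0, jitter_ppm * 1e-6, species.size))
        order = np.argsort(mz)
        spectra.append(
            PixelSpectrum(p % 10, p // 10, mz[order],
                          np.full(species.size, float(intensity)), np.full(species.size, 10.0))
        )
    return SceneDataset(spectra, mz_window=(150.0, 1000.0))


class TestKDEAlign:
    def test_two_well_separated_species(self):
        ds = make_scene([500.000, 500.100], 100, jitter_ppm=3, seed=0)
        table = kde_align(ds, AlignmentConfig(kde_bandwidth_ppm=5.0))
        assert table.n_features == 2
        assert abs(table.feature_mz[0] - 500.000) / 500.0 < 5e-6
        assert abs(table.feature_mz[1] - 500.100) / 500.1 < 5e-6

    def test_single_species_zero_jitter_exact_centroid(self):
        ds = make_scene([623.4567], 50, jitter_ppm=0, seed=0)
        table = kde_align(ds)
        assert table.n_features == 1
        # centroid limited only by the density evaluation grid (0.2 ppm step)
        assert abs(table.feature_mz[0] - 623.4567) / 623.4567 < 2.5e-7

    def test_species_beyond_six_bandwidths_never_merge(self):
        """Two populations 10 bandwidths apart must yield two features."""
        bw_ppm = 2.0
        sep = 10 * bw_ppm * 1e-6 * 700.0
        ds = make_scene([700.0, 700.0 + sep], 80, jitter_ppm=1, seed=1)
        table = kde_align(ds, AlignmentConfig(kde_bandwidth_ppm=bw_ppm))
        assert table.n_features == 2

    def test_total_intensity_never_inflated(self):
        ds = make_scene(np.linspace(300, 900, 23), 40, jitter_ppm=2, seed=2, intensity=1.5)
        total_in = sum(s.intensity.sum() for s in ds)
        table = kde_align(ds)
        assert table.matrix.sum() <= total_in + 1e-9

    def test_noise_maxima_match_independent_oracle(self):
        """Retained-feature count on pure noise equals a from-scratch
        re-implementation of the bin/KDE/prominence/dedup steps."""
        rng = np.random.default_rng(11)
        mzs = np.sort(rng.uniform(400.0, 403.0, 300))
        spectra = [
            PixelSpectrum(i, 0, np.sort(m), np.ones(m.size), np.full(m.size, 10.0))
            for i, m in enumerate(np.array_split(mzs, 10))
            if m.size
        ]
        ds = SceneDataset(spectra)
        cfg = AlignmentConfig(bin_width_da=0.5, kde_bandwidth_ppm=2.0,
                              grid_step_ppm=0.2, prominence_min=0.01)
        table = kde_align(ds, cfg)

        # independent oracle: naive Gaussian sums + manual prominence scan
        def oracle_maxima(pool):
            kept = []
            first = np.floor(pool.min() / cfg.bin_width_da) * cfg.bin_width_da
            for lo in np.arange(first, pool.max() + cfg.bin_width_da, cfg.bin_width_da):
                hi = lo + cfg.bin_width_da
                center = lo + cfg.bin_width_da / 2
                h = cfg.kde_bandwidth_ppm * 1e-6 * center
                sub = pool[(pool >= lo - 3 * h) & (pool < hi + 3 * h)]
                if sub.size == 0:
                    continue
                step = cfg.grid_step_ppm * 1e-6 * center
                grid = np.arange(lo - 3 * h, hi + 3 * h + step, step)
                dens = np.exp(-0.5 * ((grid[:, None] - sub[None, :]) / h) ** 2).sum(axis=1)
                dens /= dens.max()
                for i in range(1, grid.size - 1):
                    if not (dens[i] > dens[i - 1] and dens[i] > dens[i + 1]):
                        continue
                    # prominence: height above the higher of the two deepest
                    # flanking minima before a taller point is reached
                    left = dens[: i + 1]
                    right = dens[i:]
                    taller_l = np.nonzero(left > dens[i])[0]
                    lmin = left[taller_l[-1]:].min() if taller_l.size else left.min()
                    taller_r = np.nonzero(right > dens[i])[0]
                    rmin = right[: taller_r[0] + 1].min() if taller_r.size else right.min()
                    if dens[i] - max(lmin, rmin) > cfg.prominence_min and lo <= grid[i] < hi:
                        kept.append(grid[i])
            return np.array(sorted(kept))

        expected = oracle_maxima(np.sort(mzs))
        assert table.n_features == expected.size
        np.testing.assert_allclose(table.feature_mz, expected, rtol=1e-9)

    def test_assignment_tie_goes_to_lower_mz(self):
        aligner = KDEPeakAligner()
        aligner.feature_mz_ = np.array([500.0, 500.00002])
        idx = aligner.assign(np.array([500.00001]))
        assert idx[0] == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            kde_align(SceneDataset([]))
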