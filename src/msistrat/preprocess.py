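"""Per-spectrum cleaning, normalization, and dataset-wide KDE peak alignment.

The preprocessing chain mirrors standard untargeted MSI practice for
high-resolution (FTICR-class) data:

1. ``SNRFilter`` — drop peaks below a signal-to-noise threshold (default 4,
   boundary inclusive) to exclude instrument noise;
2. ``LockMassCalibrator`` — optional multiplicative m/z rescaling onto a
   known calibrant species;
3. ``MedianNormalizer`` / ``TICNormalizer`` — per-spectrum intensity
   normalization by the median peak intensity or by the total ion count;
4. ``KDEPeakAligner`` — pool peak m/z values across all pixels, estimate
   their density bin-wise with a Gaussian kernel, and treat sufficiently
   prominent density maxima as consensus features; every peak is assigned
   to the nearest retained maximum within three kernel bandwidths.

Each step is a stateless (or fit-once) transformer over
:class:`~msistrat.datatypes.SceneDataset`; module-level functions wrap the
single-spectrum operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import KernelDensity

from .datatypes import FeatureTable, PixelSpectrum, SceneDataset

__all__ = [
    "AlignmentConfig",
    "AlignedFeature",
    "snr_filter",
    "lockmass_recalibrate",
    "median_normalize",
    "tic_normalize",
    "kde_align",
    "SNRFilter",
    "LockMassCalibrator",
    "MedianNormalizer",
    "TICNormalizer",
    "KDEPeakAligner",
]


@dataclass
class AlignmentConfig:
    """Parameters of bin-wise KDE peak alignment.

    ``bin_width_da`` partitions the m/z axis; each bin is extended by three
    kernel bandwidths on both sides so species near a boundary are not
    split. ``kde_bandwidth_ppm`` and ``grid_step_ppm`` are expressed as ppm
    of the bin-center m/z, the natural unit of FTICR mass accuracy.
    ``prominence_min`` applies to the per-bin density curve normalized to a
    maximum of 1.
    """

    bin_width_da: float = 0.5
    kde_bandwidth_ppm: float = 2.0
    grid_step_ppm: float = 0.2
    prominence_min: float = 0.01
    snr_min: float = 4.0

    def __post_init__(self) -> None:
        if min(self.bin_width_da, self.kde_bandwidth_ppm, self.grid_step_ppm) <= 0:
            raise ValueError("bin width, bandwidth and grid step must be positive")
        if not 0 < self.prominence_min <= 1:
            raise ValueError("prominence_min must lie in (0, 1]")
        if self.snr_min < 0:
            raise ValueError("snr_min must be non-negative")


@dataclass
class AlignedFeature:
    """One consensus feature: density-maximum m/z plus assignment stats."""

    centroid_mz: float
    support: int = 0  # pixels with >= 1 assigned peak
    n_member_peaks: int = 0


# ---------------------------------------------------------------------------
# Single-spectrum operations


def snr_filter(spectrum: PixelSpectrum, snr_min: float = 4.0) -> PixelSpectrum:
    """Retain peaks with SNR >= ``snr_min`` (boundary inclusive)."""
    if snr_min < 0:
        raise ValueError("snr_min must be non-negative")
    keep = spectrum.snr >= snr_min
    return spectrum.replace_peaks(
        spectrum.mz[keep], spectrum.intensity[keep], spectrum.snr[keep]
    )


def lockmass_recalibrate(
    spectrum: PixelSpectrum, calibrant_mz: float, search_ppm: float = 20.0
) -> tuple[PixelSpectrum, bool]:
    """Rescale the m/z axis so the calibrant peak lands on its exact mass.

    The peak nearest ``calibrant_mz`` within ``+/- search_ppm`` is taken as
    the calibrant (ties broken by higher intensity) and all m/z are
    multiplied by ``calibrant_mz / observed_mz`` — exact for a uniform
    relative scale error. Returns ``(spectrum, calibrated)``; when no peak
    falls inside the window the spectrum is returned unchanged with the
    flag ``False``.
    """
    if search_ppm <= 0:
        raise ValueError("search_ppm must be positive")
    tol = calibrant_mz * search_ppm * 1e-6
    dist = np.abs(spectrum.mz - calibrant_mz)
    inside = np.flatnonzero(dist <= tol)
    if inside.size == 0:
        return spectrum, False
    best = dist[inside].min()
    candidates = inside[np.isclose(dist[inside], best, rtol=0, atol=0)]
    if candidates.size > 1:  # equidistant tie -> higher intensity wins
        candidates = candidates[np.argsort(-spectrum.intensity[candidates], kind="stable")]
    scale = calibrant_mz / spectrum.mz[candidates[0]]
    return spectrum.replace_peaks(spectrum.mz * scale, spectrum.intensity, spectrum.snr), True


def median_normalize(spectrum: PixelSpectrum) -> PixelSpectrum:
    """Divide intensities by the spectrum's median peak intensity."""
    if spectrum.n_peaks == 0:
        warnings.warn(f"empty spectrum at ({spectrum.x},{spectrum.y}); skipped")
        return spectrum
    med = float(np.median(spectrum.intensity))
    if med == 0:
        warnings.warn(f"zero median intensity at ({spectrum.x},{spectrum.y}); skipped")
        return spectrum
    return spectrum.replace_peaks(spectrum.mz, spectrum.intensity / med, spectrum.snr)


def tic_normalize(spectrum: PixelSpectrum) -> PixelSpectrum:
    """Divide intensities by the total ion count so they sum to 1."""
    if spectrum.n_peaks == 0:
        warnings.warn(f"empty spectrum at ({spectrum.x},{spectrum.y}); skipped")
        return spectrum
    tic = float(spectrum.intensity.sum())
    if tic == 0:
        warnings.warn(f"all-zero spectrum at ({spectrum.x},{spectrum.y}); skipped")
        return spectrum
    return spectrum.replace_peaks(spectrum.mz, spectrum.intensity / tic, spectrum.snr)


# ---------------------------------------------------------------------------
# Dataset transformers


class SNRFilter(BaseEstimator, TransformerMixin):
    """Dataset-level SNR filter; drops peaks with SNR below ``snr_min``."""

    def __init__(self, snr_min: float = 4.0):
        self.snr_min = snr_min

    def fit(self, dataset: SceneDataset, y=None):
        return self

    def transform(self, dataset: SceneDataset) -> SceneDataset:
        return dataset.map_spectra(lambda s: snr_filter(s, self.snr_min))


class LockMassCalibrator(BaseEstimator, TransformerMixin):
    """Per-spectrum lock-mass recalibration onto one calibrant species.

    After ``transform``, ``n_uncalibrated_`` counts spectra where no peak
    was found inside the search window (returned unchanged).
    """

    def __init__(self, calibrant_mz: float, search_ppm: float = 20.0):
        self.calibrant_mz = calibrant_mz
        self.search_ppm = search_ppm

    def fit(self, dataset: SceneDataset, y=None):
        return self

    def transform(self, dataset: SceneDataset) -> SceneDataset:
        n_missed = 0

        def _cal(s: PixelSpectrum) -> PixelSpectrum:
            nonlocal n_missed
            out, ok = lockmass_recalibrate(s, self.calibrant_mz, self.search_ppm)
            n_missed += not ok
            return out

        out = dataset.map_spectra(_cal)
        self.n_uncalibrated_ = n_missed
        return out


class MedianNormalizer(BaseEstimator, TransformerMixin):
    """Per-spectrum normalization by the median peak intensity."""

    def fit(self, dataset: SceneDataset, y=None):
        return self

    def transform(self, dataset: SceneDataset) -> SceneDataset:
        return dataset.map_spectra(median_normalize)


class TICNormalizer(BaseEstimator, TransformerMixin):
    """Per-spectrum normalization by the total ion count."""

    def fit(self, dataset: SceneDataset, y=None):
        return self

    def transform(self, dataset: SceneDataset) -> SceneDataset:
        return dataset.map_spectra(tic_normalize)


class KDEPeakAligner(BaseEstimator, TransformerMixin):
    """Bin-wise Gaussian-KDE peak alignment across all pixels.

    ``fit`` pools every peak m/z in the dataset, partitions the m/z axis
    into ``bin_width_da`` bins (each extended by three bandwidths on both
    sides), evaluates a Gaussian-kernel density on a ppm-scale grid per
    bin, keeps local density maxima whose prominence on the max-normalized
    curve exceeds ``prominence_min``, and deduplicates maxima found in two
    bins' overlap by keeping the one inside the owning bin. ``transform``
    assigns every peak of a dataset to the nearest retained maximum within
    three bandwidths (ties to the lower-m/z feature; unassignable peaks
    are dropped and counted) and emits the pixels x features intensity
    matrix.

    Fitted attributes
    -----------------
    feature_mz_ : (n_features,) aligned centroid m/z, strictly increasing
    features_ : list of :class:`AlignedFeature` with support counts
    n_dropped_peaks_ : peaks farther than three bandwidths from any maximum
        in the last ``transform``
    """

    def __init__(
        self,
        bin_width_da: float = 0.5,
        kde_bandwidth_ppm: float = 2.0,
        grid_step_ppm: float = 0.2,
        prominence_min: float = 0.01,
    ):
        self.bin_width_da = bin_width_da
        self.kde_bandwidth_ppm = kde_bandwidth_ppm
        self.grid_step_ppm = grid_step_ppm
        self.prominence_min = prominence_min

    # -- fitting ------------------------------------------------------------

    def _pool(self, dataset: SceneDataset) -> np.ndarray:
        if len(dataset) == 0:
            raise ValueError("cannot align an empty dataset")
        arrays = [s.mz for s in dataset if s.n_peaks]
        return np.sort(np.concatenate(arrays)) if arrays else np.array([])

    def fit(self, dataset: SceneDataset, y=None):
        AlignmentConfig(
            self.bin_width_da, self.kde_bandwidth_ppm, self.grid_step_ppm, self.prominence_min
        )  # validate parameters
        pooled = self._pool(dataset)
        centroids: list[float] = []
        if pooled.size:
            bw = self.bin_width_da
            first = np.floor(pooled[0] / bw) * bw
            edges = np.arange(first, pooled[-1] + bw, bw)
            for lo in edges:
                hi = lo + bw
                center = lo + bw / 2.0
                h = self.kde_bandwidth_ppm * 1e-6 * center
                ext_lo, ext_hi = lo - 3 * h, hi + 3 * h
                i0, i1 = np.searchsorted(pooled, [ext_lo, ext_hi])
                sub = pooled[i0:i1]
                if sub.size == 0:
                    continue
                step = self.grid_step_ppm * 1e-6 * center
                grid = np.arange(ext_lo, ext_hi + step, step)
                kde = KernelDensity(kernel="gaussian", bandwidth=h).fit(sub[:, None])
                density = np.exp(kde.score_samples(grid[:, None]))
                peak = density.max()
                if peak <= 0:
                    continue
                density /= peak
                maxima, _ = find_peaks(density)
                if maxima.size == 0:
                    # A single isolated cluster can peak at an interior grid
                    # point yet register no "peak" only when the curve is
                    # monotone to the window edge; treat the argmax as the
                    # maximum if it is interior.
                    am = int(np.argmax(density))
                    if 0 < am < density.size - 1:
                        maxima = np.array([am])
                    else:
                        continue
                prom = peak_prominences(density, maxima)[0]
                maxima = maxima[prom > self.prominence_min]
                for m in grid[maxima]:
                    if lo <= m < hi:  # ownership rule deduplicates bin overlaps
                        centroids.append(float(m))
        self.feature_mz_ = np.array(sorted(centroids))
        self.features_ = [AlignedFeature(c) for c in self.feature_mz_]
        self.n_dropped_peaks_ = 0
        return self

    # -- assignment ---------------------------------------------------------

    def assign(self, mz: np.ndarray) -> np.ndarray:
        """Feature index per peak; -1 where no maximum lies within 3 bandwidths.

        Nearest retained maximum wins; an exact distance tie goes to the
        lower-m/z feature.
        """
        cent = self.feature_mz_
        if cent.size == 0:
            return np.full(mz.shape, -1, dtype=int)
        right = np.searchsorted(cent, mz)
        left = np.clip(right - 1, 0, cent.size - 1)
        right = np.clip(right, 0, cent.size - 1)
        d_left = np.abs(mz - cent[left])
        d_right = np.abs(mz - cent[right])
        idx = np.where(d_left <= d_right, left, right)  # tie -> lower m/z
        dist = np.minimum(d_left, d_right)
        radius = 3.0 * self.kde_bandwidth_ppm * 1e-6 * cent[idx]
        return np.where(dist <= radius, idx, -1)

    def transform(self, dataset: SceneDataset) -> FeatureTable:
        if not hasattr(self, "feature_mz_"):
            raise RuntimeError("KDEPeakAligner must be fitted before transform")
        if self.feature_mz_.size == 0:
            warnings.warn("no retained density maxima; emitting an empty feature table")
        n_feat = self.feature_mz_.size
        coords = dataset.coordinates
        matrix = np.zeros((len(dataset), n_feat))
        dropped = 0
        support = np.zeros(n_feat, dtype=int)
        members = np.zeros(n_feat, dtype=int)
        for row, spec in enumerate(dataset):
            if spec.n_peaks == 0:
                continue
            idx = self.assign(spec.mz)
            ok = idx >= 0
            dropped += int((~ok).sum())
            np.add.at(matrix[row], idx[ok], spec.intensity[ok])
            cols, counts = np.unique(idx[ok], return_counts=True)
            support[cols] += 1
            members[cols] += counts
        self.n_dropped_peaks_ = dropped
        for f, s, m in zip(self.features_, support, members):
            f.support = int(s)
            f.n_member_peaks = int(m)
        return FeatureTable(self.feature_mz_, matrix, coords)


def kde_align(dataset: SceneDataset, config: AlignmentConfig | None = None) -> FeatureTable:
    """Fit-and-transform convenience wrapper around :class:`KDEPeakAligner`.

    The dataset is expected to be SNR-filtered and normalized already; the
    SNR threshold in ``config`` is not re-applied here.
    """
    config = config or AlignmentConfig()
    aligner = KDEPeakAligner(
        bin_width_da=config.bin_width_da,
        kde_bandwidth_ppm=config.kde_bandwidth_ppm,
        grid_step_ppm=config.grid_step_ppm,
        prominence_min=config.prominence_min,
    )
    return aligner.fit(dataset).transform(dataset)
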