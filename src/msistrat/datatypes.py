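"""Core in-memory containers for MALDI-MSI pixel spectra and derived matrices.

The pipeline moves data through four representations:

``PixelSpectrum``
    one pixel's centroided peak list (m/z, intensity, SNR) at integer raster
    coordinates;
``SceneDataset``
    all pixel spectra of one measurement plus acquisition metadata (pixel
    pitch, analytical m/z window, polarity, which raster axis is depth);
``FeatureTable``
    the pixels x aligned-features intensity matrix produced by peak
    alignment;
``VoidMask`` / ``ZoneMatrix`` / ``FingerprintModel``
    the spatial label grid used for matrix-signal cleaning, the
    zone-averaged abundance matrix, and the non-negative factorization
    result ("molecular fingerprints" and "pseudo-spectra").

All containers are plain dataclasses over numpy arrays and validate their
invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "PixelSpectrum",
    "SceneDataset",
    "VoidMask",
    "FeatureTable",
    "ZoneMatrix",
    "FingerprintModel",
    "OUTSIDE",
    "SEDIMENT",
    "VOID",
]

# VoidMask label codes (stored as small ints in the grid and in TSV masks).
OUTSIDE: int = 0
SEDIMENT: int = 1
VOID: int = 2

_LABEL_NAMES = {OUTSIDE: "outside", SEDIMENT: "sediment", VOID: "void"}


@dataclass(frozen=True)
class PixelSpectrum:
    """Centroided peak list of a single raster pixel.

    Parameters
    ----------
    x, y
        0-based raster column / row index.
    mz
        Peak m/z in Da, strictly increasing.
    intensity
        Non-negative ion counts, same length as ``mz``.
    snr
        Non-negative per-peak signal-to-noise ratios, same length as ``mz``.
    """

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        snr = np.asarray(self.snr, dtype=float)
        if not (mz.shape == intensity.shape == snr.shape) or mz.ndim != 1:
            raise ValueError("mz, intensity and snr must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError(f"peaks at ({self.x},{self.y}) must be strictly increasing in m/z")
        if np.any(intensity < 0) or np.any(snr < 0):
            raise ValueError(f"negative intensity or SNR at ({self.x},{self.y})")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "snr", snr)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def replace_peaks(
        self, mz: np.ndarray, intensity: np.ndarray, snr: np.ndarray
    ) -> "PixelSpectrum":
        """New spectrum at the same coordinates with a different peak list."""
        return PixelSpectrum(self.x, self.y, mz, intensity, snr)


@dataclass
class SceneDataset:
    """All pixel spectra of one MSI measurement plus acquisition metadata.

    ``depth_axis`` names the raster axis that increases with sediment depth
    (``"x"`` by default: depth zones bin the x coordinate). Physical position
    along either axis is ``index * pixel_pitch_um``.
    """

    spectra: list[PixelSpectrum]
    pixel_pitch_um: float = 150.0
    mz_window: tuple[float, float] = (150.0, 1000.0)
    polarity: str = "negative"
    depth_axis: str = "x"

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        lo, hi = self.mz_window
        if not lo < hi:
            raise ValueError("mz_window must satisfy low < high")
        if self.depth_axis not in ("x", "y"):
            raise ValueError("depth_axis must be 'x' or 'y'")
        seen: set[tuple[int, int]] = set()
        for s in self.spectra:
            key = (s.x, s.y)
            if key in seen:
                raise ValueError(f"duplicate spectrum coordinate {key}")
            seen.add(key)
        self.spectra = sorted(self.spectra, key=lambda s: (s.x, s.y))

    def __iter__(self) -> Iterator[PixelSpectrum]:
        return iter(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_pixels, 2) integer array of (x, y) in the dataset's pixel order."""
        return np.array([(s.x, s.y) for s in self.spectra], dtype=int).reshape(-1, 2)

    @property
    def extent(self) -> tuple[int, int]:
        """(n_x, n_y) raster extent inferred from the largest coordinates."""
        if not self.spectra:
            return (0, 0)
        coords = self.coordinates
        return (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)

    def depth_coordinate(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Depth-axis raster coordinate for each pixel."""
        if coords is None:
            coords = self.coordinates
        return coords[:, 0] if self.depth_axis == "x" else coords[:, 1]

    def map_spectra(self, fn) -> "SceneDataset":
        """Apply a per-spectrum transform, keeping metadata."""
        return SceneDataset(
            [fn(s) for s in self.spectra],
            pixel_pitch_um=self.pixel_pitch_um,
            mz_window=self.mz_window,
            polarity=self.polarity,
            depth_axis=self.depth_axis,
        )


@dataclass
class VoidMask:
    """Per-raster-cell label grid {outside, sediment, void}.

    ``labels`` is indexed ``[x, y]`` to match raster coordinates.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D grid")
        if not np.isin(labels, [OUTSIDE, SEDIMENT, VOID]).all():
            raise ValueError("mask labels must be 0 (outside), 1 (sediment) or 2 (void)")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # (n_x, n_y)

    def label_at(self, x: int, y: int) -> int:
        return int(self.labels[x, y])

    def labels_for(self, coords: np.ndarray) -> np.ndarray:
        """Labels for an (n, 2) array of (x, y) coordinates."""
        coords = np.asarray(coords, dtype=int)
        nx, ny = self.labels.shape
        if coords.size and (
            coords.min() < 0 or coords[:, 0].max() >= nx or coords[:, 1].max() >= ny
        ):
            raise ValueError("coordinates fall outside the mask grid")
        return self.labels[coords[:, 0], coords[:, 1]]

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == code).sum()) for code, name in _LABEL_NAMES.items()
        }


@dataclass
class FeatureTable:
    """Pixels x aligned-features intensity matrix.

    Rows follow ``pixel_index`` (ordered (x, y) pairs); columns follow
    ``feature_mz`` (strictly increasing aligned centroids in Da). Zero means
    "feature not detected in that pixel".
    """

    feature_mz: np.ndarray
    matrix: np.ndarray
    pixel_index: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.feature_mz, dtype=float).reshape(-1)
        mat = np.asarray(self.matrix, dtype=float)
        idx = np.asarray(self.pixel_index, dtype=int).reshape(-1, 2)
        if mat.ndim != 2:
            raise ValueError("matrix must be 2-D (pixels x features)")
        if mat.shape != (idx.shape[0], mz.size):
            raise ValueError(
                f"matrix shape {mat.shape} inconsistent with "
                f"{idx.shape[0]} pixels x {mz.size} features"
            )
        if np.any(mat < 0):
            raise ValueError("feature table intensities must be non-negative")
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise ValueError("feature_mz must be strictly increasing")
        self.feature_mz = mz
        self.matrix = mat
        self.pixel_index = idx

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def select_features(self, keep: np.ndarray) -> "FeatureTable":
        """Column subset (boolean mask or index array); order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return FeatureTable(self.feature_mz[keep], self.matrix[:, keep], self.pixel_index)

    def feature_column(self, feature: int | float) -> int:
        """Resolve a feature reference (column index or m/z value) to a column."""
        if isinstance(feature, (int, np.integer)):
            if not 0 <= feature < self.n_features:
                raise KeyError(f"feature column {feature} out of range")
            return int(feature)
        j = int(np.argmin(np.abs(self.feature_mz - float(feature))))
        if not np.isclose(self.feature_mz[j], float(feature), rtol=0, atol=5e-4):
            raise KeyError(f"no aligned feature at m/z {feature}")
        return j

    def to_dataframe(self):
        """pandas view with x, y columns and 4-decimal m/z column labels."""
        import pandas as pd

        df = pd.DataFrame(self.matrix, columns=[f"{m:.4f}" for m in self.feature_mz])
        df.insert(0, "y", self.pixel_index[:, 1])
        df.insert(0, "x", self.pixel_index[:, 0])
        return df


@dataclass
class ZoneMatrix:
    """Zones x features matrix of mean abundance per depth zone."""

    matrix: np.ndarray
    zone_bounds: np.ndarray  # (n_zones, 2) half-open [lo, hi) raster intervals
    feature_mz: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        bounds = np.asarray(self.zone_bounds, dtype=int).reshape(-1, 2)
        mz = np.asarray(self.feature_mz, dtype=float).reshape(-1)
        if mat.shape != (bounds.shape[0], mz.size):
            raise ValueError("zone matrix shape inconsistent with bounds/features")
        if np.any(mat < 0):
            raise ValueError("zone matrix must be non-negative")
        self.matrix = mat
        self.zone_bounds = bounds
        self.feature_mz = mz

    @property
    def n_zones(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class FingerprintModel:
    """Non-negative factorization of a (scaled) zone matrix.

    ``spatial`` (zones x k) holds the molecular fingerprints — the depth
    pattern of each component; ``contributions`` (k x features) holds the
    pseudo-spectra — each feature's contribution to each component.
    ``error_trace`` maps candidate component counts to the relative
    Frobenius reconstruction error measured during model selection.
    """

    n_components: int
    spatial: np.ndarray
    contributions: np.ndarray
    error_trace: dict[int, float]
    seed: int
    feature_mz: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        W = np.asarray(self.spatial, dtype=float)
        H = np.asarray(self.contributions, dtype=float)
        if W.ndim != 2 or H.ndim != 2 or W.shape[1] != self.n_components or H.shape[0] != self.n_components:
            raise ValueError("factor shapes inconsistent with n_components")
        if np.any(W < 0) or np.any(H < 0):
            raise ValueError("factors must be non-negative")
        self.spatial = W
        self.contributions = H

    @property
    def reconstruction_error(self) -> float:
        """Relative Frobenius error recorded for the selected k."""
        return self.error_trace[self.n_components]

    def reconstruct(self) -> np.ndarray:
        return self.spatial @ self.contributions
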