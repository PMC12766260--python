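"""Ion images, weighted-average component images, and depth profiles.

An :class:`IonImage` is a per-pixel non-negative intensity grid indexed
``[x, y]`` (x = depth axis by default). Component images average the
TIC-normalized ion images of all features, weighted by the component's
feature contributions raised to a power (default 5, which strongly
emphasizes the dominant features of a pseudo-spectrum). Depth profiles sum
an image across the transverse axis per depth bin (default one raster
step, i.e. 150 um at the default pitch) and smooth with a centered moving
average whose window shrinks at the profile edges.

Rendering is read-only: nothing here mutates a feature table or model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import FeatureTable, FingerprintModel

__all__ = [
    "IonImage",
    "DepthProfile",
    "ion_image",
    "component_image",
    "depth_profile",
    "moving_average",
    "save_heatmap",
    "save_grid",
    "save_profile",
]


@dataclass
class IonImage:
    """Per-pixel intensity grid with provenance (feature m/z or component)."""

    grid: np.ndarray  # (n_x, n_y), non-negative
    provenance: str
    vmin: float = 0.0
    vmax: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 2:
            raise ValueError("image grid must be 2-D")
        if np.any(grid < 0):
            raise ValueError("image intensities must be non-negative")
        self.grid = grid
        if self.vmax is None:
            self.vmax = float(grid.max()) if grid.size else 0.0

    @property
    def total(self) -> float:
        return float(self.grid.sum())


def _extent(table: FeatureTable, extent: tuple[int, int] | None) -> tuple[int, int]:
    if extent is not None:
        return extent
    idx = table.pixel_index
    return (int(idx[:, 0].max()) + 1, int(idx[:, 1].max()) + 1)


def ion_image(
    table: FeatureTable, feature: int | float, extent: tuple[int, int] | None = None
) -> IonImage:
    """Single-feature intensity map; pixels absent from the table are 0.

    ``feature`` is a column index (int) or an aligned centroid m/z (float).
    The table should carry TIC-normalized intensities when the image is
    meant to be comparable across pixels.
    """
    col = table.feature_column(feature)
    n_x, n_y = _extent(table, extent)
    grid = np.zeros((n_x, n_y))
    grid[table.pixel_index[:, 0], table.pixel_index[:, 1]] = table.matrix[:, col]
    return IonImage(grid, provenance=f"mz={table.feature_mz[col]:.4f}")


def component_image(
    table: FeatureTable,
    model: FingerprintModel,
    component: int,
    power: float = 5.0,
    normalize: bool = True,
    extent: tuple[int, int] | None = None,
) -> IonImage:
    """Weighted average ion image of one NMF component.

    Pixel value = sum_f w_f^power * I_f(pixel) / sum_f w_f^power, with w_f
    the component's contribution to feature f and I_f the per-pixel
    intensity in ``table``. ``normalize=False`` skips the denominator
    (weighted sum). The power (default 5) emphasizes dominant features.
    """
    if not 0 <= component < model.n_components:
        raise IndexError(f"component {component} out of range")
    if power < 1:
        raise ValueError("power must be >= 1")
    if model.contributions.shape[1] != table.n_features:
        raise ValueError("model and table disagree on the number of features")
    w = model.contributions[component] ** power
    wsum = w.sum()
    if wsum == 0:
        warnings.warn(f"component {component} has all-zero contributions; zero image")
        values = np.zeros(table.n_pixels)
    else:
        values = table.matrix @ w
        if normalize:
            values = values / wsum
    n_x, n_y = _extent(table, extent)
    grid = np.zeros((n_x, n_y))
    grid[table.pixel_index[:, 0], table.pixel_index[:, 1]] = values
    return IonImage(grid, provenance=f"component_{component}^p{power:g}")


@dataclass
class DepthProfile:
    """Depth-binned intensity sums and their moving-average smoothing."""

    bin_centers_um: np.ndarray
    raw_sums: np.ndarray
    smoothed: np.ndarray
    window: int


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a window that shrinks at the edges.

    Output has the same length as the input; at position i the mean runs
    over ``values[max(0, i-w//2) : i+w//2+1]``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > values.size:
        raise ValueError("smoothing window larger than the profile")
    half = window // 2
    out = np.empty_like(np.asarray(values, dtype=float))
    for i in range(values.size):
        out[i] = values[max(0, i - half) : i + half + 1].mean()
    return out


def depth_profile(
    image: IonImage,
    pixel_pitch_um: float = 150.0,
    bin_um: float | None = None,
    window: int = 5,
    depth_axis: str = "x",
) -> DepthProfile:
    """Sum an ion image across the transverse axis per depth bin and smooth.

    ``bin_um`` must be a positive multiple of the pixel pitch (default one
    raster step, i.e. one 150-um horizon at the default pitch); ``window``
    is the odd moving-average width in points (default 5).
    """
    grid = image.grid if depth_axis == "x" else image.grid.T
    if bin_um is None:
        bin_um = pixel_pitch_um
    step = bin_um / pixel_pitch_um
    if step < 1 or abs(step - round(step)) > 1e-9:
        raise ValueError("bin_um must be a positive integer multiple of the pixel pitch")
    step = int(round(step))
    n_depth = grid.shape[0]
    n_bins = int(np.ceil(n_depth / step))
    raw = np.array(
        [grid[b * step : (b + 1) * step].sum() for b in range(n_bins)]
    )
    centers = (np.arange(n_bins) + 0.5) * step * pixel_pitch_um
    return DepthProfile(centers, raw, moving_average(raw, window), window)


# ---------------------------------------------------------------------------
# Export helpers (numeric grid TSV + PNG heatmap)


def save_grid(image: IonImage, path: str | Path) -> None:
    """Write the numeric grid as TSV (rows = depth/x, columns = y)."""
    np.savetxt(path, image.grid, fmt="%.8g", delimiter="\t")


def save_heatmap(image: IonImage, path: str | Path, cmap: str = "viridis") -> None:
    """Render the grid to PNG through a matplotlib colormap (deterministic).

    Depth (x) runs down the image; low-to-high intensity maps blue-to-yellow
    under the default colormap.
    """
    import matplotlib as mpl
    from PIL import Image

    vmax = image.vmax if image.vmax else 1.0
    span = (vmax - image.vmin) or 1.0
    norm = np.clip((image.grid - image.vmin) / span, 0.0, 1.0)
    rgba = (mpl.colormaps[cmap](norm) * 255).astype(np.uint8)
    Image.fromarray(rgba, mode="RGBA").save(path)


def save_profile(profile: DepthProfile, path: str | Path) -> None:
    """Write a depth profile as TSV: center (um), raw sum, smoothed."""
    with Path(path).open("w") as fh:
        fh.write("depth_um\traw_sum\tsmoothed\n")
        for c, r, s in zip(profile.bin_centers_um, profile.raw_sums, profile.smoothed):
            fh.write(f"{c:.6g}\t{r:.8g}\t{s:.8g}\n")
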