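"""Readers and writers for all on-disk artifacts.

Spectrum exports are the comma-separated plain-text files produced when
per-pixel peak lists (m/z, intensity, SNR at each x, y coordinate) are
dumped from the instrument software: one row per peak, columns
``x,y,mz,intensity,snr``, header optional. Masks come either as an image of
the measurement area (with a colour rule identifying embedding-medium
voids) or as a plain TSV label grid. Feature tables and fingerprint
matrices are TSV; run manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    OUTSIDE,
    SEDIMENT,
    VOID,
    FeatureTable,
    FingerprintModel,
    PixelSpectrum,
    SceneDataset,
    VoidMask,
)

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_void_mask",
    "read_void_mask_grid",
    "write_void_mask_grid",
    "write_void_mask_image",
    "read_feature_table",
    "write_feature_table",
    "write_fingerprint_model",
    "read_fingerprint_model",
    "write_manifest",
]

_SPECTRUM_COLUMNS = ("x", "y", "mz", "intensity", "snr")


class SpectrumParseError(ValueError):
    """A spectrum export row failed to parse; carries file and line."""


def _read_one_export(path: Path) -> pd.DataFrame:
    try:
        first = path.open().readline()
    except FileNotFoundError:
        raise FileNotFoundError(f"spectrum export not found: {path}")
    if not first.strip():
        raise SpectrumParseError(f"{path}: empty input")
    # Header auto-detection: a header row does not parse as five numbers.
    tokens = [t.strip() for t in first.split(",")]
    has_header = True
    if len(tokens) == 5:
        try:
            [float(t) for t in tokens]
            has_header = False
        except ValueError:
            has_header = True
    try:
        df = pd.read_csv(
            path,
            header=0 if has_header else None,
            names=list(_SPECTRUM_COLUMNS),
            dtype={"x": int, "y": int, "mz": float, "intensity": float, "snr": float},
            comment="#",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise SpectrumParseError(f"{path}: malformed spectrum export ({exc})") from exc
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + (2 if has_header else 1)
        raise SpectrumParseError(f"{path}, line {line}: malformed row")
    return df


def read_spectra(
    path_or_paths: str | Path | Sequence[str | Path],
    mz_window: tuple[float, float] = (150.0, 1000.0),
    pixel_pitch_um: float = 150.0,
    polarity: str = "negative",
    depth_axis: str = "x",
) -> SceneDataset:
    """Read one or more CSV spectrum exports into a :class:`SceneDataset`.

    Peaks outside ``mz_window`` are dropped (the analytical window of the
    acquisition); duplicate (x, y, mz) rows are collapsed by summing
    intensity and taking the maximum SNR; per-spectrum peaks come out sorted
    by m/z.
    """
    if isinstance(path_or_paths, (str, Path)):
        paths = [Path(path_or_paths)]
    else:
        paths = [Path(p) for p in path_or_paths]
    if not paths:
        raise ValueError("no spectrum export paths given")
    frames = [_read_one_export(p) for p in paths]
    df = pd.concat(frames, ignore_index=True)
    if df.empty:
        raise SpectrumParseError(f"{paths[0]}: empty input")

    lo, hi = mz_window
    df = df[(df["mz"] >= lo) & (df["mz"] <= hi)]
    # Collapse exact duplicate (x, y, mz) rows: sum intensity, max snr.
    df = (
        df.groupby(["x", "y", "mz"], sort=True)
        .agg(intensity=("intensity", "sum"), snr=("snr", "max"))
        .reset_index()
    )
    spectra = [
        PixelSpectrum(
            int(x),
            int(y),
            g["mz"].to_numpy(),
            g["intensity"].to_numpy(),
            g["snr"].to_numpy(),
        )
        for (x, y), g in df.groupby(["x", "y"], sort=True)
    ]
    return SceneDataset(
        spectra,
        pixel_pitch_um=pixel_pitch_um,
        mz_window=mz_window,
        polarity=polarity,
        depth_axis=depth_axis,
    )


def write_spectra(dataset: SceneDataset, path: str | Path) -> None:
    """Write a dataset back to the CSV export dialect (with header)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(_SPECTRUM_COLUMNS) + "\n")
        for s in dataset:
            for mz, inten, snr in zip(s.mz, s.intensity, s.snr):
                fh.write(f"{s.x},{s.y},{mz:.6f},{inten:.6g},{snr:.4g}\n")


# ---------------------------------------------------------------------------
# Void masks


def _block_majority(labels_img: np.ndarray, extent: tuple[int, int]) -> np.ndarray:
    """Reduce an image-resolution label array to raster cells by majority vote.

    ``labels_img`` is (height, width) in image convention; the result is
    (n_x, n_y) in raster convention with x as the image column direction.
    """
    n_x, n_y = extent
    h, w = labels_img.shape
    if w < n_x or h < n_y:
        raise ValueError(
            f"image of {w}x{h} px cannot cover a {n_x}x{n_y} raster extent"
        )
    # Image pixel -> raster cell by proportional block assignment.
    col_cell = np.minimum((np.arange(w) * n_x) // w, n_x - 1)
    row_cell = np.minimum((np.arange(h) * n_y) // h, n_y - 1)
    out = np.empty((n_x, n_y), dtype=np.int8)
    for cx in range(n_x):
        cols = labels_img[:, col_cell == cx]
        for cy in range(n_y):
            block = cols[row_cell == cy, :]
            counts = np.bincount(block.ravel(), minlength=3)
            out[cx, cy] = int(np.argmax(counts))  # ties -> lower label code
    return out


def read_void_mask(
    image_path: str | Path,
    extent: tuple[int, int],
    void_color_rule: Callable[[np.ndarray], np.ndarray] | None = None,
    outside_color_rule: Callable[[np.ndarray], np.ndarray] | None = None,
) -> VoidMask:
    """Derive a void/sediment mask from an image of the measurement area.

    ``void_color_rule`` maps an (h, w, 3) uint8 RGB array to a boolean void
    indicator per image pixel (default: near-black pixels, the appearance of
    embedding medium in transmitted light); ``outside_color_rule`` likewise
    flags pixels outside the sample outline (default: near-white).
    Image pixels are block-reduced to raster cells by majority vote.
    """
    from PIL import Image

    rgb = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.uint8)
    if void_color_rule is None:
        void_color_rule = lambda a: a.max(axis=-1) < 64  # noqa: E731
    if outside_color_rule is None:
        outside_color_rule = lambda a: a.min(axis=-1) > 224  # noqa: E731
    labels_img = np.full(rgb.shape[:2], SEDIMENT, dtype=np.int8)
    labels_img[void_color_rule(rgb)] = VOID
    labels_img[outside_color_rule(rgb)] = OUTSIDE
    return VoidMask(_block_majority(labels_img, extent))


def read_void_mask_grid(path: str | Path) -> VoidMask:
    """Read a mask from a TSV label grid (rows = y, columns = x; 0/1/2)."""
    grid = np.loadtxt(path, dtype=int, ndmin=2)
    return VoidMask(grid.T)  # file is (n_y, n_x); container is (n_x, n_y)


def write_void_mask_grid(mask: VoidMask, path: str | Path) -> None:
    np.savetxt(path, mask.labels.T, fmt="%d", delimiter="\t")


def write_void_mask_image(mask: VoidMask, path: str | Path, cell_px: int = 4) -> None:
    """Render a mask as a PNG (void black, sediment grey, outside white)."""
    from PIL import Image

    palette = {OUTSIDE: 255, SEDIMENT: 128, VOID: 0}
    img = np.vectorize(palette.get)(mask.labels.T).astype(np.uint8)  # (n_y, n_x)
    img = np.repeat(np.repeat(img, cell_px, axis=0), cell_px, axis=1)
    Image.fromarray(img, mode="L").save(path)


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as TSV: header ``x y <mz...>`` (4-decimal Da)."""
    path = Path(path)
    header = "x\ty" + "".join(f"\t{m:.4f}" for m in table.feature_mz)
    with path.open("w") as fh:
        fh.write(header + "\n")
        for (x, y), row in zip(table.pixel_index, table.matrix):
            fh.write(f"{x}\t{y}" + "".join(f"\t{v:.6g}" for v in row) + "\n")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["x", "y"]:
            raise ValueError(f"{path}: feature table header must start with x, y")
        feature_mz = np.array([float(t) for t in header[2:]])
        pixels: list[tuple[int, int]] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}, line {lineno}: {len(parts)} fields, expected {len(header)}"
                )
            pixels.append((int(parts[0]), int(parts[1])))
            rows.append([float(v) for v in parts[2:]])
    matrix = np.array(rows, dtype=float).reshape(len(pixels), feature_mz.size)
    return FeatureTable(feature_mz, matrix, np.array(pixels, dtype=int).reshape(-1, 2))


# ---------------------------------------------------------------------------
# Fingerprint models and manifests


def write_fingerprint_model(model: FingerprintModel, outdir: str | Path) -> None:
    """Write spatial/contribution matrices, error trace and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    comp_cols = [f"component_{i}" for i in range(model.n_components)]
    spatial = pd.DataFrame(model.spatial, columns=comp_cols)
    spatial.insert(0, "zone", np.arange(model.spatial.shape[0]))
    spatial.to_csv(outdir / "spatial.tsv", sep="\t", index=False, float_format="%.8g")
    contrib = pd.DataFrame(
        model.contributions.T,
        columns=comp_cols,
    )
    contrib.insert(0, "mz", [f"{m:.4f}" for m in model.feature_mz])
    contrib.to_csv(outdir / "contributions.tsv", sep="\t", index=False, float_format="%.8g")
    trace = pd.DataFrame(
        {"k": list(model.error_trace), "relative_error": list(model.error_trace.values())}
    )
    trace.to_csv(outdir / "error_trace.tsv", sep="\t", index=False, float_format="%.10g")
    manifest = {
        "n_components": model.n_components,
        "seed": model.seed,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "reconstruction_error": model.reconstruction_error,
        "error_trace": {str(k): v for k, v in model.error_trace.items()},
    }
    (outdir / "model.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_fingerprint_model(outdir: str | Path) -> FingerprintModel:
    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    spatial = pd.read_csv(outdir / "spatial.tsv", sep="\t").drop(columns="zone")
    contrib = pd.read_csv(outdir / "contributions.tsv", sep="\t")
    feature_mz = contrib["mz"].to_numpy(dtype=float)
    H = contrib.drop(columns="mz").to_numpy(dtype=float).T
    return FingerprintModel(
        n_components=int(meta["n_components"]),
        spatial=spatial.to_numpy(dtype=float),
        contributions=H,
        error_trace={int(k): float(v) for k, v in meta["error_trace"].items()},
        seed=int(meta["seed"]),
        feature_mz=feature_mz,
        n_iter=int(meta["n_iter"]),
        converged=bool(meta["converged"]),
    )


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
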