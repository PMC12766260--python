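"""End-to-end pipeline: simulate/read -> preprocess -> filter -> fingerprint -> render.

``RunConfig`` carries every stage's parameters (YAML round-trippable,
unknown keys rejected); ``run_all`` executes the stages in fixed order,
always writes intermediate artifacts so stages can be re-run
independently, and records a ``RunManifest`` with the parameter echo and
the feature funnel (spectra read, peaks dropped by the SNR filter,
features after alignment / sparsity / void filtering, selected component
count, final reconstruction error). The manifest is written even when a
stage fails part-way.

The default synthetic configuration analyzes the built-in stratified-core
scene; because that scene is a roughly tenfold scaled-down core (80 depth
units instead of ~800), its depth zones are 4 raster units wide — the
scaled analogue of 30-unit zones on a full-size section, which remains
the default for real-size data.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import io as mio
from .datatypes import SceneDataset
from .filtering import SparsityFilter, VoidRegionFilter
from .fingerprint import MolecularFingerprintNMF, maxabs_scale, zone_average
from .imaging import component_image, depth_profile, save_grid, save_heatmap, save_profile
from .preprocess import KDEPeakAligner, LockMassCalibrator, MedianNormalizer, SNRFilter, TICNormalizer
from .synthetic import GeneratorConfig, generate, make_default_scene

__all__ = ["RunConfig", "PipelineError", "run_all"]

logger = logging.getLogger("msistrat")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PreprocessParams:
    snr_min: float = 4.0
    lockmass_mz: Optional[float] = None
    lockmass_ppm: float = 20.0
    bin_width_da: float = 0.5
    kde_bandwidth_ppm: float = 2.0
    grid_step_ppm: float = 0.2
    prominence_min: float = 0.01


@dataclass
class FilterParams:
    zone_width: int = 30
    sparsity_threshold: float = 0.07
    void_ratio_max: float = 1.5


@dataclass
class FingerprintParams:
    zone_width: int = 30
    k_max: int = 20
    delta_tol: float = 0.0015
    criterion: str = "decrement"
    n_components: Optional[int] = None


@dataclass
class RenderParams:
    power: float = 5.0
    profile_bin_um: Optional[float] = None  # None -> one raster step
    smooth_window: int = 5


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    seed: int = 42
    scene: str = "synthetic"  # "synthetic" or "files"
    input_spectra: Optional[list[str]] = None
    input_mask: Optional[str] = None
    mz_window: tuple[float, float] = (150.0, 1000.0)
    pixel_pitch_um: float = 150.0
    depth_axis: str = "x"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    filtering: FilterParams = field(default_factory=FilterParams)
    fingerprint: FingerprintParams = field(default_factory=FingerprintParams)
    render: RenderParams = field(default_factory=RenderParams)
    log_level: str = "INFO"

    @classmethod
    def default_synthetic(cls, seed: int = 42) -> "RunConfig":
        """Config for the built-in scaled-down stratified-core scene."""
        cfg = cls(seed=seed)
        cfg.filtering.zone_width = 4
        cfg.fingerprint.zone_width = 4
        cfg.fingerprint.k_max = 8
        return cfg

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mz_window"] = list(self.mz_window)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, payload, path):
            names = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - set(names)
            if unknown:
                raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
            kwargs = {}
            for key, value in payload.items():
                f = names[key]
                if dataclasses.is_dataclass(f.type) or f.name in (
                    "preprocess",
                    "filtering",
                    "fingerprint",
                    "render",
                ):
                    sub = {
                        "preprocess": PreprocessParams,
                        "filtering": FilterParams,
                        "fingerprint": FingerprintParams,
                        "render": RenderParams,
                    }[f.name]
                    kwargs[key] = build(sub, value or {}, f"{path}.{key}")
                else:
                    kwargs[key] = value
            return dc_type(**kwargs)

        cfg = build(cls, dict(data), "config")
        cfg.mz_window = tuple(cfg.mz_window)
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _count_peaks(dataset: SceneDataset) -> int:
    return int(sum(s.n_peaks for s in dataset))


def run_all(
    config: RunConfig,
    outdir: str | Path,
    generator_config: GeneratorConfig | None = None,
) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    With ``scene="synthetic"`` the built-in default scene (or an explicit
    ``generator_config``) is realized first and its ground truth written
    alongside; with ``scene="files"`` the configured spectrum exports and
    mask are read. Missing inputs abort before any computation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict[str, Any] = {
        "parameters": config.to_dict(),
        "seed": config.seed,
        "started": datetime.datetime.now().isoformat(),
        "stages": [],
    }

    # Pre-flight: inputs must exist before anything is computed or written.
    if config.scene == "files":
        missing = [
            p
            for p in (config.input_spectra or []) + ([config.input_mask] if config.input_mask else [])
            if not Path(p).exists()
        ]
        if not config.input_spectra:
            raise PipelineError("pre-flight: no input spectra configured")
        if missing:
            raise PipelineError(f"pre-flight: missing inputs {missing}")
    elif config.scene != "synthetic":
        raise PipelineError(f"pre-flight: unknown scene kind {config.scene!r}")

    stage = "setup"
    try:
        # -- stage: acquire -------------------------------------------------
        stage = "simulate" if config.scene == "synthetic" else "read"
        if config.scene == "synthetic":
            gen = generator_config if generator_config is not None else make_default_scene(config.seed)
            dataset, mask, truth = generate(gen)
            mio.write_spectra(dataset, outdir / "spectra.csv")
            mio.write_void_mask_grid(mask, outdir / "mask.tsv")
            (outdir / "ground_truth.json").write_text(
                json.dumps(
                    {
                        "component_profiles": {
                            k: v.tolist() for k, v in truth.component_profiles.items()
                        },
                        "feature_membership": {
                            f"{mz:.4f}": c for mz, c in truth.feature_membership.items()
                        },
                        "matrix_mzs": truth.matrix_mzs,
                        "void_pixels": sorted([int(a), int(b)] for a, b in truth.void_pixels),
                    },
                    sort_keys=True,
                )
            )
        else:
            dataset = mio.read_spectra(
                config.input_spectra,
                mz_window=config.mz_window,
                pixel_pitch_um=config.pixel_pitch_um,
                depth_axis=config.depth_axis,
            )
            mask = mio.read_void_mask_grid(config.input_mask)
        manifest["n_spectra"] = len(dataset)
        manifest["n_peaks_raw"] = _count_peaks(dataset)
        manifest["stages"].append(stage)

        # -- stage: preprocess ---------------------------------------------
        stage = "preprocess"
        pp = config.preprocess
        filtered = SNRFilter(pp.snr_min).transform(dataset)
        manifest["n_peaks_after_snr"] = _count_peaks(filtered)
        manifest["n_peaks_dropped_snr"] = manifest["n_peaks_raw"] - manifest["n_peaks_after_snr"]
        if pp.lockmass_mz is not None:
            cal = LockMassCalibrator(pp.lockmass_mz, pp.lockmass_ppm)
            filtered = cal.transform(filtered)
            manifest["n_spectra_uncalibrated"] = cal.n_uncalibrated_
        median_ds = MedianNormalizer().transform(filtered)
        tic_ds = TICNormalizer().transform(filtered)
        aligner = KDEPeakAligner(
            bin_width_da=pp.bin_width_da,
            kde_bandwidth_ppm=pp.kde_bandwidth_ppm,
            grid_step_ppm=pp.grid_step_ppm,
            prominence_min=pp.prominence_min,
        )
        table_median = aligner.fit(median_ds).transform(median_ds)
        manifest["n_peaks_unassigned"] = aligner.n_dropped_peaks_
        table_tic = aligner.transform(tic_ds)
        manifest["n_features_aligned"] = table_median.n_features
        mio.write_feature_table(table_median, outdir / "features_median.tsv")
        mio.write_feature_table(table_tic, outdir / "features_tic.tsv")
        manifest["stages"].append(stage)

        # -- stage: filter ----------------------------------------------------
        stage = "filter"
        fp = config.filtering
        sparsity = SparsityFilter(fp.zone_width, fp.sparsity_threshold, config.depth_axis)
        sparsity.fit(table_median)
        table_median = sparsity.transform(table_median)
        table_tic = table_tic.select_features(sparsity.support_)
        manifest["n_features_after_sparsity"] = table_median.n_features
        voidf = VoidRegionFilter(ratio_max=fp.void_ratio_max)
        voidf.fit(table_median, mask)
        table_median = voidf.transform(table_median)
        table_tic = table_tic.select_features(voidf.support_)
        manifest["n_features_after_void"] = table_tic.n_features
        mio.write_feature_table(table_tic, outdir / "features_clean.tsv")
        report = {
            "sparsity_summary": sparsity.report_.summary.tolist(),
            "sparsity_retained": sparsity.support_.tolist(),
            "void_ratio": np.where(
                np.isfinite(voidf.report_.ratio), voidf.report_.ratio, -1.0
            ).tolist(),
            "void_excluded": voidf.report_.excluded.tolist(),
        }
        (outdir / "filter_report.json").write_text(json.dumps(report, sort_keys=True))
        manifest["stages"].append(stage)

        # -- stage: fingerprint ----------------------------------------------
        stage = "fingerprint"
        fg = config.fingerprint
        zm = zone_average(table_tic, fg.zone_width, config.depth_axis)
        zm_scaled, _, zero_cols = maxabs_scale(zm)
        nmf = MolecularFingerprintNMF(
            n_components=fg.n_components,
            k_max=fg.k_max,
            delta_tol=fg.delta_tol,
            criterion=fg.criterion,
            random_state=config.seed,
        ).fit(zm_scaled)
        model = nmf.model_
        manifest["n_zero_feature_columns"] = int(zero_cols.sum())
        manifest["selected_k"] = model.n_components
        manifest["reconstruction_error"] = model.reconstruction_error
        manifest["error_trace"] = {str(k): v for k, v in model.error_trace.items()}
        mio.write_fingerprint_model(model, outdir / "model")
        manifest["stages"].append(stage)

        # -- stage: render ---------------------------------------------------
        stage = "render"
        rp = config.render
        for comp in range(model.n_components):
            img = component_image(table_tic, model, comp, power=rp.power)
            save_grid(img, outdir / f"component_{comp}_grid.tsv")
            save_heatmap(img, outdir / f"component_{comp}.png")
            prof = depth_profile(
                img,
                pixel_pitch_um=config.pixel_pitch_um,
                bin_um=rp.profile_bin_um,
                window=rp.smooth_window,
                depth_axis=config.depth_axis,
            )
            save_profile(prof, outdir / f"component_{comp}_profile.tsv")
        manifest["stages"].append(stage)
        manifest["status"] = "complete"
    except PipelineError:
        manifest["status"] = f"failed at {stage}"
        raise
    except Exception as exc:
        manifest["status"] = f"failed at {stage}"
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        manifest["finished"] = datetime.datetime.now().isoformat()
        mio.write_manifest(manifest, outdir / "manifest.json")

    # Funnel sanity: feature counts never increase along the filter chain.
    assert (
        manifest["n_features_aligned"]
        >= manifest["n_features_after_sparsity"]
        >= manifest["n_features_after_void"]
    )
    logger.info(
        "pipeline complete: %d spectra, %d features aligned -> %d after filters, k=%d",
        manifest["n_spectra"],
        manifest["n_features_aligned"],
        manifest["n_features_after_void"],
        manifest["selected_k"],
    )
    return manifest
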