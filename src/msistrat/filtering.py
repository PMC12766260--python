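"""Spatially informed feature filtering: sparsity and void-region exclusion.

Two cleaning steps remove columns from an aligned feature table without
touching retained values:

* ``SparsityFilter`` bins the depth-axis coordinate into zones (default 30
  raster units), computes each feature's non-zero pixel fraction per zone,
  and keeps features whose *maximum* zone fraction reaches a threshold
  (default 7%). Using the per-zone maximum lets a feature confined to one
  thin depth band — exactly the signal class of interest in stratified
  sediment — survive, while pixels-scattered noise features fall below the
  threshold in every zone.
* ``VoidRegionFilter`` compares each feature's mean intensity over
  embedding-medium void pixels with its mean over sediment pixels and
  excludes features whose void/sediment enrichment ratio exceeds a
  threshold (default 1.5): the hallmark of MALDI-matrix-derived ions,
  which coat voids and sediment alike but find no competing analyte in
  the voids. Pixels labelled outside the sample are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import OUTSIDE, SEDIMENT, VOID, FeatureTable, VoidMask

__all__ = [
    "SparsityReport",
    "VoidReport",
    "compute_sparsity",
    "sparsity_filter",
    "void_exclusion",
    "SparsityFilter",
    "VoidRegionFilter",
]


@dataclass
class SparsityReport:
    """Per-feature, per-zone non-zero fractions and the retention decision."""

    zone_fractions: np.ndarray  # (n_features, n_zones) in [0, 1]
    zone_bounds: np.ndarray  # (n_zones, 2) half-open [lo, hi) raster intervals
    summary: np.ndarray  # (n_features,) max fraction over zones
    retained: np.ndarray | None = None  # set by sparsity_filter


@dataclass
class VoidReport:
    """Per-feature void/sediment mean intensities and exclusion decision."""

    void_mean: np.ndarray
    sediment_mean: np.ndarray
    ratio: np.ndarray  # inf where sediment mean is 0 but void mean > 0
    excluded: np.ndarray


def _depth_coord(table: FeatureTable, depth_axis: str) -> np.ndarray:
    return table.pixel_index[:, 0] if depth_axis == "x" else table.pixel_index[:, 1]


def compute_sparsity(
    table: FeatureTable, zone_width: int = 30, depth_axis: str = "x"
) -> SparsityReport:
    """Non-zero pixel fraction of every feature in every depth zone.

    Zones are the half-open intervals ``[k*w, (k+1)*w)`` anchored at
    coordinate 0; a final partial zone is kept when it holds at least one
    pixel. The summary statistic is the maximum fraction over zones.
    """
    if zone_width < 1:
        raise ValueError("zone_width must be >= 1")
    if table.n_pixels == 0 or table.n_features == 0:
        return SparsityReport(
            np.zeros((table.n_features, 0)),
            np.zeros((0, 2), dtype=int),
            np.zeros(table.n_features),
        )
    depth = _depth_coord(table, depth_axis)
    zone_of = depth // zone_width
    zones = np.unique(zone_of)
    fractions = np.empty((table.n_features, zones.size))
    bounds = np.empty((zones.size, 2), dtype=int)
    for j, z in enumerate(zones):
        in_zone = zone_of == z
        fractions[:, j] = (table.matrix[in_zone] > 0).sum(axis=0) / in_zone.sum()
        bounds[j] = (z * zone_width, (z + 1) * zone_width)
    return SparsityReport(fractions, bounds, fractions.max(axis=1))


def sparsity_filter(
    table: FeatureTable, report: SparsityReport, threshold: float = 0.07
) -> FeatureTable:
    """Retain features whose maximum zone fraction reaches ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    keep = report.summary >= threshold
    report.retained = keep
    return table.select_features(keep)


def void_exclusion(
    table: FeatureTable, mask: VoidMask, ratio_max: float = 1.5
) -> tuple[FeatureTable, VoidReport]:
    """Exclude features disproportionately concentrated in void pixels.

    The enrichment ratio is (mean intensity over void pixels) / (mean
    intensity over sediment pixels); a feature is excluded when the ratio
    exceeds ``ratio_max`` or when it has positive void intensity but zero
    sediment intensity. ``outside`` pixels never enter either mean.
    """
    if ratio_max <= 0:
        raise ValueError("ratio_max must be positive")
    labels = mask.labels_for(table.pixel_index)
    is_void = labels == VOID
    is_sed = labels == SEDIMENT
    if not is_sed.any() or not is_void.any():
        raise ValueError("mask must contain at least one sediment and one void pixel")
    void_mean = table.matrix[is_void].mean(axis=0)
    sed_mean = table.matrix[is_sed].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            sed_mean > 0,
            void_mean / np.where(sed_mean > 0, sed_mean, 1.0),
            np.where(void_mean > 0, np.inf, 0.0),
        )
    excluded = ratio > ratio_max
    report = VoidReport(void_mean, sed_mean, ratio, excluded)
    return table.select_features(~excluded), report


class SparsityFilter(BaseEstimator, TransformerMixin):
    """Estimator form of the zone-sparsity filter.

    ``fit`` computes the :class:`SparsityReport` (``report_``) and the
    boolean retention mask (``support_``); ``transform`` drops the columns.
    """

    def __init__(self, zone_width: int = 30, threshold: float = 0.07, depth_axis: str = "x"):
        self.zone_width = zone_width
        self.threshold = threshold
        self.depth_axis = depth_axis

    def fit(self, table: FeatureTable, y=None):
        self.report_ = compute_sparsity(table, self.zone_width, self.depth_axis)
        self.support_ = self.report_.summary >= self.threshold
        self.report_.retained = self.support_
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        return table.select_features(self.support_)


class VoidRegionFilter(BaseEstimator, TransformerMixin):
    """Estimator form of void-enrichment exclusion.

    ``fit`` needs the void mask (pass it as ``y`` or via the constructor);
    ``report_`` and ``support_`` are available afterwards.
    """

    def __init__(self, mask: VoidMask | None = None, ratio_max: float = 1.5):
        self.mask = mask
        self.ratio_max = ratio_max

    def fit(self, table: FeatureTable, y: VoidMask | None = None):
        mask = y if y is not None else self.mask
        if mask is None:
            raise ValueError("VoidRegionFilter requires a VoidMask")
        _, self.report_ = void_exclusion(table, mask, self.ratio_max)
        self.support_ = ~self.report_.excluded
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        return table.select_features(self.support_)
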