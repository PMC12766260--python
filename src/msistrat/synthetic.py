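"""Synthetic MALDI-MSI scenes with planted stratified lipid components.

The generator emulates the statistical structure of a sediment-core MSI
measurement: a handful of molecular components, each a set of
characteristic m/z features sharing one spatial pattern (a thin
near-surface band, a suboxic zone with a sharp lower boundary, an anoxic
zone box, a concretion-like blob); matrix-derived ions concentrated in
embedding-medium voids; ppm-scale mass jitter; multiplicative lognormal
intensity noise with per-pixel dropout; and spurious low-SNR instrument
noise peaks. Ground truth (true spatial maps, feature memberships, true
centroids, void pixels) is returned alongside so recovery can be scored.

Everything is driven by one integer seed through independent
``numpy.random`` sub-streams per stage, so output is reproducible
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import SEDIMENT, VOID, PixelSpectrum, SceneDataset, VoidMask

__all__ = [
    "ComponentSpec",
    "GeneratorConfig",
    "GroundTruth",
    "make_default_scene",
    "generate",
    "SceneSimulator",
]

# Profiles below this value are treated as zero support (no emission).
PROFILE_FLOOR = 0.02


# ---------------------------------------------------------------------------
# Spatial profile families


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _profile_values(profile: dict, n_x: int, n_y: int, depth_axis: str) -> np.ndarray:
    """Evaluate a parametric profile on the raster grid; values in [0, 1].

    ``d`` is the depth coordinate (axis configured on the scene), ``t`` the
    transverse coordinate. Families: ``sigmoid_box`` (smooth rise/fall along
    depth), ``box`` (hard half-open depth interval), ``gaussian_blob``,
    ``exp_decay`` (downcore decay), ``constant``.
    """
    x, y = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="ij")
    d, t = (x, y) if depth_axis == "x" else (y, x)
    kind = profile["kind"]
    if kind == "sigmoid_box":
        w = profile.get("width", 0.5)
        vals = _sigmoid((d - profile["rise"]) / w) * _sigmoid((profile["fall"] - d) / w)
    elif kind == "box":
        vals = ((d >= profile["lo"]) & (d < profile["hi"])).astype(float)
    elif kind == "gaussian_blob":
        vals = np.exp(
            -0.5 * ((d - profile["center_depth"]) / profile["sigma_depth"]) ** 2
            - 0.5 * ((t - profile["center_across"]) / profile["sigma_across"]) ** 2
        )
    elif kind == "exp_decay":
        vals = np.exp(-d / profile["scale"])
    elif kind == "constant":
        vals = np.full_like(d, float(profile["value"]), dtype=float)
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    return np.clip(vals, 0.0, 1.0)


@dataclass
class ComponentSpec:
    """One planted molecular component: feature signature + spatial profile."""

    id: str
    signature: list[tuple[float, float]]  # (mz in Da, relative abundance > 0)
    profile: dict  # parametric profile, see _profile_values

    def __post_init__(self) -> None:
        mzs = [m for m, _ in self.signature]
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"component {self.id}: duplicate signature m/z")
        if any(a <= 0 for _, a in self.signature):
            raise ValueError(f"component {self.id}: abundances must be positive")

    def profile_values(self, n_x: int, n_y: int, depth_axis: str = "x") -> np.ndarray:
        return _profile_values(self.profile, n_x, n_y, depth_axis)


@dataclass
class GeneratorConfig:
    """Full description of a synthetic scene.

    Noise defaults describe a well-behaved high-resolution (FTICR-class)
    acquisition: ~1 ppm mass jitter after lock-mass calibration, a strong
    per-pixel detection-efficiency factor (50% CV, the shot-to-shot and
    matrix-crystallization variability that per-spectrum normalization is
    designed to cancel) on top of ~10% per-peak residual variability, 1%
    dropout of present features, a handful of sub-threshold noise peaks
    per pixel, and matrix ions more than an order of magnitude enriched
    in void pixels. Inside voids the *presence* of analyte features is
    suppressed (embedding medium carries no sediment lipids), not merely
    their intensity.
    """

    grid: tuple[int, int] = (80, 10)  # (n_x, n_y); x is the depth axis
    components: list[ComponentSpec] = field(default_factory=list)
    matrix_features: list[tuple[float, float]] = field(default_factory=list)
    void_blob_count: int = 3
    void_blob_radius: tuple[float, float] = (1.0, 2.5)  # cells, min/max
    mass_jitter_ppm: float = 1.0
    intensity_cv: float = 0.10
    pixel_efficiency_cv: float = 0.5
    dropout_p: float = 0.01
    noise_peaks_per_pixel: float = 5.0
    snr_real: float = 20.0  # median SNR of genuine peaks (drawn above 4)
    snr_noise: tuple[float, float] = (1.0, 3.9)  # uniform range, below threshold
    matrix_void_rate: float = 0.9  # presence probability of a matrix ion in a void pixel
    matrix_sediment_rate: float = 0.06  # ... in a sediment pixel
    void_signal_suppression: float = 0.05  # analyte presence factor inside voids
    base_intensity: float = 1000.0
    mz_window: tuple[float, float] = (150.0, 1000.0)
    pixel_pitch_um: float = 150.0
    polarity: str = "negative"
    depth_axis: str = "x"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_p, self.matrix_void_rate, self.matrix_sediment_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mass_jitter_ppm < 0:
            raise ValueError("mass_jitter_ppm must be non-negative")
        lo, hi = self.mz_window
        for comp in self.components:
            for mz, _ in comp.signature:
                if not lo <= mz <= hi:
                    raise ValueError(
                        f"component {comp.id}: signature m/z {mz} outside window {self.mz_window}"
                    )


@dataclass
class GroundTruth:
    """What was planted: spatial maps, memberships, centroids, void pixels."""

    component_profiles: dict[str, np.ndarray]  # id -> (n_x, n_y) in [0, 1]
    feature_membership: dict[float, str]  # true centroid m/z -> component id
    matrix_mzs: list[float]
    void_pixels: set[tuple[int, int]]

    @property
    def component_ids(self) -> list[str]:
        return list(self.component_profiles)

    def signature_of(self, component_id: str) -> set[float]:
        return {m for m, c in self.feature_membership.items() if c == component_id}


# ---------------------------------------------------------------------------
# Default scene


def _draw_signature(
    rng: np.random.Generator,
    n: int,
    lo: float,
    hi: float,
    taken: list[float],
    min_sep: float = 0.2,
) -> list[tuple[float, float]]:
    """Draw n signature (m/z, abundance) pairs separated by >= min_sep Da."""
    out: list[tuple[float, float]] = []
    while len(out) < n:
        mz = round(float(rng.uniform(lo, hi)), 4)
        if all(abs(mz - t) >= min_sep for t in taken):
            taken.append(mz)
            out.append((mz, round(float(rng.uniform(0.3, 1.0)), 3)))
    return sorted(out)


def make_default_scene(seed: int) -> GeneratorConfig:
    """Default stratified-sediment scene on an 80 x 10 raster (x = depth).

    Four components mimic sediment-core zonation and together cover the
    whole depth range, as real pixels always carry some signal: a thin
    3-pixel band at the very surface (depth 0-2), a suboxic zone rising at
    depth ~2.5 and vanishing sharply at depth 29-30, an anoxic zone box
    from depth 30 downward, and a concretion-like blob around depth 45.
    Each carries 40 characteristic m/z features, reflecting the dozens of
    co-occurring lipid species a real component comprises. Thirty
    matrix-derived ions (matrix clusters are numerous in MALDI spectra)
    concentrate in void pixels and ~5 low-SNR noise peaks per pixel mimic
    instrument noise. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 91001]))
    taken: list[float] = []
    comps = [
        ComponentSpec(
            "surface_band",
            _draw_signature(rng, 40, 200.0, 950.0, taken),
            {"kind": "box", "lo": 0, "hi": 3},
        ),
        ComponentSpec(
            "suboxic",
            _draw_signature(rng, 40, 200.0, 950.0, taken),
            {"kind": "sigmoid_box", "rise": 2.5, "fall": 29.0, "width": 0.5},
        ),
        ComponentSpec(
            "anoxic",
            _draw_signature(rng, 40, 200.0, 950.0, taken),
            {"kind": "box", "lo": 30, "hi": 80},
        ),
        ComponentSpec(
            "concretion",
            _draw_signature(rng, 40, 200.0, 950.0, taken),
            {
                "kind": "gaussian_blob",
                "center_depth": 45.0,
                "sigma_depth": 5.0,
                "center_across": 4.5,
                "sigma_across": 2.5,
            },
        ),
    ]
    matrix_features = [(mz, 3.0) for mz, _ in _draw_signature(rng, 30, 200.0, 950.0, taken)]
    return GeneratorConfig(components=comps, matrix_features=matrix_features, seed=int(seed))


# ---------------------------------------------------------------------------
# Generation


def _make_void_mask(config: GeneratorConfig, rng: np.random.Generator) -> VoidMask:
    """Elliptical void blobs on an otherwise all-sediment grid."""
    n_x, n_y = config.grid
    labels = np.full((n_x, n_y), SEDIMENT, dtype=np.int8)
    x, y = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="ij")
    r_lo, r_hi = config.void_blob_radius
    for _ in range(config.void_blob_count):
        cx = rng.uniform(0, n_x)
        cy = rng.uniform(0, n_y)
        rx = rng.uniform(r_lo, r_hi)
        ry = rng.uniform(r_lo, r_hi)
        labels[((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0] = VOID
    if not (labels == SEDIMENT).any():  # voids must never swallow the scene
        labels[0, 0] = SEDIMENT
    return VoidMask(labels)


def generate(config: GeneratorConfig) -> tuple[SceneDataset, VoidMask, GroundTruth]:
    """Realize one stochastic scene from a :class:`GeneratorConfig`.

    For every pixel, each component feature on the profile's support is
    emitted with probability ``1 - dropout_p`` at mean intensity
    ``base * abundance * profile`` (so the expected intensity map is
    proportional to the planted profile), times a shared per-pixel
    detection-efficiency factor and per-peak lognormal noise, with
    ppm-scale Gaussian mass jitter. In void pixels the analyte presence
    probability is multiplied by ``void_signal_suppression``. Matrix ions
    appear with a high rate in void pixels and a low rate in sediment;
    noise peaks land at uniform random m/z with sub-threshold SNR.
    """
    lo, hi = config.mz_window
    n_x, n_y = config.grid
    ss = np.random.SeedSequence([int(config.seed), 4242])
    rng_mask, rng_comp, rng_matrix, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    mask = _make_void_mask(config, rng_mask)
    profiles = {
        c.id: c.profile_values(n_x, n_y, config.depth_axis) for c in config.components
    }
    sigma_ln = math.sqrt(math.log(1.0 + config.intensity_cv**2))
    jitter = config.mass_jitter_ppm * 1e-6
    snr_sigma = 0.5

    membership = {
        mz: c.id for c in config.components for mz, _ in c.signature
    }
    if len(membership) != sum(len(c.signature) for c in config.components):
        raise ValueError("signature m/z values must be unique across components")

    eff_sigma = math.sqrt(math.log(1.0 + config.pixel_efficiency_cv**2))

    spectra: list[PixelSpectrum] = []
    for px in range(n_x):
        for py in range(n_y):
            in_void = mask.labels[px, py] == VOID
            # Shared per-pixel detection efficiency (laser/matrix variability);
            # per-spectrum normalization is meant to cancel exactly this.
            efficiency = rng_comp.lognormal(0.0, eff_sigma)
            mzs: list[float] = []
            intens: list[float] = []
            snrs: list[float] = []
            # Planted component features; analyte presence is suppressed in
            # voids (embedding medium carries no sediment lipids).
            p_present = 1.0 - config.dropout_p
            if in_void:
                p_present *= config.void_signal_suppression
            for comp in config.components:
                prof = profiles[comp.id][px, py]
                if prof < PROFILE_FLOOR:
                    continue
                for mz_true, abundance in comp.signature:
                    if rng_comp.random() >= p_present:
                        continue
                    inten = (
                        config.base_intensity
                        * abundance
                        * prof
                        * efficiency
                        * rng_comp.lognormal(0.0, sigma_ln)
                    )
                    mzs.append(mz_true * (1.0 + rng_comp.normal(0.0, jitter)))
                    intens.append(inten)
                    snrs.append(4.0 + rng_comp.lognormal(math.log(config.snr_real - 4.0), snr_sigma))
            # Matrix-derived ions (void-enriched)
            rate = config.matrix_void_rate if in_void else config.matrix_sediment_rate
            for mz_true, abundance in config.matrix_features:
                if rng_matrix.random() < rate:
                    mzs.append(mz_true * (1.0 + rng_matrix.normal(0.0, jitter)))
                    intens.append(
                        config.base_intensity
                        * abundance
                        * efficiency
                        * rng_matrix.lognormal(0.0, sigma_ln)
                    )
                    snrs.append(4.0 + rng_matrix.lognormal(math.log(config.snr_real - 4.0), snr_sigma))
            # Instrument noise peaks, below the SNR threshold
            for _ in range(rng_noise.poisson(config.noise_peaks_per_pixel)):
                mzs.append(float(rng_noise.uniform(lo, hi)))
                intens.append(50.0 * rng_noise.lognormal(0.0, sigma_ln))
                snrs.append(float(rng_noise.uniform(*config.snr_noise)))

            mz_arr = np.asarray(mzs)
            order = np.argsort(mz_arr, kind="stable")
            mz_arr = mz_arr[order]
            inten_arr = np.asarray(intens)[order]
            snr_arr = np.asarray(snrs)[order]
            # Collapse (vanishingly rare) exact m/z collisions
            if mz_arr.size > 1 and np.any(np.diff(mz_arr) == 0):
                uniq, inv = np.unique(mz_arr, return_inverse=True)
                inten_c = np.zeros_like(uniq)
                snr_c = np.zeros_like(uniq)
                np.add.at(inten_c, inv, inten_arr)
                np.maximum.at(snr_c, inv, snr_arr)
                mz_arr, inten_arr, snr_arr = uniq, inten_c, snr_c
            spectra.append(PixelSpectrum(px, py, mz_arr, inten_arr, snr_arr))

    dataset = SceneDataset(
        spectra,
        pixel_pitch_um=config.pixel_pitch_um,
        mz_window=config.mz_window,
        polarity=config.polarity,
        depth_axis=config.depth_axis,
    )
    truth = GroundTruth(
        component_profiles=profiles,
        feature_membership=membership,
        matrix_mzs=[m for m, _ in config.matrix_features],
        void_pixels={tuple(c) for c in np.argwhere(mask.labels == VOID)},
    )
    return dataset, mask, truth


class SceneSimulator:
    """Estimator-style wrapper around :func:`generate`.

    ``sample()`` realizes a scene from the held config; repeated calls with
    the same config return identical scenes (the seed lives in the config).
    """

    def __init__(self, config: GeneratorConfig | None = None, seed: int = 0):
        self.config = config if config is not None else make_default_scene(seed)

    def sample(self) -> tuple[SceneDataset, VoidMask, GroundTruth]:
        return generate(self.config)
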