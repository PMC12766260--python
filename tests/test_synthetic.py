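"""Synthetic scene generator: determinism, planted structure, noise models."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from msistrat import generate, make_default_scene
from msistrat.datatypes import VOID
from msistrat.io import write_spectra
from msistrat.synthetic import PROFILE_FLOOR


class TestDefaultScene:
    def test_same_seed_identical_config(self):
        a, b = make_default_scene(42), make_default_scene(42)
        assert a == b

    def test_different_seed_different_signatures(self):
        a, b = make_default_scene(1), make_default_scene(2)
        assert a.components[0].signature != b.components[0].signature

    def test_suboxic_and_anoxic_zones_barely_overlap(self):
        """The sharp redox transition: both profiles exceed 0.05 in < 5% of depth bins."""
        cfg = make_default_scene(0)
        profs = {c.id: c.profile_values(*cfg.grid) for c in cfg.components}
        sub = profs["suboxic"][:, 0]
        ano = profs["anoxic"][:, 0]
        overlap = np.sum((sub > 0.05) & (ano > 0.05)) / cfg.grid[0]
        assert overlap < 0.05

    def test_grid_spans_12mm_by_1p5mm(self):
        cfg = make_default_scene(0)
        n_x, n_y = cfg.grid
        assert n_x * cfg.pixel_pitch_um == 12_000  # 12.0 mm along depth
        assert n_y * cfg.pixel_pitch_um == 1_500

    def test_signature_mz_inside_window(self):
        cfg = make_default_scene(3)
        lo, hi = cfg.mz_window
        for comp in cfg.components:
            assert all(lo <= m <= hi for m, _ in comp.signature)

    def test_out_of_window_signature_rejected(self):
        cfg = make_default_scene(0)
        bad = dataclasses.replace(cfg)
        bad.components[0].signature[0] = (120.0, 1.0)
        with pytest.raises(ValueError, match="outside window"):
            dataclasses.replace(bad)


class TestGenerate:
    def test_bit_identical_under_fixed_seed(self, tmp_path):
        ds1, m1, _ = generate(make_default_scene(7))
        ds2, m2, _ = generate(make_default_scene(7))
        write_spectra(ds1, tmp_path / "a.csv")
        write_spectra(ds2, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_full_dropout_removes_all_component_peaks(self):
        cfg = make_default_scene(0)
        cfg.dropout_p = 1.0
        cfg.matrix_features = []
        cfg.noise_peaks_per_pixel = 0.0
        ds, _, _ = generate(cfg)
        assert all(s.n_peaks == 0 for s in ds)

    def test_zero_jitter_gives_exact_centroids(self):
        cfg = make_default_scene(0)
        cfg.mass_jitter_ppm = 0.0
        cfg.noise_peaks_per_pixel = 0.0
        cfg.matrix_features = []
        ds, _, truth = generate(cfg)
        true_mzs = np.array(sorted(truth.feature_membership))
        for s in ds:
            for mz in s.mz:
                assert np.isclose(true_mzs, mz, rtol=0, atol=1e-9).any()

    def test_jitter_mean_near_zero(self):
        """Monte-Carlo check of the ppm jitter model over >= 1e4 peaks."""
        cfg = make_default_scene(0)
        cfg.mass_jitter_ppm = 3.0
        cfg.noise_peaks_per_pixel = 0.0
        cfg.matrix_features = []
        ds, _, truth = generate(cfg)
        true_mzs = np.array(sorted(truth.feature_membership))
        devs = []
        for s in ds:
            idx = np.argmin(np.abs(s.mz[:, None] - true_mzs[None, :]), axis=1)
            devs.extend(((s.mz - true_mzs[idx]) / true_mzs[idx]) * 1e6)
        devs = np.asarray(devs)
        assert devs.size >= 10_000
        se = devs.std(ddof=1) / np.sqrt(devs.size)
        assert abs(devs.mean()) < 3 * se

    def test_expected_intensity_tracks_profile(self):
        """Average of many realizations is proportional to the planted profile."""
        cfg = make_default_scene(0)
        cfg.grid = (24, 4)
        cfg.components = [c for c in cfg.components if c.id == "suboxic"]
        cfg.components[0].profile = {"kind": "sigmoid_box", "rise": 4.0, "fall": 18.0, "width": 1.5}
        cfg.components[0].signature = cfg.components[0].signature[:3]
        cfg.matrix_features = []
        cfg.noise_peaks_per_pixel = 0.0
        cfg.void_blob_count = 0
        cfg.pixel_efficiency_cv = 0.0
        mz0, a0 = cfg.components[0].signature[0]
        prof = cfg.components[0].profile_values(*cfg.grid)
        acc = np.zeros(cfg.grid)
        n_rep = 60
        for rep in range(n_rep):
            cfg.seed = 1000 + rep
            ds, _, _ = generate(cfg)
            for s in ds:
                hit = np.isclose(s.mz, mz0, rtol=5e-6)
                if hit.any():
                    acc[s.x, s.y] += s.intensity[hit].sum()
        acc /= n_rep
        expected = cfg.base_intensity * a0 * prof * (1 - cfg.dropout_p)
        on = prof >= PROFILE_FLOOR
        ratio = acc[on] / expected[on]
        assert abs(ratio.mean() - 1.0) < 0.05
        # and the spatial shape correlates essentially perfectly
        r = np.corrcoef(acc.ravel(), (prof * (prof >= PROFILE_FLOOR)).ravel())[0, 1]
        assert r > 0.99

    def test_matrix_intensity_concentrated_in_voids(self, default_scene):
        cfg, ds, mask, truth = default_scene
        void_mass = sed_mass = 0.0
        n_void = int((mask.labels == VOID).sum())
        n_sed = mask.labels.size - n_void
        for s in ds:
            in_void = (s.x, s.y) in truth.void_pixels
            for mz in truth.matrix_mzs:
                hit = np.isclose(s.mz, mz, rtol=5e-6)
                if in_void:
                    void_mass += s.intensity[hit].sum()
                else:
                    sed_mass += s.intensity[hit].sum()
        enrichment = (void_mass / n_void) / (sed_mass / n_sed)
        # presence rates 0.9 vs 0.06 -> ~15x per-pixel enrichment
        assert enrichment > 5.0

    def test_real_peaks_above_and_noise_below_snr_threshold(self):
        cfg = make_default_scene(9)
        cfg.noise_peaks_per_pixel = 0.0
        ds_real, _, _ = generate(cfg)
        assert all((s.snr >= 4.0).all() for s in ds_real)

        cfg = make_default_scene(9)
        cfg.dropout_p = 1.0
        cfg.matrix_features = []
        ds_noise, _, _ = generate(cfg)
        assert all((s.snr < 4.0).all() for s in ds_noise)
        assert any(s.n_peaks for s in ds_noise)
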