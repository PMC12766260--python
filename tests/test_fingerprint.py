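"""Zone averaging, MaxAbs scaling, and the NMF fingerprint machinery."""

from __future__ import annotations

import numpy as np
import pytest

from msistrat import (
    FeatureTable,
    MolecularFingerprintNMF,
    ZoneMatrix,
    fit_nmf,
    maxabs_scale,
    select_n_components,
    top_features,
    zone_average,
)
from msistrat.fingerprint import _sweep

from conftest import random_table


def planted_rank(seed, n_zones=20, n_feat=50, k=3):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0, 1, (n_zones, k))
    H = rng.uniform(0, 1, (k, n_feat))
    return W @ H


class TestZoneAverage:
    def test_mean_includes_zeros(self):
        t = FeatureTable(
            np.array([500.0]), np.array([[0.0], [4.0]]), np.array([[0, 0], [1, 0]])
        )
        zm = zone_average(t, zone_width=2)
        assert zm.matrix[0, 0] == pytest.approx(2.0)

    def test_constant_table(self):
        t = FeatureTable(
            np.array([500.0]), np.full((8, 1), 3.3), np.array([(d, 0) for d in range(8)])
        )
        zm = zone_average(t, zone_width=3)
        np.testing.assert_allclose(zm.matrix, 3.3)
        assert zm.n_zones == 3  # partial last zone kept

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_x=int(rng.integers(4, 15)))
        w = int(rng.integers(1, 6))
        zm = zone_average(t, zone_width=w)
        depth = t.pixel_index[:, 0]
        for j, z in enumerate(sorted(set(depth // w))):
            rows = depth // w == z
            np.testing.assert_allclose(zm.matrix[j], t.matrix[rows].mean(axis=0))


class TestMaxAbsScale:
    def _zm(self, matrix):
        f = matrix.shape[1]
        return ZoneMatrix(matrix, np.array([[i, i + 1] for i in range(matrix.shape[0])]),
                          np.arange(f) + 200.0)

    def test_column_example(self):
        scaled, scale, zero = maxabs_scale(self._zm(np.array([[1.0], [2.0], [4.0]])))
        np.testing.assert_allclose(scaled.matrix[:, 0], [0.25, 0.5, 1.0])
        assert scale[0] == 4.0 and not zero[0]

    def test_zero_column_flagged_unchanged(self):
        scaled, _, zero = maxabs_scale(self._zm(np.zeros((3, 2))))
        assert zero.all()
        np.testing.assert_array_equal(scaled.matrix, 0.0)

    def test_every_scaled_column_peaks_at_one(self):
        rng = np.random.default_rng(4)
        scaled, _, zero = maxabs_scale(self._zm(rng.uniform(0, 9, (6, 5))))
        np.testing.assert_allclose(scaled.matrix.max(axis=0)[~zero], 1.0)

    def test_scale_invariance_of_model(self):
        """Rescaling one input column leaves the scaled matrix, and hence
        the fitted factors, unchanged."""
        X = planted_rank(0)
        X2 = X.copy()
        X2[:, 3] *= 37.5
        s1, _, _ = maxabs_scale(self._zm(X))
        s2, _, _ = maxabs_scale(self._zm(X2))
        np.testing.assert_allclose(s1.matrix, s2.matrix, atol=1e-14)
        m1 = fit_nmf(s1, 3, seed=0)
        m2 = fit_nmf(s2, 3, seed=0)
        np.testing.assert_allclose(m1.spatial, m2.spatial, rtol=1e-6, atol=1e-9)


class TestComponentSelection:
    def test_exact_rank3_matrix_selects_3(self):
        X = planted_rank(0)
        k, trace = select_n_components(X, k_max=8, seed=0)
        assert k == 3
        assert trace[3] < 1e-6

    def test_rank1_matrix_selects_1(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.uniform(0.1, 1, 20), rng.uniform(0.1, 1, 40))
        k, _ = select_n_components(X, k_max=5, seed=0)
        assert k == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_error_trace_non_increasing(self, seed):
        X = np.random.default_rng(seed).uniform(0, 1, (12, 25))
        with pytest.warns(UserWarning):
            _, trace, _, _ = _sweep(X, 8, 1e-12, 0, "decrement", 1e-10, 50000)
        errs = [trace[k] for k in sorted(trace)]
        assert (np.diff(errs) <= 1e-9).all()

    def test_kmax_capped_with_warning(self):
        X = np.random.default_rng(0).uniform(0, 1, (4, 6))
        with pytest.warns(UserWarning, match="capped"):
            k, _ = select_n_components(X, k_max=10, delta_tol=1e-12, seed=0)
        assert k <= 4

    def test_absolute_criterion(self):
        X = planted_rank(2)
        k, trace = select_n_components(X, k_max=6, seed=0, criterion="absolute", delta_tol=1e-4)
        assert k == 3 and trace[3] < 1e-4


class TestFitNMF:
    def _zm(self, X):
        return ZoneMatrix(X, np.array([[i, i + 1] for i in range(X.shape[0])]),
                          np.arange(X.shape[1]) + 200.0)

    def test_planted_factorization_recovered(self):
        X = planted_rank(5)
        model = fit_nmf(self._zm(X), 3, seed=1)
        assert model.reconstruction_error < 1e-4

    def test_rank1_constant_matrix_exact(self):
        X = np.full((5, 7), 2.5)
        model = fit_nmf(self._zm(X), 1, seed=0)
        np.testing.assert_allclose(model.reconstruct(), X, atol=1e-10)

    def test_same_seed_bit_identical(self):
        X = planted_rank(6)
        m1 = fit_nmf(self._zm(X), 3, seed=9)
        m2 = fit_nmf(self._zm(X), 3, seed=9)
        assert np.array_equal(m1.spatial, m2.spatial)
        assert np.array_equal(m1.contributions, m2.contributions)

    def test_recorded_error_matches_recomputation(self):
        X = np.random.default_rng(2).uniform(0, 1, (10, 20))
        model = fit_nmf(self._zm(X), 4, seed=0)
        recomputed = np.linalg.norm(X - model.reconstruct()) / np.linalg.norm(X)
        assert abs(recomputed - model.reconstruction_error) < 1e-10


class TestTopFeatures:
    def _model(self, contributions):
        H = np.asarray(contributions, dtype=float)
        W = np.ones((2, H.shape[0]))
        from msistrat.datatypes import FingerprintModel

        return FingerprintModel(H.shape[0], W, H, {H.shape[0]: 0.0}, seed=0,
                                feature_mz=np.arange(H.shape[1]) + 100.0)

    def test_ranking_example(self):
        model = self._model([[0.1, 0.9, 0.5]])
        assert top_features(model, 0, 2) == [1, 2]

    def test_n_zero_empty(self):
        model = self._model([[0.3, 0.2]])
        assert top_features(model, 0, 0) == []

    def test_ties_break_to_lower_mz(self):
        model = self._model([[0.5, 0.9, 0.5]])
        assert top_features(model, 0, 3) == [1, 0, 2]

    def test_n_beyond_count_returns_full_list(self):
        model = self._model([[0.1, 0.2]])
        assert len(top_features(model, 0, 99)) == 2


class TestEstimator:
    def test_sklearn_get_set_params(self):
        est = MolecularFingerprintNMF(k_max=5)
        params = est.get_params()
        assert params["k_max"] == 5
        est.set_params(delta_tol=0.01)
        assert est.delta_tol == 0.01

    def test_fit_selects_and_exposes_attributes(self):
        X = planted_rank(3)
        est = MolecularFingerprintNMF(k_max=6, random_state=0).fit(X)
        assert est.n_components_ == 3
        assert est.spatial_.shape == (20, 3)
        assert est.contributions_.shape == (3, 50)
        assert est.reconstruction_err_ == est.error_trace_[3]

    def test_transform_projects_onto_fixed_pseudospectra(self):
        X = planted_rank(4)
        est = MolecularFingerprintNMF(n_components=3, random_state=0).fit(X)
        W = est.transform(X)
        err = np.linalg.norm(X - W @ est.contributions_) / np.linalg.norm(X)
        assert err < 1e-3
        assert (W >= 0).all()
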