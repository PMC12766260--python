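"""Molecular fingerprint extraction by non-negative matrix factorization.

The cleaned, TIC-normalized feature table is averaged over depth zones
(noise reduction), each feature column is scaled to [0, 1] by its maximum
(so high- and low-abundance species contribute equally), and the resulting
zones x features matrix X is factorized as X ~ W H with W, H >= 0: the
columns of W are the components' depth patterns ("molecular
fingerprints"), the rows of H each feature's contribution to a component
("pseudo-spectra").

The number of components is chosen by sweeping k upward while tracking the
relative Frobenius reconstruction error err(k) = ||X - WH||_F / ||X||_F
and stopping when the error stabilizes: by default when the decrement
err(k) - err(k+1) falls below ``delta_tol`` (default 0.0015); an absolute
reading (smallest k with err(k) < delta_tol) is selectable. The sweep
warm-starts k+1 from the fitted rank-k factors augmented with the
least-squares-scaled leading rank-1 part of the positive residual, which
makes the recorded error trace non-increasing in k and the whole sweep
deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .datatypes import FeatureTable, FingerprintModel, ZoneMatrix

__all__ = [
    "zone_average",
    "maxabs_scale",
    "select_n_components",
    "fit_nmf",
    "top_features",
    "ZoneAverager",
    "MolecularFingerprintNMF",
]


def zone_average(
    table: FeatureTable, zone_width: int = 30, depth_axis: str = "x"
) -> ZoneMatrix:
    """Mean abundance of every feature in every depth zone (zeros included).

    Zones are the half-open intervals ``[k*w, (k+1)*w)`` over the depth-axis
    coordinate, anchored at 0; a final partial zone is kept when it holds
    at least one pixel.
    """
    if zone_width < 1:
        raise ValueError("zone_width must be >= 1")
    depth = table.pixel_index[:, 0] if depth_axis == "x" else table.pixel_index[:, 1]
    zone_of = depth // zone_width
    zones = np.unique(zone_of)
    matrix = np.empty((zones.size, table.n_features))
    bounds = np.empty((zones.size, 2), dtype=int)
    for j, z in enumerate(zones):
        in_zone = zone_of == z
        matrix[j] = table.matrix[in_zone].mean(axis=0)
        bounds[j] = (z * zone_width, (z + 1) * zone_width)
    return ZoneMatrix(matrix, bounds, table.feature_mz)


def maxabs_scale(zm: ZoneMatrix) -> tuple[ZoneMatrix, np.ndarray, np.ndarray]:
    """Scale every feature column to [0, 1] by its maximum absolute value.

    Returns ``(scaled, scale_factors, zero_flags)``; all-zero columns are
    left unchanged and flagged (their scale factor is reported as 1).
    Matches MaxAbsScaler semantics for non-negative input.
    """
    col_max = zm.matrix.max(axis=0)
    zero = col_max == 0
    scale = np.where(zero, 1.0, col_max)
    scaled = ZoneMatrix(zm.matrix / scale, zm.zone_bounds, zm.feature_mz)
    return scaled, scale, zero


# ---------------------------------------------------------------------------
# NMF with a deterministic, monotone k-sweep


def _relative_error(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(X - W @ H) / np.linalg.norm(X))


def _solve(X, k, seed, tol, max_iter, W0=None, H0=None):
    """One sklearn coordinate-descent NMF solve; nndsvda or custom init."""
    kwargs = dict(
        n_components=k, solver="cd", tol=tol, max_iter=max_iter, random_state=seed
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        if W0 is None:
            model = NMF(init="nndsvda", **kwargs)
            W = model.fit_transform(X)
        else:
            model = NMF(init="custom", **kwargs)
            W = model.fit_transform(X, W=np.ascontiguousarray(W0), H=np.ascontiguousarray(H0))
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return W, model.components_, model.n_iter_, converged

def _augment(X, W, H):
    """Warm-start factors for k+1: append the least-squares-scaled leading
    rank-1 part of the positive residual, so the initial error at k+1 never
    exceeds the converged error at k."""
    R = X - W @ H
    Rpos = np.clip(R, 0.0, None)
    if Rpos.max() <= 0:
        w_new = np.full((X.shape[0], 1), 1e-10)
        h_new = np.full((1, X.shape[1]), 1e-10)
        return np.hstack([W, w_new]), np.vstack([H, h_new])
    U, s, Vt = np.linalg.svd(Rpos, full_matrices=False)
    # Leading singular vectors of a non-negative matrix can be taken
    # non-negative (Perron-Frobenius); abs() fixes the sign convention.
    u = np.abs(U[:, 0])
    v = np.abs(Vt[0])
    rank1 = np.outer(u, v)
    denom = float((rank1 * rank1).sum())
    alpha = max(float((R * rank1).sum()) / denom, 0.0) if denom > 0 else 0.0
    if alpha <= 0:
        u = np.full(X.shape[0], 1e-10)
        v = np.full(X.shape[1], 1e-10)
        alpha = 1.0
    w_new = (np.sqrt(alpha) * u)[:, None]
    h_new = (np.sqrt(alpha) * v)[None, :]
    return np.hstack([W, w_new]), np.vstack([H, h_new])


def _sweep(
    X: np.ndarray,
    k_max: int,
    delta_tol: float,
    seed: int,
    criterion: str,
    tol: float,
    max_iter: int,
):
    """Sweep k upward with warm starts; return (k, trace, factors, meta)."""
    if criterion not in ("decrement", "absolute"):
        raise ValueError("criterion must be 'decrement' or 'absolute'")
    k_cap = min(k_max, *X.shape)
    if k_cap < k_max:
        warnings.warn(f"k_max={k_max} capped at min(zones, features)={k_cap}")
    trace: dict[int, float] = {}
    factors: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    meta: dict[int, tuple[int, bool]] = {}
    W = H = None
    selected = None
    for k in range(1, k_cap + 1):
        if W is None:
            W, H, n_iter, conv = _solve(X, k, seed, tol, max_iter)
        else:
            W0, H0 = _augment(X, W, H)
            W, H, n_iter, conv = _solve(X, k, seed, tol, max_iter, W0, H0)
        trace[k] = _relative_error(X, W, H)
        factors[k] = (W, H)
        meta[k] = (n_iter, conv)
        if criterion == "absolute" and trace[k] < delta_tol:
            selected = k
            break
        if criterion == "decrement" and k >= 2 and trace[k - 1] - trace[k] < delta_tol:
            selected = k - 1
            break
    if selected is None:
        selected = k_cap
        warnings.warn(
            f"reconstruction error never stabilized below {delta_tol}; using k={k_cap}"
        )
    return selected, trace, factors, meta


def select_n_components(
    zm_scaled: ZoneMatrix | np.ndarray,
    k_max: int = 20,
    delta_tol: float = 0.0015,
    seed: int = 0,
    criterion: str = "decrement",
    tol: float = 1e-10,
    max_iter: int = 50000,
) -> tuple[int, dict[int, float]]:
    """Pick the component count at which the error trace stabilizes.

    Under the default ``decrement`` criterion this is the smallest k with
    ``err(k) - err(k+1) < delta_tol``; under ``absolute`` the smallest k
    with ``err(k) < delta_tol``. Capped at ``min(k_max, zones, features)``
    with a warning when never stabilized.
    """
    X = zm_scaled.matrix if isinstance(zm_scaled, ZoneMatrix) else np.asarray(zm_scaled)
    k, trace, _, _ = _sweep(X, k_max, delta_tol, seed, criterion, tol, max_iter)
    return k, trace


def fit_nmf(
    zm_scaled: ZoneMatrix, k: int, seed: int = 0, tol: float = 1e-10, max_iter: int = 50000
) -> FingerprintModel:
    """Factorize a scaled zone matrix at a fixed component count.

    Uses deterministic NNDSVD-based initialization (data's leading singular
    structure); the seed only perturbs exact ties inside the solver, so
    repeated runs with one seed are bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    W, H, n_iter, conv = _solve(zm_scaled.matrix, k, seed, tol, max_iter)
    if not conv:
        warnings.warn(f"NMF did not converge within {max_iter} iterations")
    err = _relative_error(zm_scaled.matrix, W, H)
    return FingerprintModel(
        n_components=k,
        spatial=W,
        contributions=H,
        error_trace={k: err},
        seed=seed,
        feature_mz=zm_scaled.feature_mz,
        n_iter=n_iter,
        converged=conv,
    )


def top_features(model: FingerprintModel, component: int, n: int) -> list[int]:
    """Feature indices ranked by contribution to one component, descending.

    Exact ties are broken toward the lower m/z. ``n`` larger than the
    feature count returns the full ranking.
    """
    if not 0 <= component < model.n_components:
        raise IndexError(f"component {component} out of range")
    contrib = model.contributions[component]
    order = np.lexsort((np.arange(contrib.size), -contrib))
    return [int(i) for i in order[: max(n, 0)]]


# ---------------------------------------------------------------------------
# Estimators


class ZoneAverager(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`zone_average`."""

    def __init__(self, zone_width: int = 30, depth_axis: str = "x"):
        self.zone_width = zone_width
        self.depth_axis = depth_axis

    def fit(self, table: FeatureTable, y=None):
        return self

    def transform(self, table: FeatureTable) -> ZoneMatrix:
        return zone_average(table, self.zone_width, self.depth_axis)


class MolecularFingerprintNMF(BaseEstimator, TransformerMixin):
    """NMF fingerprint extractor with built-in component-count selection.

    Parameters
    ----------
    n_components : int or None
        Fixed component count; ``None`` (default) selects it by the error
        stabilization sweep.
    k_max, delta_tol, criterion
        Sweep bounds and stabilization rule (see :func:`select_n_components`).
    solver_tol, max_iter
        Convergence tolerance (relative error change) and iteration cap of
        each coordinate-descent solve.
    random_state
        Seed recorded in the model; initialization is deterministic.

    Fitted attributes
    -----------------
    n_components_, spatial_ (zones x k), contributions_ (k x features),
    error_trace_ (k -> relative Frobenius error), reconstruction_err_,
    n_iter_, converged_, model_ (:class:`FingerprintModel`).
    """

    def __init__(
        self,
        n_components: int | None = None,
        k_max: int = 20,
        delta_tol: float = 0.0015,
        criterion: str = "decrement",
        solver_tol: float = 1e-10,
        max_iter: int = 50000,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.k_max = k_max
        self.delta_tol = delta_tol
        self.criterion = criterion
        self.solver_tol = solver_tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, zm_scaled: ZoneMatrix | np.ndarray, y=None):
        if isinstance(zm_scaled, ZoneMatrix):
            X, feature_mz = zm_scaled.matrix, zm_scaled.feature_mz
        else:
            X = np.asarray(zm_scaled, dtype=float)
            feature_mz = np.array([])
        if np.any(X < 0):
            raise ValueError("NMF input must be non-negative")
        if self.n_components is not None:
            k = int(self.n_components)
            W, H, n_iter, conv = _solve(
                X, k, self.random_state, self.solver_tol, self.max_iter
            )
            trace = {k: _relative_error(X, W, H)}
        else:
            k, trace, factors, meta = _sweep(
                X,
                self.k_max,
                self.delta_tol,
                self.random_state,
                self.criterion,
                self.solver_tol,
                self.max_iter,
            )
            W, H = factors[k]
            n_iter, conv = meta[k]
        self.n_components_ = k
        self.spatial_ = W
        self.contributions_ = H
        self.error_trace_ = trace
        self.reconstruction_err_ = trace[k]
        self.n_iter_ = n_iter
        self.converged_ = conv
        self.model_ = FingerprintModel(
            n_components=k,
            spatial=W,
            contributions=H,
            error_trace=trace,
            seed=self.random_state,
            feature_mz=feature_mz,
            n_iter=n_iter,
            converged=conv,
        )
        return self

    def transform(self, zm_scaled: ZoneMatrix | np.ndarray) -> np.ndarray:
        """Project a (scaled) zone matrix onto the fitted pseudo-spectra.

        Solves the non-negative least-squares problem row by row with the
        contribution matrix held fixed.
        """
        from scipy.optimize import nnls

        X = zm_scaled.matrix if isinstance(zm_scaled, ZoneMatrix) else np.asarray(zm_scaled)
        Ht = self.contributions_.T  # (features, k)
        return np.vstack([nnls(Ht, row)[0] for row in X])

    def fit_transform(self, zm_scaled, y=None):
        self.fit(zm_scaled)
        return self.spatial_
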