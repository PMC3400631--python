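"""Gaussian mixture fitting by EM with BIC-based component selection.

Univariate (unequal-variance) and bivariate (fully unconstrained covariance)
mixtures only — the two model families used for marginal and joint expression
profiles. BIC follows the maximize convention ``2·lnL − k·ln n`` (larger is
better), so the dependency score defined downstream is positive for dependent
pairs.

Free parameters for G components in dimension d:
``k = (G−1) + G·d + G·d(d+1)/2`` — i.e. 3G−1 univariate, 6G−1 bivariate.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from ._em import fit_once

__all__ = [
    "FitConfig",
    "MixtureModel",
    "DegenerateDataError",
    "bic_score",
    "n_free_params",
    "em_fit",
    "fit_best_mixture",
]


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested number of components."""


@dataclass(frozen=True)
class FitConfig:
    """EM fitting configuration.

    Attributes
    ----------
    g_min, g_max : component-count search range for :func:`fit_best_mixture`.
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap per run (non-convergence returns the best
        iterate with ``converged=False``, it is not an error).
    n_restarts : independent k-means++ initializations per component count;
        the best log-likelihood run is kept.
    cov_floor : covariance eigenvalue floor; ``None`` means
        ``1e-6 × mean per-dimension data variance`` (with an absolute fallback
        of 1e-6 for constant data).
    seed : base RNG seed; all randomness derives deterministically from it.
    """

    g_min: int = 1
    g_max: int = 9
    tol: float = 1e-6
    max_iter: int = 500
    n_restarts: int = 5
    cov_floor: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.g_min <= self.g_max):
            raise ValueError(f"require 1 <= g_min <= g_max, got {self.g_min}..{self.g_max}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.cov_floor is not None and self.cov_floor <= 0:
            raise ValueError("cov_floor must be > 0")
        if not (0 <= int(self.seed) < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")


@dataclass(frozen=True)
class MixtureModel:
    """A fitted Gaussian mixture with its BIC accounting.

    ``covariances`` has shape (G, d, d) even for d=1. ``data_hash`` is the
    SHA1 of the training array bytes and lets downstream consumers verify a
    model belongs to given profiles.
    """

    dimension: int
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    bic: float
    converged: bool
    cov_floor: float
    data_hash: str
    max_monotonicity_violation: float = 0.0

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        w = np.asarray(self.weights)
        if abs(float(w.sum()) - 1.0) > 1e-10 or np.any(w <= 0):
            raise ValueError("weights must be positive and sum to 1")
        if not np.isfinite(self.loglik):
            raise ValueError("loglik must be finite")
        expected_k = n_free_params(self.n_components, self.dimension)
        if self.n_params != expected_k:
            raise ValueError(f"n_params {self.n_params} != counting rule {expected_k}")
        if abs(self.bic - bic_score(self.loglik, self.n_params, self.n_obs)) > 1e-9:
            raise ValueError("bic inconsistent with loglik/k/n")

    def responsibilities(self, data: np.ndarray) -> np.ndarray:
        """Posterior component membership probabilities, one row per point."""
        from ._em import log_responsibilities

        X = _as_points(data)
        if X.shape[1] != self.dimension:
            raise ValueError("data dimension does not match model")
        return log_responsibilities(
            X,
            np.ascontiguousarray(self.weights, dtype=np.float64),
            np.ascontiguousarray(self.means, dtype=np.float64),
            np.ascontiguousarray(self.covariances, dtype=np.float64),
        )


def n_free_params(n_components: int, dimension: int) -> int:
    """Free-parameter count: (G−1) weights + G·d means + G·d(d+1)/2 covariances."""
    G, d = n_components, dimension
    return (G - 1) + G * d + G * (d * (d + 1) // 2)


def bic_score(loglik: float, k: int, n: int) -> float:
    """BIC in the maximize convention, ``2·loglik − k·ln n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not np.isfinite(loglik):
        raise ValueError("loglik must be finite")
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * float(loglik) - k * float(np.log(n))


def _as_points(data) -> np.ndarray:
    X = np.asarray(data, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] not in (1, 2):
        raise ValueError("data must be 1-D or an (n, d) array with d in {1, 2}")
    if X.shape[0] == 0:
        raise ValueError("data must be nonempty")
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    return np.ascontiguousarray(X)


def data_hash(data) -> str:
    """SHA1 digest of the (n, d) float64 representation of `data`."""
    return hashlib.sha1(_as_points(data).tobytes()).hexdigest()


def _resolve_floor(X: np.ndarray, config: FitConfig) -> float:
    if config.cov_floor is not None:
        return float(config.cov_floor)
    scale = float(np.mean(np.var(X, axis=0)))
    return 1e-6 * scale if scale > 0 else 1e-6


def _n_distinct(X: np.ndarray) -> int:
    return int(np.unique(X, axis=0).shape[0])


def em_fit(data, n_components: int, config: FitConfig | None = None) -> MixtureModel:
    """Fit a G-component mixture by EM, keeping the best of ``n_restarts`` runs.

    Raises :class:`DegenerateDataError` when the data has fewer distinct
    points than components. Non-convergence within ``max_iter`` is reported
    through ``converged=False`` on the returned model, not as an error.
    """
    config = config or FitConfig()
    X = _as_points(data)
    G = int(n_components)
    if G < 1:
        raise ValueError("n_components must be >= 1")
    if _n_distinct(X) < G:
        raise DegenerateDataError(
            f"{G} components requested but only {_n_distinct(X)} distinct points"
        )
    return _em_fit_checked(X, G, config, _resolve_floor(X, config))


def _em_fit_checked(X: np.ndarray, G: int, config: FitConfig, floor: float) -> MixtureModel:
    n, d = X.shape
    n_restarts = 1 if G == 1 else config.n_restarts
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(config.seed), spawn_key=(G, r))
        )
        u = rng.random(G)
        out = fit_once(X, G, u, config.tol, config.max_iter, floor)
        if best is None or out[3] > best[3]:
            best = out
    weights, means, covs, ll, _n_iter, converged, max_dec = best
    k = n_free_params(G, d)
    return MixtureModel(
        dimension=d,
        n_components=G,
        weights=np.asarray(weights),
        means=np.asarray(means),
        covariances=np.asarray(covs),
        loglik=float(ll),
        n_params=k,
        n_obs=n,
        bic=bic_score(float(ll), k, n),
        converged=bool(converged),
        cov_floor=floor,
        data_hash=hashlib.sha1(X.tobytes()).hexdigest(),
        max_monotonicity_violation=float(max_dec),
    )


def fit_best_mixture(data, config: FitConfig | None = None) -> MixtureModel:
    """Fit each G in ``g_min..g_max`` and return the model with maximal BIC.

    Component counts exceeding the number of distinct data points are
    skipped; BIC ties break toward the smaller G (parsimony).
    """
    config = config or FitConfig()
    X = _as_points(data)
    floor = _resolve_floor(X, config)
    n_distinct = _n_distinct(X)
    g_hi = min(config.g_max, n_distinct)
    if g_hi < config.g_min:
        raise DegenerateDataError(
            f"g_min={config.g_min} exceeds the {n_distinct} distinct data points"
        )
    best = None
    for G in range(config.g_min, g_hi + 1):
        model = _em_fit_checked(X, G, config, floor)
        if best is None or model.bic > best.bic:
            best = model
    return best
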