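"""Pairwise gene dependency measures.

The model-based score is the difference in BIC between a joint bivariate
Gaussian-mixture fit of two expression profiles and the product of their two
univariate marginal mixture fits:

    D(x, y) = BIC(M_xy) − BIC(M_x) − BIC(M_y)

with BIC in the maximize convention, so D > 0 means the joint model beats
independence after the dimension penalty. With the component search forced to
G = 1 the score collapses to the closed form −n·ln(1 − r̂²) − ln n, i.e. a
penalized likelihood-ratio test of zero correlation — the mixture extends
this to condition-dependent (locally linear) relationships.

Baselines: Euclidean distance, Pearson correlation, Kendall's tau-b, and
mutual information of the two profiles discretized into equal-width bins
(default 10, natural log).
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.metrics import mutual_info_score

from .expression import ExpressionMatrix
from .gmm import FitConfig, MixtureModel, fit_best_mixture

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "HIGHER_IS_DEPENDENT",
    "DependencyScores",
    "PairDependency",
    "UndefinedCorrelationError",
    "euclidean",
    "pearson",
    "kendall_tau",
    "mutual_information",
    "mi_from_contingency",
    "dbomm",
    "loglik_ratio",
    "pair_dependency",
    "score_all_pairs",
]

METHODS = ("dbomm", "llr", "euc", "cor", "tau", "mi")

# Orientation of each measure: True when larger values indicate dependence.
# Kendall's tau follows the smaller-is-dependent direction used when testing
# real against background interactions; the |tau| / |r| ranking transforms
# are available through `transform="abs"`.
HIGHER_IS_DEPENDENT = {
    "dbomm": True,
    "llr": True,
    "mi": True,
    "cor": True,
    "euc": False,
    "tau": False,
}


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant / all-tied profile)."""


def _check_pair(x, y, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"profile lengths differ: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < min_n:
        raise ValueError(f"profiles must have length >= {min_n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("profiles must be finite")
    return x, y


def euclidean(x, y) -> float:
    """Euclidean distance between two expression profiles."""
    x, y = _check_pair(x, y, min_n=1)
    return float(np.linalg.norm(x - y))


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two profiles."""
    x, y = _check_pair(x, y, min_n=2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("Pearson correlation undefined for a constant profile")
    return float(stats.pearsonr(x, y).statistic)


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected); equals tau-a when there are no ties."""
    x, y = _check_pair(x, y, min_n=2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("Kendall's tau undefined for an all-tied profile")
    return float(stats.kendalltau(x, y).statistic)


def _bin_edges(v: np.ndarray, bins: int, strategy: str) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        # constant profile: one occupied bin
        return np.array([lo - 0.5, hi + 0.5])
    if strategy == "width":
        return np.linspace(lo, hi, bins + 1)
    if strategy == "frequency":
        edges = np.quantile(v, np.linspace(0.0, 1.0, bins + 1))
        return np.unique(edges)
    raise ValueError(f"unknown binning strategy {strategy!r}")


def mi_from_contingency(table) -> float:
    """Mutual information (nats) of a joint count table, with 0·log 0 := 0."""
    table = np.asarray(table, dtype=np.float64)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    return float(mutual_info_score(None, None, contingency=table))


def mutual_information(x, y, bins: int = 10, strategy: str = "width") -> float:
    """Binned mutual information of two profiles, in nats.

    Each profile is discretized independently into `bins` equal-width
    intervals over its own observed range (`strategy="frequency"` switches to
    equal-count quantile bins). The joint count table then yields
    ``sum p_ij · ln(p_ij / (p_i · p_j))``.
    """
    x, y = _check_pair(x, y, min_n=1)
    if bins < 1:
        raise ValueError("bins must be >= 1")
    ex = _bin_edges(x, bins, strategy)
    ey = _bin_edges(y, bins, strategy)
    counts, _, _ = np.histogram2d(x, y, bins=[ex, ey])
    return mi_from_contingency(counts)


# ---------------------------------------------------------------------------
# model-based scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairDependency:
    """Joint and marginal mixture fits for one gene pair, with both scores."""

    dbomm: float
    llr: float
    joint: MixtureModel
    marginal_x: MixtureModel
    marginal_y: MixtureModel


def pair_dependency(x, y, config: FitConfig | None = None) -> PairDependency:
    """Fit M_xy, M_x, M_y under one config and return both dependency scores.

    The joint fit canonicalizes the column order of (x, y) by byte
    comparison; the joint BIC is invariant to coordinate order, so this only
    guarantees bit-exact symmetry of the score.
    """
    config = config or FitConfig()
    x, y = _check_pair(x, y, min_n=2)
    if x.shape[0] < 10:
        logger.warning("scoring a pair with only n=%d conditions (< 10)", x.shape[0])
    swapped = x.tobytes() > y.tobytes()
    a, b = (y, x) if swapped else (x, y)
    joint = fit_best_mixture(np.column_stack([a, b]), config)
    ma = fit_best_mixture(a, config)
    mb = fit_best_mixture(b, config)
    # scores evaluated in canonical operand order for bit-exact symmetry
    score_d = joint.bic - ma.bic - mb.bic
    score_l = joint.loglik - ma.loglik - mb.loglik
    mx, my = (mb, ma) if swapped else (ma, mb)
    return PairDependency(
        dbomm=score_d,
        llr=score_l,
        joint=joint,
        marginal_x=mx,
        marginal_y=my,
    )


def dbomm(x, y, config: FitConfig | None = None) -> float:
    """Difference in BIC between the joint and the two marginal mixture fits."""
    return pair_dependency(x, y, config).dbomm


def loglik_ratio(x, y, config: FitConfig | None = None) -> float:
    """Log-likelihood-ratio variant: loglik(M_xy) − loglik(M_x) − loglik(M_y)."""
    return pair_dependency(x, y, config).llr


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

@dataclass
class DependencyScores:
    """Scores of one measure over a list of gene pairs.

    `higher_is_dependent` records the orientation used by the evaluation
    layer. For model-based methods the selected component counts of the
    joint and both marginal fits are carried along; otherwise they are None.
    """

    pairs: list[tuple[str, str]]
    scores: np.ndarray
    method: str
    higher_is_dependent: bool
    joint_components: np.ndarray | None = None
    x_components: np.ndarray | None = None
    y_components: np.ndarray | None = None
    meta: dict = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.pairs) != self.scores.shape[0]:
            raise ValueError("pairs and scores must align")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        keys = {tuple(sorted(p)) for p in self.pairs}
        if len(keys) != len(self.pairs):
            raise ValueError("pairs must be unique (unordered)")
        if self.meta is None:
            self.meta = {}


def _pair_seed(base_seed: int, gene_a: str, gene_b: str) -> int:
    """Order-independent per-pair seed, below 2^31."""
    a, b = sorted((gene_a, gene_b))
    return (zlib.crc32(f"{a}\t{b}".encode()) ^ int(base_seed)) & 0x7FFFFFFF


def score_all_pairs(
    expr: ExpressionMatrix,
    pairs,
    method: str,
    config: FitConfig | None = None,
    bins: int = 10,
    transform: str = "raw",
) -> DependencyScores:
    """Score every gene pair with one measure.

    `transform` applies an optional monotone re-expression of correlation
    measures: "abs" ranks by |value| (cor/tau), "distance" uses 1 − value.
    Model-based methods derive a per-pair seed from the sorted gene names so
    the result is independent of evaluation order.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if transform not in ("raw", "abs", "distance"):
        raise ValueError(f"unknown transform {transform!r}")
    if transform != "raw" and method not in ("cor", "tau"):
        raise ValueError("transforms apply only to cor and tau")
    config = config or FitConfig()
    pairs = [(str(a), str(b)) for a, b in pairs]
    for a, b in pairs:
        for g in (a, b):
            if g not in expr:
                raise KeyError(f"unknown gene id: {g!r}")

    scores = np.empty(len(pairs))
    g_joint = np.zeros(len(pairs), dtype=int) if method in ("dbomm", "llr") else None
    g_x = np.zeros(len(pairs), dtype=int) if method in ("dbomm", "llr") else None
    g_y = np.zeros(len(pairs), dtype=int) if method in ("dbomm", "llr") else None
    for i, (a, b) in enumerate(pairs):
        x, y = expr.row(a), expr.row(b)
        if method in ("dbomm", "llr"):
            cfg = replace(config, seed=_pair_seed(config.seed, a, b))
            dep = pair_dependency(x, y, cfg)
            scores[i] = dep.dbomm if method == "dbomm" else dep.llr
            g_joint[i] = dep.joint.n_components
            g_x[i] = dep.marginal_x.n_components
            g_y[i] = dep.marginal_y.n_components
        elif method == "euc":
            scores[i] = euclidean(x, y)
        elif method == "cor":
            scores[i] = pearson(x, y)
        elif method == "tau":
            scores[i] = kendall_tau(x, y)
        elif method == "mi":
            scores[i] = mutual_information(x, y, bins=bins)
        if (i + 1) % 500 == 0:
            logger.info("scored %d / %d pairs (%s)", i + 1, len(pairs), method)

    higher = HIGHER_IS_DEPENDENT[method]
    if transform == "abs":
        scores = np.abs(scores)
        higher = True
    elif transform == "distance":
        scores = 1.0 - scores
        higher = False
    return DependencyScores(
        pairs=pairs,
        scores=scores,
        method=method,
        higher_is_dependent=higher,
        joint_components=g_joint,
        x_components=g_x,
        y_components=g_y,
        meta={"bins": bins if method == "mi" else None, "seed": config.seed,
              "transform": transform, "log_base": "e"},
    )
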