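"""Network-level evaluation of dependency scores.

Builds inferred TF→target networks by thresholding, traces precision–recall
curves against a curated reference network, and runs the one-sided Welch
two-sample t-test of real-interaction scores against background
(all TF×gene pairs that are not curated edges).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .measures import DependencyScores

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceNetwork",
    "PRCurve",
    "background_pairs",
    "real_vs_background_test",
    "pr_curve",
    "infer_network",
    "aupr",
]


@dataclass
class ReferenceNetwork:
    """Curated directed TF→target edges plus the TF list and gene universe."""

    edges: set
    tfs: set
    genes: set

    def __post_init__(self) -> None:
        self.edges = {(str(a), str(b)) for a, b in self.edges}
        self.tfs = {str(t) for t in self.tfs}
        self.genes = {str(g) for g in self.genes}
        for tf, tg in self.edges:
            if tf == tg:
                raise ValueError(f"self-loop {tf}->{tg} not allowed")
            if tf not in self.tfs:
                raise ValueError(f"edge source {tf!r} is not a listed TF")
            if tf not in self.genes or tg not in self.genes:
                raise ValueError(f"edge {tf}->{tg} has an endpoint outside the gene universe")

    def undirected_edges(self) -> set:
        """Edges as unordered pairs (dependency measures are symmetric)."""
        return {tuple(sorted(e)) for e in self.edges}


@dataclass
class PRCurve:
    """Precision–recall curve over descending-dependency score thresholds."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        for name in ("thresholds", "precision", "recall"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        for name in ("tp", "fp", "fn"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        denom_p = self.tp + self.fp
        denom_r = self.tp + self.fn
        ok_p = np.where(denom_p > 0, self.tp / np.maximum(denom_p, 1), 1.0)
        if not np.allclose(self.precision, ok_p, rtol=0, atol=1e-12):
            raise ValueError("precision rows inconsistent with TP/FP counters")
        if np.any(denom_r == 0):
            raise ValueError("no real interactions in the evaluation universe")
        if not np.allclose(self.recall, self.tp / denom_r, rtol=0, atol=1e-12):
            raise ValueError("recall rows inconsistent with TP/FN counters")
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing as the threshold loosens")


def background_pairs(ref: ReferenceNetwork) -> set:
    """All TF×gene pairs (no self-pairs) that are not curated edges."""
    if not ref.tfs:
        raise ValueError("reference network has no TFs")
    return {
        (tf, g) for tf in ref.tfs for g in ref.genes if g != tf
    } - ref.edges


def real_vs_background_test(
    real_scores, bg_scores, higher_is_dependent: bool
) -> tuple[float, float]:
    """One-sided Welch two-sample t-test of real vs background scores.

    The alternative is "real mean bigger" for higher-is-dependent measures
    and "real mean smaller" otherwise. Returns (t statistic, p value).
    """
    real = np.asarray(real_scores, dtype=np.float64)
    bg = np.asarray(bg_scores, dtype=np.float64)
    if real.size < 2 or bg.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.var(real) == 0 or np.var(bg) == 0:
        raise ValueError("degenerate (zero-variance) sample")
    alternative = "greater" if higher_is_dependent else "less"
    res = stats.ttest_ind(real, bg, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _real_labels(scores: DependencyScores, ref: ReferenceNetwork):
    """Constrain scored pairs to the reference gene universe and label them."""
    kept_idx = [
        i for i, (a, b) in enumerate(scores.pairs)
        if a in ref.genes and b in ref.genes
    ]
    if not kept_idx:
        raise ValueError("no scored pair overlaps the reference gene universe")
    constrained_genes = {g for i in kept_idx for g in scores.pairs[i]}
    positives = {
        e for e in ref.undirected_edges()
        if e[0] in constrained_genes and e[1] in constrained_genes
    }
    labels = np.array(
        [tuple(sorted(scores.pairs[i])) in positives for i in kept_idx], dtype=bool
    )
    vals = scores.scores[kept_idx]
    return vals, labels, len(positives)


def pr_curve(scores: DependencyScores, ref: ReferenceNetwork) -> PRCurve:
    """Precision–recall curve of one score vector against the reference.

    Pairs are ranked by dependency (per the measure's orientation); one
    curve point is emitted per distinct score value. A scored pair counts as
    a true positive when it matches a curated edge in either direction; FN is
    counted against all curated edges among the evaluated gene set.
    """
    vals, labels, n_pos = _real_labels(scores, ref)
    if n_pos == 0:
        raise ValueError("no real interactions among the evaluated genes")
    order = np.argsort(-vals if scores.higher_is_dependent else vals, kind="stable")
    vals, labels = vals[order], labels[order]
    tp_cum = np.cumsum(labels)
    n_pred = np.arange(1, vals.size + 1)
    # one point per distinct score value: the last index of each run
    last = np.r_[np.nonzero(np.diff(vals))[0], vals.size - 1]
    tp = tp_cum[last]
    fp = n_pred[last] - tp
    fn = n_pos - tp
    precision = tp / (tp + fp)
    recall = tp / n_pos
    return PRCurve(
        thresholds=vals[last], tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall,
    )


def aupr(curve: PRCurve) -> float:
    """Trapezoidal area under the PR curve over recall.

    The curve is anchored at recall 0 with the precision of its most
    stringent threshold, so a single-point curve at full recall integrates
    to its own precision.
    """
    if curve.recall.size == 0:
        raise ValueError("empty curve")
    recall = np.r_[0.0, curve.recall]
    precision = np.r_[curve.precision[0], curve.precision]
    return float(np.trapezoid(precision, recall))


def infer_network(
    scores: DependencyScores,
    ref_tfs,
    threshold: float = 0.0,
) -> list[tuple[str, str]]:
    """Threshold scores and orient kept pairs TF→gene.

    Pairs strictly beyond `threshold` (above for higher-is-dependent
    measures, below otherwise) are kept. TF–TF pairs are emitted in both
    directions; pairs with no TF endpoint are dropped (count logged). The
    default threshold 0 is the natural cutoff for the BIC-difference score.
    """
    tfs = {str(t) for t in ref_tfs}
    if not tfs:
        raise ValueError("ref_tfs must be nonempty")
    if scores.higher_is_dependent:
        keep = scores.scores > threshold
    else:
        keep = scores.scores < threshold
    edges: list[tuple[str, str]] = []
    dropped = 0
    for (a, b), k in zip(scores.pairs, keep):
        if not k:
            continue
        a_tf, b_tf = a in tfs, b in tfs
        if a_tf and b_tf:
            edges.append((a, b))
            edges.append((b, a))
        elif a_tf:
            edges.append((a, b))
        elif b_tf:
            edges.append((b, a))
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d pairs with no TF endpoint", dropped)
    return edges
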