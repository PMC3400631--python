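"""Condition clustering: assign experimental conditions to the components of
a fitted joint mixture and summarize per-cluster expression.

A dependent gene pair whose joint profile needs several mixture components
is, in effect, regulated differently in different groups of experiments; the
component memberships recover those groups and the per-cluster mean
expression levels describe the regime (e.g. "both genes low" vs "both
high").
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmm import MixtureModel, data_hash

__all__ = ["ConditionClustering", "assign_conditions", "cluster_report", "plot_clusters"]


@dataclass
class ConditionClustering:
    """Hard labels (1..G) and soft posteriors of conditions for one gene pair."""

    pair: tuple[str, str]
    condition_ids: list[str]
    labels: np.ndarray          # per-condition component index, 1-based
    posteriors: np.ndarray      # n × G responsibilities
    cluster_means: np.ndarray   # G × 2 means of hard-assigned members (NaN if empty)
    model_means: np.ndarray     # G × 2 component means of the model
    cluster_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.posteriors = np.asarray(self.posteriors, dtype=np.float64)
        n, G = self.posteriors.shape
        if np.max(np.abs(self.posteriors.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("posterior rows must sum to 1")
        if not np.array_equal(self.labels, np.argmax(self.posteriors, axis=1) + 1):
            raise ValueError("labels must be the argmax of the posteriors")
        if int(self.cluster_sizes.sum()) != n:
            raise ValueError("cluster sizes must sum to n")


def assign_conditions(
    model: MixtureModel, x, y, condition_ids, pair: tuple[str, str] = ("x", "y")
) -> ConditionClustering:
    """Compute responsibilities of each condition under a fitted joint model.

    The model must have been fitted on exactly these paired profiles
    (verified through the sample size and a content hash). Hard labels take
    the maximum responsibility; np.argmax resolves ties toward the lower
    component index.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if model.dimension != 2:
        raise ValueError("a bivariate (joint) model is required")
    data = np.column_stack([x, y])
    if model.n_obs != data.shape[0] or len(condition_ids) != data.shape[0]:
        raise ValueError("model / profile / condition-id sample sizes disagree")
    if data_hash(data) != model.data_hash:
        raise ValueError("model was not fitted on these profiles (content hash mismatch)")

    post = model.responsibilities(data)
    # exact renormalization guards accumulated round-off
    post = post / post.sum(axis=1, keepdims=True)
    labels = np.argmax(post, axis=1) + 1
    G = model.n_components
    sizes = np.bincount(labels - 1, minlength=G)
    means = np.full((G, 2), np.nan)
    for g in range(G):
        members = labels == g + 1
        if members.any():
            means[g] = data[members].mean(axis=0)
    return ConditionClustering(
        pair=pair,
        condition_ids=[str(c) for c in condition_ids],
        labels=labels,
        posteriors=post,
        cluster_means=means,
        model_means=np.asarray(model.means),
        cluster_sizes=sizes,
    )


def cluster_report(clustering: ConditionClustering) -> pd.DataFrame:
    """One row per cluster: index, size, mean x/y of hard members, member ids.

    Empty clusters (components capturing no argmax point) are emitted with
    size 0 and NaN means, flagged in the `empty` column.
    """
    rows = []
    ids = np.asarray(clustering.condition_ids, dtype=object)
    G = clustering.posteriors.shape[1]
    for g in range(G):
        members = ids[clustering.labels == g + 1]
        rows.append(
            {
                "cluster": g + 1,
                "size": int(clustering.cluster_sizes[g]),
                "mean_x": clustering.cluster_means[g, 0],
                "mean_y": clustering.cluster_means[g, 1],
                "model_mean_x": clustering.model_means[g, 0],
                "model_mean_y": clustering.model_means[g, 1],
                "empty": clustering.cluster_sizes[g] == 0,
                "members": ",".join(members),
            }
        )
    return pd.DataFrame(rows)


def plot_clusters(clustering: ConditionClustering, x, y, path) -> None:
    """Scatter the two profiles colored by hard cluster assignment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(x, y, c=clustering.labels, cmap="tab10", s=20)
    ax.set_xlabel(clustering.pair[0])
    ax.set_ylabel(clustering.pair[1])
    ax.set_title("conditions by mixture component")
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
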