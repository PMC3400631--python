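"""Reading and writing the tab-delimited file formats.

Expression matrices are genes-as-rows TSVs with a header row of condition
ids and gene ids in the first column. Reference networks are 2-column
TF→target edge lists. All outputs carry '#'-prefixed metadata header lines
(version, seed, config) so a run can be regenerated bit-identically; readers
skip comment lines.
"""
from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .measures import DependencyScores
from .network import PRCurve, ReferenceNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_reference_network",
    "write_scores",
    "read_scores",
    "write_pr_curve",
    "write_edge_list",
    "write_sif",
    "metadata_header",
]


def metadata_header(seed: int | None = None, **config) -> str:
    """'#'-prefixed metadata block: version, seed, and a config hash."""
    from . import __version__

    lines = [f"# dbomm_version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config:
        blob = json.dumps(config, sort_keys=True, default=str)
        lines.append(f"# config: {blob}")
        lines.append(f"# config_sha1: {hashlib.sha1(blob.encode()).hexdigest()}")
    return "\n".join(lines) + "\n"


def read_expression_matrix(path, impute: str = "none") -> ExpressionMatrix:
    """Load a genes × conditions TSV.

    impute="none" raises on any missing cell; impute="row_mean" replaces
    missing cells by their row mean (an all-missing row is still an error).
    Duplicate gene ids and non-numeric cells are errors naming the culprit.
    """
    if impute not in ("none", "row_mean"):
        raise ValueError("impute must be 'none' or 'row_mean'")
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    # a present cell that failed conversion and is not a missing-value marker
    missing_markers = {"", "na", "nan", "null", "none"}
    is_marker = frame.apply(
        lambda col: col.fillna("").str.strip().str.lower().isin(missing_markers)
    )
    nonnum = numeric.isna() & frame.notna() & ~is_marker
    if nonnum.to_numpy().any():
        r, c = np.argwhere(nonnum.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {frame.iloc[r, c]!r} at gene {frame.index[r]!r}, "
            f"condition {frame.columns[c]!r}"
        )
    values = numeric.to_numpy(dtype=np.float64)
    missing = ~np.isfinite(values)
    if missing.any():
        if impute == "none":
            r, c = np.argwhere(missing)[0]
            raise ValueError(
                f"missing value at gene {frame.index[r]!r}, condition "
                f"{frame.columns[c]!r} (use impute='row_mean' to fill)"
            )
        row_all_missing = missing.all(axis=1)
        if row_all_missing.any():
            raise ValueError(
                f"gene {frame.index[int(np.argmax(row_all_missing))]!r} has no observed values"
            )
        row_means = np.nanmean(np.where(missing, np.nan, values), axis=1)
        values = np.where(missing, row_means[:, None], values)
        logger.info("imputed %d missing cells by row mean", int(missing.sum()))
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in frame.index],
        condition_ids=[str(c) for c in frame.columns],
    )


def write_expression_matrix(expr: ExpressionMatrix, path, seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(metadata_header(seed=seed))
        expr.to_frame().to_csv(fh, sep="\t", index_label="gene")


def read_reference_network(path, expr: ExpressionMatrix) -> ReferenceNetwork:
    """Load a 2-column TF→target TSV, filtered to genes present in `expr`.

    Self-loops and duplicate lines are dropped (counts logged); an empty
    result after filtering is an error.
    """
    edges_raw: list[tuple[str, str]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            edges_raw.append((parts[0].strip(), parts[1].strip()))
    n_raw = len(edges_raw)
    dedup = set(edges_raw)
    n_self = sum(1 for a, b in dedup if a == b)
    n_unknown = sum(1 for a, b in dedup if a != b and (a not in expr or b not in expr))
    edges = {(a, b) for a, b in dedup if a != b and a in expr and b in expr}
    logger.info(
        "reference network: %d lines, %d unique, dropped %d self-loops and %d "
        "edges with genes absent from the expression matrix, kept %d",
        n_raw, len(dedup), n_self, n_unknown, len(edges),
    )
    if not edges:
        raise ValueError(f"no usable edges in {path} after filtering")
    tfs = {a for a, _ in edges}
    genes = {g for e in edges for g in e}
    return ReferenceNetwork(edges=edges, tfs=tfs, genes=genes)


_SCORE_COLS = [
    "gene_a", "gene_b", "method", "score",
    "n_components_joint", "n_components_x", "n_components_y",
]


def write_scores(scores: DependencyScores, path, seed: int | None = None) -> None:
    """Scores as TSV; mixture-component columns are empty for non-model methods."""
    rows = []
    for i, (a, b) in enumerate(scores.pairs):
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "method": scores.method,
                "score": repr(float(scores.scores[i])),
                "n_components_joint": "" if scores.joint_components is None
                else int(scores.joint_components[i]),
                "n_components_x": "" if scores.x_components is None
                else int(scores.x_components[i]),
                "n_components_y": "" if scores.y_components is None
                else int(scores.y_components[i]),
            }
        )
    with open(path, "w") as fh:
        fh.write(metadata_header(seed=seed, method=scores.method,
                                 higher_is_dependent=scores.higher_is_dependent,
                                 **{k: v for k, v in scores.meta.items()
                                    if v is not None and k != "seed"}))
        pd.DataFrame(rows, columns=_SCORE_COLS).to_csv(fh, sep="\t", index=False)


def read_scores(path) -> DependencyScores:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_a": str, "gene_b": str},
                        float_precision="round_trip")
    if frame.empty:
        raise ValueError(f"no scores in {path}")
    methods = frame["method"].unique()
    if len(methods) != 1:
        raise ValueError(f"mixed methods in {path}: {methods}")
    method = str(methods[0])
    higher = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# config:"):
                cfg = json.loads(line.split(":", 1)[1])
                higher = bool(cfg.get("higher_is_dependent"))
            if not line.startswith("#"):
                break
    from .measures import HIGHER_IS_DEPENDENT

    if higher is None:
        higher = HIGHER_IS_DEPENDENT[method]
    has_g = frame["n_components_joint"].notna().all()
    return DependencyScores(
        pairs=list(zip(frame["gene_a"], frame["gene_b"])),
        scores=frame["score"].to_numpy(dtype=np.float64),
        method=method,
        higher_is_dependent=higher,
        joint_components=frame["n_components_joint"].to_numpy(dtype=np.float64).astype(int)
        if has_g else None,
        x_components=frame["n_components_x"].to_numpy(dtype=np.float64).astype(int)
        if has_g else None,
        y_components=frame["n_components_y"].to_numpy(dtype=np.float64).astype(int)
        if has_g else None,
    )


def write_pr_curve(curve: PRCurve, path, seed: int | None = None, **meta) -> None:
    frame = pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "tp": curve.tp,
            "fp": curve.fp,
            "fn": curve.fn,
            "precision": curve.precision,
            "recall": curve.recall,
        }
    )
    with open(path, "w") as fh:
        fh.write(metadata_header(seed=seed, **meta))
        frame.to_csv(fh, sep="\t", index=False)


def write_edge_list(edges, path, seed: int | None = None, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_header(seed=seed, **meta))
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_sif(edges, path, relation: str = "regulates") -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{relation}\t{b}\n")
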