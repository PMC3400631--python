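"""Synthetic regulatory networks and expression compendia with tunable noise.

The generator emulates the structure of simulated microarray benchmarks: a
known directed TF→target network, nonlinear (Hill-type) regulation with
activator/repressor edges, and two noise sources — "biological" noise that
perturbs the regulated signal multiplicatively and "experimental" noise that
adds Gaussian measurement error — both scaled by a single noise level in
[0, 1]. Expression values live on a log-intensity-like scale (baseline ~6–9,
regulatory span ~2–4 units).

Also provides simple dependent / independent pair generators whose
dependence is *conditional*: the mixture component means lie on a regular
polygon, so the between-component covariance is zero and the pair is only
correlated within components. A global correlation measure sees almost
nothing while a mixture-based score sees everything.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix

__all__ = ["SyntheticDataset", "simulate_network", "simulate_expression", "make_pair"]


@dataclass
class SyntheticDataset:
    """A simulated compendium with its gold-standard network."""

    expr: ExpressionMatrix
    gold_edges: set
    tfs: set
    noise_level: float
    seed: int
    params: dict

    def params_json(self) -> str:
        return json.dumps(self.params, indent=2, sort_keys=True)


def _gene_names(n_genes: int) -> list[str]:
    width = max(3, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def simulate_network(
    n_genes: int, n_tfs: int, n_edges: int, seed: int
) -> tuple[set, set]:
    """Sample a directed TF→gene network with preferential attachment.

    TFs are the first `n_tfs` genes. Each edge picks a TF with probability
    proportional to (current out-degree + 1) — giving hub-heavy topologies —
    and a uniform target distinct from the TF. No duplicates or self-loops.
    """
    if n_tfs < 1 or n_tfs >= n_genes:
        raise ValueError("require 1 <= n_tfs < n_genes")
    max_edges = n_tfs * (n_genes - 1)
    if n_edges < 0 or n_edges > max_edges:
        raise ValueError(f"n_edges must be in 0..{max_edges}")
    genes = _gene_names(n_genes)
    tfs = genes[:n_tfs]
    rng = np.random.default_rng(seed)
    edges: set = set()
    out_deg = np.zeros(n_tfs)
    # guard against stalling near saturation: fall back to enumeration
    attempts = 0
    while len(edges) < n_edges:
        attempts += 1
        if attempts > 50 * n_edges + 1000:
            remaining = [
                (tf, g) for tf in tfs for g in genes if g != tf and (tf, g) not in edges
            ]
            idx = rng.choice(len(remaining), size=n_edges - len(edges), replace=False)
            for i in idx:
                edges.add(remaining[i])
            break
        p = (out_deg + 1.0) / (out_deg + 1.0).sum()
        ti = rng.choice(n_tfs, p=p)
        gi = rng.integers(n_genes)
        edge = (tfs[ti], genes[gi])
        if genes[gi] == tfs[ti] or edge in edges:
            continue
        edges.add(edge)
        out_deg[ti] += 1
    return edges, set(tfs)


def _hill(u: np.ndarray, K: float, h: float) -> np.ndarray:
    uh = u**h
    return uh / (uh + K**h)


def simulate_expression(
    edges, tfs, n_conditions: int, noise_level: float, seed: int,
    n_genes: int | None = None,
) -> SyntheticDataset:
    """Simulate an expression compendium for a known network.

    Every gene carries an intrinsic per-condition activity u ~ U(0,1). A
    regulated gene's signal is the mean of its edges' Hill responses to the
    regulator activities (activation w.p. 0.7, else repression); a regulated
    TF mixes that input equally with its own intrinsic activity, so TF–TF
    cycles are well-defined. Expression = base + span·signal, with
    base ~ U(6,9) and span ~ U(2,4) per gene. At noise_level 0 the map from
    intrinsic activities to target expression is deterministic.

    Noise: the regulated signal is multiplied by exp(N(0, noise_level)) and
    Gaussian measurement error with sd = noise_level × per-gene signal sd is
    added on top.
    """
    if not (0.0 <= noise_level <= 1.0):
        raise ValueError("noise_level must be in [0, 1]")
    edges = {(str(a), str(b)) for a, b in edges}
    tfs = {str(t) for t in tfs}
    nodes = sorted(tfs | {g for e in edges for g in e})
    if n_genes is None:
        genes = nodes
    else:
        genes = _gene_names(n_genes)
        missing = set(nodes) - set(genes)
        if missing:
            raise ValueError(f"edge endpoints outside the gene set: {sorted(missing)[:5]}")
    for tf, tg in edges:
        if tf == tg:
            raise ValueError("self-loops are not allowed")
        if tf not in tfs:
            raise ValueError(f"edge source {tf!r} is not a TF")
    n = int(n_conditions)
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(genes)}
    n_g = len(genes)

    # per-gene and per-edge kinetic parameters (seeded, part of the topology draw)
    base = rng.uniform(6.0, 9.0, size=n_g)
    span = rng.uniform(2.0, 4.0, size=n_g)
    edge_list = sorted(edges)
    K = rng.uniform(0.3, 0.7, size=len(edge_list))
    h = rng.uniform(2.0, 4.0, size=len(edge_list))
    sign = rng.random(len(edge_list)) < 0.7  # True = activation

    regulators: dict[str, list[int]] = {g: [] for g in genes}
    for e_i, (tf, tg) in enumerate(edge_list):
        regulators[tg].append(e_i)

    u = rng.uniform(0.0, 1.0, size=(n_g, n))  # intrinsic activities
    signal = np.empty((n_g, n))
    for g in genes:
        gi = idx[g]
        regs = regulators[g]
        if not regs:
            signal[gi] = u[gi]
            continue
        terms = np.empty((len(regs), n))
        for k_i, e_i in enumerate(regs):
            src = idx[edge_list[e_i][0]]
            resp = _hill(u[src], K[e_i], h[e_i])
            terms[k_i] = resp if sign[e_i] else 1.0 - resp
        reg_input = terms.mean(axis=0)
        if g in tfs:
            signal[gi] = 0.5 * u[gi] + 0.5 * reg_input
        else:
            signal[gi] = reg_input

    clean = base[:, None] + span[:, None] * signal
    if noise_level > 0:
        bio = np.exp(rng.normal(0.0, noise_level, size=(n_g, n)))
        values = base[:, None] + span[:, None] * signal * bio
        sd_sig = clean.std(axis=1, keepdims=True)
        sd_sig[sd_sig == 0] = 1.0
        values = values + rng.normal(0.0, noise_level * sd_sig, size=(n_g, n))
    else:
        values = clean

    expr = ExpressionMatrix(
        values=values,
        gene_ids=genes,
        condition_ids=[f"C{j:03d}" for j in range(n)],
    )
    params = {
        "n_genes": n_g,
        "n_tfs": len(tfs),
        "n_edges": len(edges),
        "n_conditions": n,
        "noise_level": noise_level,
        "seed": int(seed),
        "base_range": [6.0, 9.0],
        "span_range": [2.0, 4.0],
        "hill_K_range": [0.3, 0.7],
        "hill_exponent_range": [2.0, 4.0],
        "activation_prob": 0.7,
        "tf_intrinsic_mix": 0.5,
        "edge_kinetics": {
            f"{tf}->{tg}": {
                "sign": "activation" if sign[e_i] else "repression",
                "K": float(K[e_i]),
                "h": float(h[e_i]),
            }
            for e_i, (tf, tg) in enumerate(edge_list)
        },
        "biological_noise": "signal multiplied by exp(N(0, noise_level))",
        "experimental_noise": "additive N(0, noise_level * per-gene signal sd)",
    }
    return SyntheticDataset(
        expr=expr, gold_edges=edges, tfs=tfs,
        noise_level=float(noise_level), seed=int(seed), params=params,
    )


def make_pair(
    kind: str,
    n: int,
    n_components: int = 3,
    within_r: float = 0.8,
    seed: int = 0,
    spread: float = 4.0,
    return_labels: bool = False,
):
    """Draw one (x, y) profile pair from a planted bivariate mixture.

    kind="dependent": both coordinates share the component draw; within each
    component (x, y) is bivariate normal with unit variances and correlation
    `within_r`. Component means sit on a regular polygon of radius `spread`,
    which zeroes the between-component covariance: the dependence is purely
    conditional. kind="independent": identical marginals, but the component
    and noise draws of x and y are decoupled, so the population MI is 0.
    """
    if kind not in ("dependent", "independent"):
        raise ValueError("kind must be 'dependent' or 'independent'")
    if not (-1.0 < within_r < 1.0):
        raise ValueError("within_r must be in (-1, 1)")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    G = n_components
    if G == 1:
        mu = np.zeros((1, 2))
    else:
        theta = 2.0 * np.pi * np.arange(G) / G
        mu = spread * np.column_stack([np.cos(theta), np.sin(theta)])
    c = within_r
    chol = np.linalg.cholesky(np.array([[1.0, c], [c, 1.0]]))
    if kind == "dependent":
        z = rng.integers(G, size=n)
        eps = rng.standard_normal((n, 2)) @ chol.T
        pts = mu[z] + eps
        x, y = pts[:, 0], pts[:, 1]
        labels = z
    else:
        zx = rng.integers(G, size=n)
        zy = rng.integers(G, size=n)
        x = mu[zx, 0] + rng.standard_normal(n)
        y = mu[zy, 1] + rng.standard_normal(n)
        labels = None
    if return_labels:
        return x, y, labels
    return x, y
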