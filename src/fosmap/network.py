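"""Interregional correlation networks with a bootstrapped null for edge tests.

For one condition, region activity vectors across subjects are correlated
pairwise (Pearson).  Edges with strong positive correlation form the
co-activation graph, communities are found by greedy modularity
maximization, and each edge's condition-uniqueness is tested against a
null distribution of correlations obtained by bootstrap-resampling
subjects from the pooled, condition-label-ignoring set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import data_matrix_from_table, DataMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationNetwork",
    "correlation_matrix",
    "build_graph",
    "cluster_communities",
    "bootstrap_null_edges",
    "build_network",
    "export_graphml",
    "import_graphml",
]

DEFAULT_EDGE_THRESHOLD = 0.75


def _condition_matrix(
    table: pd.DataFrame, condition: str, value: str, label_class: str | None
) -> DataMatrix:
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not present in table")
    return data_matrix_from_table(sub, value=value, label_class=label_class)


def correlation_matrix(
    table: pd.DataFrame,
    condition: str,
    value: str = "density",
    label_class: str | None = None,
) -> tuple[np.ndarray, list]:
    """Pearson correlation across subjects for every region pair.

    Requires ≥ 3 subjects in the condition; regions incomplete across
    those subjects are dropped (logged).  Zero-variance regions get NaN
    correlations with all partners (logged); the diagonal is exactly 1.

    Returns ``(r_matrix, regions)``.
    """
    dm = _condition_matrix(table, condition, value, label_class)
    if dm.X.shape[0] < 3:
        raise ValueError("correlation needs at least 3 subjects in the condition")
    return _pearson_matrix(dm.X), dm.regions


def _pearson_matrix(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    if degenerate.size:
        logger.info("zero-variance region column(s) at index %s; correlations set missing",
                    degenerate.tolist())
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def build_graph(
    r_matrix: np.ndarray, threshold: float = DEFAULT_EDGE_THRESHOLD
) -> list[tuple[int, int, float]]:
    """Edges ``(i, j, r)`` with ``i < j`` where ``r >= threshold``.

    Positive-correlation (co-activation) graph; NaN entries never form
    edges; isolated regions remain as nodes of the eventual graph.
    """
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [-1, 1]")
    r_matrix = np.asarray(r_matrix)
    edges = []
    p = r_matrix.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            r = r_matrix[i, j]
            if np.isfinite(r) and r >= threshold:
                edges.append((i, j, float(r)))
    return edges


def cluster_communities(
    edges: Sequence[tuple[int, int, float]],
    n_nodes: int,
    seed: int = 0,
) -> dict[int, int]:
    """Community per node by greedy modularity agglomeration.

    Deterministic: ties inside the agglomeration resolve by construction
    order (nodes added in increasing index), and community labels are
    assigned 0..k−1 by decreasing size (then smallest member index).
    Nodes with no edges end up as singleton communities.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    G = nx.Graph()
    G.add_nodes_from(range(n_nodes))
    for i, j, r in edges:
        G.add_edge(i, j, weight=float(r))
    if G.number_of_edges() == 0:
        communities = [{n} for n in range(n_nodes)]
    else:
        communities = [set(c) for c in
                       nx.algorithms.community.greedy_modularity_communities(G)]
    communities.sort(key=lambda c: (-len(c), min(c)))
    out: dict[int, int] = {}
    for label, members in enumerate(communities):
        for n in sorted(members):
            out[n] = label
    return out


def bootstrap_null_edges(
    table: pd.DataFrame,
    condition: str,
    value: str = "density",
    label_class: str | None = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    replace: bool = False,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-edge p-values against a pooled-resampling null network.

    Null replicate ``b`` draws, ignoring condition labels, as many
    subjects from the pooled table as the target condition has, and
    computes that replicate's correlation matrix.  The one-sided p-value
    ``(#{r_null ≥ r_obs} + 1)/(B + 1)`` asks whether the observed
    correlation exceeds what condition-blind subject mixtures produce —
    i.e. whether the edge is unique to the condition.

    By default subjects are drawn *without* replacement: under a global
    null the draw then reproduces exactly the sampling process that
    produced the observed condition, so the per-edge false-positive rate
    is calibrated at the nominal level.  ``replace=True`` switches to a
    classic with-replacement bootstrap, which is strictly more
    conservative (duplicated subjects widen the null correlation
    distribution).

    Returns ``(null_p, r_observed, regions)`` (matrices over the regions
    complete in the pooled table).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if table[table["condition"] == condition].empty:
        raise ValueError(f"condition {condition!r} not present in table")
    if table["condition"].nunique() < 2:
        raise ValueError("null network needs >= 2 conditions in the table")
    pooled = data_matrix_from_table(table, value=value, label_class=label_class)
    cond = np.asarray(pooled.conditions)
    target_idx = np.flatnonzero(cond == condition)
    n_target = target_idx.size
    if pooled.X.shape[0] < n_target:
        raise ValueError("pooled subject count smaller than target condition count")
    r_obs = _pearson_matrix(pooled.X[target_idx])
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(r_obs)
    valid = np.zeros_like(r_obs)
    n_pool = pooled.X.shape[0]
    for _ in range(B):
        if replace:
            take = rng.integers(0, n_pool, size=n_target)
        else:
            take = rng.permutation(n_pool)[:n_target]
        r_null = _pearson_matrix(pooled.X[take])
        finite = np.isfinite(r_null) & np.isfinite(r_obs)
        exceed[finite] += r_null[finite] >= r_obs[finite]
        valid += finite
    with np.errstate(invalid="ignore", divide="ignore"):
        null_p = (exceed + 1.0) / (valid + 1.0)
    null_p[valid == 0] = np.nan
    np.fill_diagonal(null_p, np.nan)
    return null_p, r_obs, pooled.regions


@dataclass
class CorrelationNetwork:
    """A thresholded co-activation graph with communities and edge tests."""

    condition: str
    regions: list
    acronyms: list[str]
    r_matrix: np.ndarray
    edges: list[dict]                    # i, j, r, null_p, significant
    communities: dict[int, int]
    params: dict = field(default_factory=dict)

    def to_nx(self) -> nx.Graph:
        G = nx.Graph(condition=self.condition, **{
            k: v for k, v in self.params.items() if v is not None
        })
        for i, rid in enumerate(self.regions):
            G.add_node(i, region_id=int(rid), acronym=self.acronyms[i],
                       community=int(self.communities.get(i, -1)))
        for e in self.edges:
            G.add_edge(e["i"], e["j"], r=float(e["r"]),
                       null_p=float(e["null_p"]) if e["null_p"] is not None else float("nan"),
                       significant=bool(e["significant"]))
        return G


def build_network(
    table: pd.DataFrame,
    condition: str,
    value: str = "density",
    label_class: str | None = None,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    acronyms: dict | None = None,
) -> CorrelationNetwork:
    """Correlation matrix → thresholded graph → communities → null-edge test."""
    null_p, r_obs, regions = bootstrap_null_edges(
        table, condition, value=value, label_class=label_class, B=B, seed=seed
    )
    edges_raw = build_graph(r_obs, threshold)
    edges = [
        {
            "i": i, "j": j, "r": r,
            "null_p": float(null_p[i, j]) if np.isfinite(null_p[i, j]) else None,
            "significant": bool(np.isfinite(null_p[i, j]) and null_p[i, j] < alpha),
        }
        for i, j, r in edges_raw
    ]
    communities = cluster_communities(edges_raw, n_nodes=len(regions), seed=seed)
    acr = [
        (acronyms or {}).get(rid, str(rid)) for rid in regions
    ]
    return CorrelationNetwork(
        condition=condition,
        regions=list(regions),
        acronyms=acr,
        r_matrix=r_obs,
        edges=edges,
        communities=communities,
        params={"threshold": threshold, "B": B, "seed": seed, "alpha": alpha,
                "value": value},
    )


def export_graphml(network: CorrelationNetwork, path) -> None:
    """Write the network as GraphML (node: region_id/acronym/community;
    edge: r/null_p/significant)."""
    nx.write_graphml(network.to_nx(), path)


def import_graphml(path) -> CorrelationNetwork:
    """Rebuild a :class:`CorrelationNetwork` from an exported GraphML file."""
    try:
        G = nx.read_graphml(path)
    except Exception as exc:  # malformed XML / not graphml
        raise ValueError(f"could not parse GraphML file {path}: {exc}") from exc
    nodes = sorted(G.nodes, key=lambda n: int(n))
    index_of = {n: k for k, n in enumerate(nodes)}
    regions = [int(G.nodes[n].get("region_id", int(n))) for n in nodes]
    acronyms = [str(G.nodes[n].get("acronym", "")) for n in nodes]
    communities = {index_of[n]: int(G.nodes[n].get("community", -1)) for n in nodes}
    p = len(nodes)
    r_matrix = np.full((p, p), np.nan)
    np.fill_diagonal(r_matrix, 1.0)
    edges = []
    for u, v, d in G.edges(data=True):
        i, j = sorted((index_of[u], index_of[v]))
        r = float(d.get("r", np.nan))
        r_matrix[i, j] = r_matrix[j, i] = r
        null_p = d.get("null_p")
        null_p = float(null_p) if null_p is not None and np.isfinite(float(null_p)) else None
        edges.append({"i": i, "j": j, "r": r, "null_p": null_p,
                      "significant": bool(d.get("significant", False))})
    edges.sort(key=lambda e: (e["i"], e["j"]))
    return CorrelationNetwork(
        condition=str(G.graph.get("condition", "")),
        regions=regions,
        acronyms=acronyms,
        r_matrix=r_matrix,
        edges=edges,
        communities=communities,
        params={k: v for k, v in G.graph.items() if k != "condition"},
    )
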