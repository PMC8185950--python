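"""Promoter-promoter interaction graphs and circadian-subnetwork statistics.

Nodes are promoter (bait) fragments; edges are significant bait-bait
interactions (deduplicated, no self-loops), weighted by supporting read
counts. Circadian connectivity is scored against resampled equal-size sets
of non-circadian promoter nodes: an induced-edge-count z-score and a
Mann-Whitney comparison of edge read support.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .io import InteractionTable

__all__ = ["PromoterGraph", "NetworkNullResult", "build_graph",
           "filter_small_components", "circadian_edge_zscore",
           "edge_support_comparison"]


@dataclass
class NetworkNullResult:
    observed: float
    null_values: np.ndarray
    z: float
    empirical_p: float
    degenerate: bool = False
    mannwhitney_p: float | None = None

    @property
    def null_mean(self) -> float:
        return float(self.null_values.mean()) if len(self.null_values) else np.nan

    @property
    def null_sd(self) -> float:
        return float(self.null_values.std(ddof=1)) if len(self.null_values) > 1 else 0.0


class PromoterGraph(nx.Graph):
    """Simple undirected graph of bait fragments; edge attr ``support``."""


def build_graph(table: InteractionTable, timepoint: int | None = None,
                score_threshold: float = 5.0,
                labels: dict[int, str] | None = None) -> PromoterGraph:
    """Graph of significant bait-bait interactions.

    ``timepoint=None`` takes the union over timepoints. Edge ``support`` is
    the summed read count at the timepoint (all timepoints for the union);
    duplicate records merge by summing support.
    """
    g = PromoterGraph()
    df = table.df
    bb = df[df["is_bait_bait"].astype(bool)]
    if timepoint is not None:
        sig = table.significant_at(timepoint, score_threshold)
        count_cols = [c for c in table.count_columns if f"_ZT{timepoint}_" in c]
    else:
        sig = table.significant_any(score_threshold)
        count_cols = table.count_columns
    bb = bb[sig.loc[bb.index]]
    for _, r in bb.iterrows():
        a, b = int(r["bait_frag"]), int(r["other_frag"])
        if a == b:
            continue
        support = float(sum(r[c] for c in count_cols)) if count_cols else 0.0
        if g.has_edge(a, b):
            g[a][b]["support"] += support
        else:
            g.add_edge(a, b, support=support)
    if labels:
        nx.set_node_attributes(g, {n: labels.get(n, str(n)) for n in g}, "label")
    return g


def filter_small_components(graph: PromoterGraph, min_nodes: int = 4) -> PromoterGraph:
    """Drop connected components with fewer than ``min_nodes`` nodes."""
    keep = [c for c in nx.connected_components(graph) if len(c) >= min_nodes]
    sub = graph.subgraph(set().union(*keep) if keep else set()).copy()
    out = PromoterGraph()
    out.add_nodes_from(sub.nodes(data=True))
    out.add_edges_from(sub.edges(data=True))
    return out


def _induced_edges(graph: nx.Graph, nodes: set) -> int:
    return graph.subgraph(nodes).number_of_edges()


def circadian_edge_zscore(graph: PromoterGraph, circadian_nodes: set,
                          n_iter: int = 1000,
                          seed: int | None = None) -> NetworkNullResult:
    """Edges between circadian promoters vs equal-size non-circadian node sets."""
    circ = set(circadian_nodes) & set(graph.nodes)
    if not circ:
        raise ValueError("circadian node set is empty on this graph")
    non = sorted(set(graph.nodes) - circ)
    observed = _induced_edges(graph, circ)
    if len(non) < len(circ):
        return NetworkNullResult(observed, np.array([]), np.nan, np.nan,
                                 degenerate=True)
    rng = np.random.default_rng(seed)
    non_arr = np.array(non)
    null = np.array([
        _induced_edges(graph, set(non_arr[rng.choice(len(non_arr),
                                                     size=len(circ),
                                                     replace=False)]))
        for _ in range(n_iter)
    ], dtype=float)
    sd = null.std(ddof=1) if n_iter > 1 else 0.0
    z = (observed - null.mean()) / sd if sd > 0 else np.nan
    p = (1 + int((null >= observed).sum())) / (n_iter + 1)
    return NetworkNullResult(float(observed), null, float(z), float(p),
                             degenerate=sd == 0)


def edge_support_comparison(graph: PromoterGraph, circadian_nodes: set,
                            n_iter: int = 100,
                            seed: int | None = None) -> NetworkNullResult:
    """Read support of circadian-circadian edges vs resampled null edges."""
    circ = set(circadian_nodes) & set(graph.nodes)
    circ_support = np.array([
        d["support"] for _, _, d in graph.subgraph(circ).edges(data=True)
    ], dtype=float)
    if len(circ_support) == 0:
        return NetworkNullResult(np.nan, np.array([]), np.nan, np.nan,
                                 degenerate=True)
    non = sorted(set(graph.nodes) - circ)
    rng = np.random.default_rng(seed)
    pooled = []
    if len(non) >= len(circ):
        non_arr = np.array(non)
        for _ in range(n_iter):
            draw = set(non_arr[rng.choice(len(non_arr), size=len(circ),
                                          replace=False)])
            pooled.extend(d["support"]
                          for _, _, d in graph.subgraph(draw).edges(data=True))
    pooled = np.array(pooled, dtype=float)
    observed = float(np.median(circ_support))
    if len(pooled) == 0:
        return NetworkNullResult(observed, pooled, np.nan, np.nan, degenerate=True)
    sd = pooled.std(ddof=1) if len(pooled) > 1 else 0.0
    z = (circ_support.mean() - pooled.mean()) / sd if sd > 0 else np.nan
    if np.all(circ_support == circ_support[0]) and np.all(pooled == circ_support[0]):
        mw_p = 1.0
    else:
        mw_p = float(stats.mannwhitneyu(circ_support, pooled,
                                        alternative="two-sided").pvalue)
    emp_p = (1 + int((pooled >= observed).sum())) / (len(pooled) + 1)
    return NetworkNullResult(observed, pooled, float(z), float(emp_p),
                             mannwhitney_p=mw_p)
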