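"""Group-level directed weighted symptom networks and their centralities.

The group network averages, for each ordered symptom pair, the present PCR
ratings over the participants who endorsed both endpoints.  Node size carries
the mean symptom frequency.  Centrality uses the weighted-network measures of
Opsahl and colleagues: outdegree / indegree are weight sums, and betweenness
counts minimal-cost directed paths with edge costs ``weight**(-alpha)``
(default alpha = 1, i.e. strong perceived causes are short hops).  Observed
centralities are judged against a null built by permuting the observed edge
weights — either over the existing edge positions (default) or over all 40*39
ordered pairs — and flagged when they fall outside the central 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import SymptomCatalog, default_catalog
from .records import ParticipantRecord

MEASURES = ("outdegree", "indegree", "betweenness")


@dataclass
class SymptomNetwork:
    """Weighted directed graph over symptoms.

    Edge attributes: ``weight`` (mean PCR, 0-10) and ``n`` (contributing
    participants).  Node attribute: ``mean_frequency``.
    """

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, i: int, j: int) -> float:
        return float(self.graph[i][j]["weight"])

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "weight": d["weight"],
                "n": d.get("n", np.nan),
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "n"])

    def to_edgelist_csv(self, path: str | Path) -> None:
        self.edges_dataframe().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def build_mean_network(
    records: Sequence[ParticipantRecord],
    min_n: int = 1,
    catalog: SymptomCatalog | None = None,
) -> SymptomNetwork:
    """Mean-PCR network averaged over participants who endorsed both symptoms.

    Edge (i, j) exists iff at least ``min_n`` participants answered the
    i-causes-j question; its weight is the available-case mean of those
    answers.  Every catalog item is a node, annotated with its mean frequency
    across all participants (available-case).
    """
    if not records:
        raise ValueError("need at least one participant record")
    catalog = catalog or default_catalog()
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for record in records:
        for pair, value in record.pcr_present().items():
            sums[pair] = sums.get(pair, 0.0) + value
            counts[pair] = counts.get(pair, 0) + 1
    graph = nx.DiGraph()
    for item in catalog.items:
        freqs = [
            r.frequencies[item.id]
            for r in records
            if isinstance(r.frequencies[item.id], int)
        ]
        graph.add_node(
            item.id,
            mean_frequency=float(np.mean(freqs)) if freqs else 0.0,
            abbreviation=item.abbreviation,
            category=item.category,
        )
    for pair, total in sums.items():
        if counts[pair] >= min_n:
            graph.add_edge(pair[0], pair[1], weight=total / counts[pair], n=counts[pair])
    return SymptomNetwork(graph)


def threshold_network(
    net: SymptomNetwork, cutoff: float, strict: bool = True
) -> SymptomNetwork:
    """Keep edges with weight > cutoff (strict) or >= cutoff."""
    if not 0 <= cutoff <= 10:
        raise ValueError("cutoff must lie in [0, 10]")
    graph = net.graph.copy()
    drop = [
        (u, v)
        for u, v, d in graph.edges(data=True)
        if (d["weight"] <= cutoff if strict else d["weight"] < cutoff)
    ]
    graph.remove_edges_from(drop)
    return SymptomNetwork(graph)


def weighted_degrees(net: SymptomNetwork) -> pd.DataFrame:
    """Outdegree and indegree as weight sums, zero for isolated nodes."""
    out = dict(net.graph.out_degree(weight="weight"))
    inn = dict(net.graph.in_degree(weight="weight"))
    return pd.DataFrame(
        {
            "outdegree": [float(out.get(v, 0.0)) for v in net.nodes],
            "indegree": [float(inn.get(v, 0.0)) for v in net.nodes],
        },
        index=pd.Index(net.nodes, name="symptom_id"),
    )


def betweenness_weighted(
    net: SymptomNetwork, alpha: float = 1.0, normalized: bool = False
) -> pd.Series:
    """Directed weighted betweenness with inverse-weight path costs.

    Shortest paths minimise the summed cost ``weight**(-alpha)``; a node's
    score is the fraction of minimal-cost s->t paths through it, summed over
    ordered pairs, with fractional credit across co-minimal paths.
    Zero-weight edges are uncrossable and excluded; unreachable pairs
    contribute nothing.  Raw (unnormalized) counts by default.
    """
    cost_graph = nx.DiGraph()
    cost_graph.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        w = d["weight"]
        if w < 0:
            raise ValueError("edge weights must be non-negative")
        if w > 0:
            cost_graph.add_edge(u, v, cost=w ** (-alpha))
    scores = nx.betweenness_centrality(cost_graph, weight="cost", normalized=normalized)
    return pd.Series(
        [float(scores[v]) for v in net.nodes],
        index=pd.Index(net.nodes, name="symptom_id"),
        name="betweenness",
    )


def _centrality_matrix(net: SymptomNetwork, alpha: float) -> np.ndarray:
    deg = weighted_degrees(net)
    btw = betweenness_weighted(net, alpha=alpha)
    return np.column_stack([deg["outdegree"], deg["indegree"], btw])


@dataclass
class CentralityReport:
    """Observed centralities with permutation-null percentiles and flags.

    ``table`` has one row per symptom and, per measure, the observed value,
    the 2.5 / 50 / 97.5 permutation percentiles, and an extremity flag set
    iff the observed value lies outside the central 95% interval.
    """

    table: pd.DataFrame
    n_perm: int
    mode: str

    def flagged(self, measure: str) -> list[int]:
        return list(self.table.index[self.table[f"{measure}_extreme"]])


def permutation_null(
    net: SymptomNetwork,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "shuffle_weights",
    alpha: float = 1.0,
) -> CentralityReport:
    """Null distributions of the three centralities under weight permutation.

    ``shuffle_weights`` permutes the observed weight multiset over the
    existing edge positions (topology fixed); ``rewire_pairs`` scatters the
    observed weights over all ordered node pairs, absent edges counting as
    zeros.  True permutation (without replacement), deterministic per seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("shuffle_weights", "rewire_pairs"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    nodes = net.nodes
    edges = list(net.graph.edges)
    weights = np.array([net.graph[u][v]["weight"] for u, v in edges], dtype=float)
    observed = _centrality_matrix(net, alpha)

    all_pairs = [(u, v) for u in nodes for v in nodes if u != v]
    null = np.empty((n_perm, len(nodes), 3))
    for k in range(n_perm):
        perm_graph = nx.DiGraph()
        perm_graph.add_nodes_from(nodes)
        if mode == "shuffle_weights":
            shuffled = weights[rng.permutation(len(weights))]
            for (u, v), w in zip(edges, shuffled):
                perm_graph.add_edge(u, v, weight=float(w))
        else:
            positions = rng.choice(len(all_pairs), size=len(weights), replace=False)
            for pos, w in zip(positions, weights):
                u, v = all_pairs[pos]
                perm_graph.add_edge(u, v, weight=float(w))
        null[k] = _centrality_matrix(SymptomNetwork(perm_graph), alpha)

    pct = np.percentile(null, [2.5, 50.0, 97.5], axis=0)  # (3, nodes, measures)
    data: dict[str, np.ndarray] = {}
    for j, measure in enumerate(MEASURES):
        data[measure] = observed[:, j]
        data[f"{measure}_p2.5"] = pct[0, :, j]
        data[f"{measure}_p50"] = pct[1, :, j]
        data[f"{measure}_p97.5"] = pct[2, :, j]
        data[f"{measure}_extreme"] = (observed[:, j] < pct[0, :, j]) | (
            observed[:, j] > pct[2, :, j]
        )
    table = pd.DataFrame(data, index=pd.Index(nodes, name="symptom_id"))
    return CentralityReport(table=table, n_perm=n_perm, mode=mode)


def layout_fruchterman_reingold(
    net: SymptomNetwork, seed: int = 0
) -> dict[int, tuple[float, float]]:
    """Force-directed node coordinates (deterministic per seed)."""
    if len(net.nodes) == 1:
        return {net.nodes[0]: (0.0, 0.0)}
    pos = nx.spring_layout(net.graph, seed=seed, weight="weight")
    return {v: (float(p[0]), float(p[1])) for v, p in pos.items()}


def plot_network(
    net: SymptomNetwork,
    path: str | Path,
    seed: int = 0,
    light_cutoff: float = 3.0,
    dark_cutoff: float = 4.5,
) -> None:
    """Basic figure export: edges above ``light_cutoff``, darker above
    ``dark_cutoff``, node size proportional to mean frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = threshold_network(net, light_cutoff, strict=True)
    pos = layout_fruchterman_reingold(shown, seed=seed)
    fig, ax = plt.subplots(figsize=(9, 9))
    freqs = [shown.graph.nodes[v].get("mean_frequency", 0.0) for v in shown.nodes]
    sizes = [100 + 400 * f for f in freqs]
    nx.draw_networkx_nodes(shown.graph, pos, nodelist=shown.nodes, node_size=sizes, ax=ax)
    light = [(u, v) for u, v, d in shown.graph.edges(data=True) if d["weight"] <= dark_cutoff]
    dark = [(u, v) for u, v, d in shown.graph.edges(data=True) if d["weight"] > dark_cutoff]
    nx.draw_networkx_edges(shown.graph, pos, edgelist=light, alpha=0.25, ax=ax)
    nx.draw_networkx_edges(shown.graph, pos, edgelist=dark, alpha=0.9, width=2.0, ax=ax)
    labels = {v: shown.graph.nodes[v].get("abbreviation", str(v)) for v in shown.nodes}
    nx.draw_networkx_labels(shown.graph, pos, labels=labels, font_size=7, ax=ax)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
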