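"""Per-participant feedback loops and their link to symptom burden.

Each participant's network keeps only the strong perceived causal relations
(PCR above 4.5 by default).  A feedback loop is a simple directed cycle in
that network; for computational feasibility only loops over at most four
distinct symptoms are enumerated.  The census feeds two analyses: which
symptoms sit in loops most often (optionally corrected for how many
participants endorse them), and whether participants with more loops carry a
heavier symptom burden (Spearman's rho against the 40-item frequency sum,
with rank-based partial correlations controlling network size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import SymptomNetwork
from .records import ParticipantRecord, frequency_sum_score

Cycle = tuple[int, ...]


def participant_network(
    record: ParticipantRecord, cutoff: float = 4.5, strict: bool = True
) -> SymptomNetwork:
    """One participant's thresholded PCR network.

    Nodes are the endorsed symptoms; edge (i, j) exists iff PCR(i, j) is
    present and above the cutoff ("above" read as strict > by default).
    """
    graph = nx.DiGraph()
    for sid in record.endorsed():
        freq = record.frequencies[sid]
        graph.add_node(sid, frequency=freq)
    for (i, j), value in record.pcr_present().items():
        if value > cutoff if strict else value >= cutoff:
            graph.add_edge(i, j, weight=float(value))
    return SymptomNetwork(graph)


def enumerate_cycles(
    net: SymptomNetwork | nx.DiGraph, max_len: int = 4
) -> list[Cycle]:
    """All simple directed cycles of length 2..max_len, canonical and sorted.

    Bounded-depth DFS anchored at each node in increasing id order, visiting
    only larger ids, so every cycle is found exactly once already in canonical
    rotation (smallest id first, direction preserved).  Output is sorted by
    (length, node tuple).  The depth bound keeps even a complete 40-node
    digraph tractable.
    """
    graph = net.graph if isinstance(net, SymptomNetwork) else net
    if any(graph.has_edge(v, v) for v in graph):
        raise ValueError("self-edges are not allowed")
    adj = {u: sorted(graph.successors(u)) for u in graph}
    cycles: list[Cycle] = []
    path: list[int] = []
    on_path: set[int] = set()

    def extend(start: int, u: int) -> None:
        for v in adj[u]:
            if v == start and len(path) >= 2:
                cycles.append(tuple(path))
            elif v > start and v not in on_path and len(path) < max_len:
                path.append(v)
                on_path.add(v)
                extend(start, v)
                path.pop()
                on_path.remove(v)

    for start in sorted(adj):
        path[:] = [start]
        on_path = {start}
        extend(start, start)
    return sorted(cycles, key=lambda c: (len(c), c))


def canonical_cycle(cycle: Sequence[int]) -> Cycle:
    """Rotate a cycle so its smallest node comes first, direction preserved."""
    cycle = tuple(cycle)
    k = cycle.index(min(cycle))
    return cycle[k:] + cycle[:k]


@dataclass
class LoopCensus:
    """Enumerated feedback loops per participant plus population totals."""

    cutoff: float
    max_len: int
    cycles: dict[str, list[Cycle]]  # participant id -> canonical cycles
    per_participant: pd.DataFrame  # n_symptoms, n_edges, n_pcr_present, loop_count
    symptom_incidences: Mapping[int, int] = field(default_factory=dict)
    total_incidences: int = 0  # (participant, loop) pairs
    unique_loop_types: int = 0  # distinct canonical cycles pooled over participants

    def loop_counts(self) -> pd.Series:
        return self.per_participant["loop_count"]


def compute_loop_census(
    records: Sequence[ParticipantRecord],
    cutoff: float = 4.5,
    max_len: int = 4,
    strict: bool = True,
) -> LoopCensus:
    """Enumerate every participant's feedback loops and tally involvement."""
    cycles: dict[str, list[Cycle]] = {}
    rows = []
    incidences: dict[int, int] = {}
    pooled: set[Cycle] = set()
    for record in records:
        net = participant_network(record, cutoff=cutoff, strict=strict)
        found = enumerate_cycles(net, max_len=max_len)
        cycles[record.participant_id] = found
        pooled.update(found)
        for cycle in found:
            for sid in cycle:
                incidences[sid] = incidences.get(sid, 0) + 1
        rows.append(
            {
                "participant_id": record.participant_id,
                "n_symptoms": len(record.endorsed()),
                "n_edges": net.n_edges,
                "n_pcr_present": record.n_pcr_present(),
                "loop_count": len(found),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["participant_id", "n_symptoms", "n_edges", "n_pcr_present", "loop_count"],
    ).set_index("participant_id")
    return LoopCensus(
        cutoff=cutoff,
        max_len=max_len,
        cycles=cycles,
        per_participant=table,
        symptom_incidences=incidences,
        total_incidences=sum(len(c) for c in cycles.values()),
        unique_loop_types=len(pooled),
    )


def symptom_involvement(
    census: LoopCensus,
    records: Sequence[ParticipantRecord],
    normalization: str = "per-endorsing-participant",
) -> pd.Series:
    """Per-symptom loop involvement, optionally frequency-corrected.

    Raw involvement counts (participant, loop) incidences containing the
    symptom.  ``per-endorsing-participant`` divides by how many participants
    endorsed the symptom; ``per-frequency-sum`` divides by the symptom's total
    frequency across participants; ``none`` returns raw counts.
    """
    if normalization not in ("per-endorsing-participant", "per-frequency-sum", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    all_ids = sorted(records[0].frequencies) if records else []
    raw = pd.Series(
        [float(census.symptom_incidences.get(sid, 0)) for sid in all_ids],
        index=pd.Index(all_ids, name="symptom_id"),
        name="involvement",
    )
    if normalization == "none":
        return raw
    if normalization == "per-endorsing-participant":
        denom = pd.Series(
            [
                sum(
                    1
                    for r in records
                    if isinstance(r.frequencies[sid], int) and r.frequencies[sid] >= 1
                )
                for sid in all_ids
            ],
            index=raw.index,
            dtype=float,
        )
    else:
        denom = pd.Series(
            [
                float(
                    sum(
                        r.frequencies[sid]
                        for r in records
                        if isinstance(r.frequencies[sid], int)
                    )
                )
                for sid in all_ids
            ],
            index=raw.index,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = raw / denom
    return corrected.where(raw > 0, 0.0).fillna(0.0)


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Spearman correlation of x and y partialling out the controls.

    Computed as the Pearson partial correlation on mid-rank-transformed
    variables (residualising both rank vectors on the ranked controls);
    two-tailed p from the t approximation with df = n - 2 - k.  Constant
    controls carry no information and drop out, so the result reduces to the
    plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    active = [
        stats.rankdata(np.asarray(c, dtype=float))
        for c in controls
        if np.std(np.asarray(c, dtype=float)) > 0
    ]
    k = len(active)
    Z = np.column_stack([np.ones(n)] + active)
    rx_res = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ry_res = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    if np.std(rx_res) == 0 or np.std(ry_res) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx_res, ry_res)[0, 1])
    df = n - 2 - k
    if df < 1:
        return rho, float("nan")
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    return rho, float(2 * stats.t.sf(abs(t), df))


@dataclass
class LoopBurdenResult:
    """Association between per-participant loop count and symptom burden."""

    rho: float
    p: float
    partial_rho_symptoms: float  # controlling number of endorsed symptoms
    partial_p_symptoms: float
    partial_rho_full: float  # + number of present PCR entries
    partial_p_full: float
    n: int
    defined: bool


def loop_burden_association(
    census: LoopCensus,
    records: Sequence[ParticipantRecord],
    burden_items: Iterable[int] | None = None,
    pcr_control: str = "present",
) -> LoopBurdenResult:
    """Spearman and partial Spearman of loop count vs frequency sum score.

    Controls: (1) the number of endorsed symptoms; (2) additionally the
    number of PCR entries — present ratings by default, or supra-threshold
    edges with ``pcr_control='edges'``.  Returns an undefined-result marker
    when either variable has zero variance.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 participants")
    order = [r.participant_id for r in records]
    table = census.per_participant.loc[order]
    loops = table["loop_count"].to_numpy(dtype=float)
    burden = np.array([frequency_sum_score(r, burden_items) for r in records])
    n_symptoms = table["n_symptoms"].to_numpy(dtype=float)
    n_pcr = (
        table["n_pcr_present"] if pcr_control == "present" else table["n_edges"]
    ).to_numpy(dtype=float)

    if np.std(loops) == 0 or np.std(burden) == 0:
        return LoopBurdenResult(
            rho=float("nan"), p=float("nan"),
            partial_rho_symptoms=float("nan"), partial_p_symptoms=float("nan"),
            partial_rho_full=float("nan"), partial_p_full=float("nan"),
            n=len(records), defined=False,
        )
    res = stats.spearmanr(loops, burden)
    rho1, p1 = partial_spearman(loops, burden, [n_symptoms])
    rho2, p2 = partial_spearman(loops, burden, [n_symptoms, n_pcr])
    return LoopBurdenResult(
        rho=float(res.statistic),
        p=float(res.pvalue),
        partial_rho_symptoms=rho1,
        partial_p_symptoms=p1,
        partial_rho_full=rho2,
        partial_p_full=p2,
        n=len(records),
        defined=True,
    )
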