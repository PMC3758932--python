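import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from pcrnet.loops import (
    canonical_cycle,
    compute_loop_census,
    enumerate_cycles,
    loop_burden_association,
    partial_spearman,
    participant_network,
    symptom_involvement,
)
from conftest import build_record, random_digraph


class TestParticipantNetwork:
    def test_weak_ratings_leave_no_edges(self, catalog):
        record = build_record(
            "p", {1: 1, 2: 1}, {(1, 2): 4, (2, 1): 3}, catalog
        )
        assert participant_network(record).n_edges == 0

    def test_reciprocal_strong_pair(self, catalog):
        record = build_record(
            "p", {1: 1, 2: 1}, {(1, 2): 5, (2, 1): 5}, catalog
        )
        net = participant_network(record)
        assert sorted(net.graph.edges) == [(1, 2), (2, 1)]

    def test_cutoff_is_strict_by_default(self, catalog):
        record = build_record("p", {1: 1, 2: 1}, {(1, 2): 5}, catalog)
        assert participant_network(record, cutoff=5.0).n_edges == 0
        assert participant_network(record, cutoff=5.0, strict=False).n_edges == 1

    def test_brute_force_filter(self, catalog, rng):
        freqs = {i: 1 for i in range(1, 8)}
        pcr = {}
        record = build_record("p", freqs, catalog=catalog)
        for pair in record.eligible_pairs():
            pcr[pair] = int(rng.integers(0, 11))
            record.pcr[pair] = pcr[pair]
        net = participant_network(record, cutoff=4.5)
        expected = {pair for pair, v in pcr.items() if v > 4.5}
        assert set(net.graph.edges) == expected

    def test_nodes_are_endorsed_symptoms(self, catalog):
        record = build_record("p", {3: 2, 9: 1, 17: 7}, catalog=catalog)
        net = participant_network(record)
        assert net.nodes == [3, 9, 17]


def nx_cycles(g, max_len):
    """Independent oracle: networkx simple_cycles with a length bound."""
    return sorted(
        (canonical_cycle(c) for c in nx.simple_cycles(g, length_bound=max_len)
         if len(c) >= 2),
        key=lambda c: (len(c), c),
    )


class TestEnumerateCycles:
    def test_acyclic_graph_has_none(self):
        g = nx.DiGraph([(1, 2), (2, 3), (1, 3)])
        assert enumerate_cycles(g) == []

    def test_complete_four_node_digraph(self):
        g = nx.DiGraph(
            [(u, v) for u in range(1, 5) for v in range(1, 5) if u != v]
        )
        cycles = enumerate_cycles(g, max_len=4)
        # 6 two-cycles + 8 three-cycles + 6 four-cycles
        assert len(cycles) == 20
        by_len = {k: sum(1 for c in cycles if len(c) == k) for k in (2, 3, 4)}
        assert by_len == {2: 6, 3: 8, 4: 6}

    def test_canonical_form_and_order(self):
        g = nx.DiGraph([(3, 1), (1, 3), (2, 5), (5, 7), (7, 2)])
        cycles = enumerate_cycles(g)
        assert cycles == [(1, 3), (2, 5, 7)]
        for c in cycles:
            assert c[0] == min(c)
            assert canonical_cycle(c) == c  # canonicalization idempotent

    def test_direction_preserved(self):
        g = nx.DiGraph([(1, 2), (2, 3), (3, 1)])  # only one orientation
        assert enumerate_cycles(g) == [(1, 2, 3)]

    def test_length_bound_respected(self):
        g = nx.DiGraph([(1, 2), (2, 3), (3, 4), (4, 5), (5, 1)])  # 5-cycle
        assert enumerate_cycles(g, max_len=4) == []
        assert enumerate_cycles(g, max_len=5) == [(1, 2, 3, 4, 5)]

    def test_self_edges_rejected(self):
        g = nx.DiGraph([(1, 1)])
        with pytest.raises(ValueError):
            enumerate_cycles(g)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_oracle_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_digraph(rng, int(rng.integers(3, 9)), float(rng.uniform(0.1, 0.6)))
        assert enumerate_cycles(g, max_len=4) == nx_cycles(g, 4)

    def test_exhaustive_on_all_small_graphs(self):
        """Every digraph on 4 nodes with 4 labeled candidate edges agrees
        with the networkx oracle (full enumeration of edge subsets)."""
        all_edges = [(u, v) for u in range(1, 5) for v in range(1, 5) if u != v]
        for subset in itertools.combinations(all_edges, 4):
            g = nx.DiGraph()
            g.add_nodes_from(range(1, 5))
            g.add_edges_from(subset)
            assert enumerate_cycles(g, max_len=4) == nx_cycles(g, 4)


class TestCensus:
    def _population(self, catalog):
        strong = {(1, 2): 6, (2, 1): 7}
        weak = {(1, 2): 2}
        return [
            build_record("a", {1: 1, 2: 1}, strong, catalog),
            build_record("b", {1: 1, 2: 1}, strong, catalog),
            build_record("c", {1: 1, 2: 1}, weak, catalog),
            build_record("d", {1: 1, 2: 2, 3: 1}, strong, catalog),
        ]

    def test_counts_and_totals(self, catalog):
        census = compute_loop_census(self._population(catalog))
        assert census.per_participant["loop_count"].tolist() == [1, 1, 0, 1]
        assert census.total_incidences == 3
        assert census.unique_loop_types == 1

    def test_relabeling_participants_preserves_census(self, catalog):
        records = self._population(catalog)
        census1 = compute_loop_census(records)
        for i, r in enumerate(records):
            r.participant_id = f"z{i}"
        census2 = compute_loop_census(records)
        assert sorted(census1.cycles.values()) == sorted(census2.cycles.values())
        assert census1.total_incidences == census2.total_incidences

    def test_loop_count_monotone_in_cutoff(self, catalog, rng):
        freqs = {i: 1 for i in range(1, 9)}
        record = build_record("p", freqs, catalog=catalog)
        for pair in record.eligible_pairs():
            record.pcr[pair] = int(rng.integers(0, 11))
        counts = [
            compute_loop_census([record], cutoff=c).total_incidences
            for c in (0, 2, 4, 6, 8, 10)
        ]
        assert counts == sorted(counts, reverse=True)


class TestInvolvement:
    def test_loopless_symptom_scores_zero(self, catalog):
        records = [build_record("a", {1: 1, 2: 1}, {(1, 2): 6, (2, 1): 6}, catalog)]
        census = compute_loop_census(records)
        for norm in ("none", "per-endorsing-participant", "per-frequency-sum"):
            inv = symptom_involvement(census, records, norm)
            assert inv[5] == 0.0

    def test_shared_loop_normalized_by_endorsers(self, catalog):
        strong = {(1, 2): 6, (2, 1): 6}
        records = [
            build_record("a", {1: 1, 2: 1}, strong, catalog),
            build_record("b", {1: 1, 2: 1}, strong, catalog),
            build_record("c", {1: 1, 2: 1}, {}, catalog),
            build_record("d", {1: 1, 2: 1}, {}, catalog),
        ]
        census = compute_loop_census(records)
        raw = symptom_involvement(census, records, "none")
        corrected = symptom_involvement(census, records)
        assert raw[1] == 2.0  # item 1 in one loop for two participants
        assert corrected[1] == 0.5  # 2 incidences / 4 endorsing participants

    def test_unknown_normalization(self, catalog):
        records = [build_record("a", {1: 1}, catalog=catalog)]
        census = compute_loop_census(records)
        with pytest.raises(ValueError):
            symptom_involvement(census, records, "bogus")


class TestPartialSpearman:
    def test_constant_control_equals_plain_spearman(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        rho, p = partial_spearman(x, y, [np.full(60, 5.0)])
        plain = stats.spearmanr(x, y)
        assert rho == pytest.approx(plain.statistic)
        assert p == pytest.approx(plain.pvalue, rel=0.05)

    def test_partialling_removes_shared_driver(self, rng):
        n = 500
        z = rng.normal(size=n)
        x = z + 0.1 * rng.normal(size=n)
        y = z + 0.1 * rng.normal(size=n)
        rho_plain = stats.spearmanr(x, y).statistic
        rho_partial, _ = partial_spearman(x, y, [z])
        assert rho_plain > 0.9
        assert abs(rho_partial) < 0.4

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 80
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 0.5 * x + 0.5 * z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        rho, p = partial_spearman(x, y, [z])
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-3)


class TestLoopBurdenAssociation:
    def _records_with_loops(self, catalog, n_loops_per_pid):
        """Participants whose loop counts scale with how many reciprocal
        strong pairs they endorse."""
        records = []
        for pid, k in n_loops_per_pid:
            items = list(range(1, 2 * k + 1)) or [1]
            freqs = {i: 2 for i in items}
            pcr = {}
            for j in range(k):
                a, b = 2 * j + 1, 2 * j + 2
                pcr[(a, b)] = 7
                pcr[(b, a)] = 7
            records.append(build_record(pid, freqs, pcr, catalog))
        return records

    def test_constant_loop_count_is_undefined(self, catalog):
        records = [
            build_record(f"p{k}", {1: k % 7 + 1}, catalog=catalog) for k in range(12)
        ]
        census = compute_loop_census(records)
        res = loop_burden_association(census, records)
        assert not res.defined

    def test_monotone_relation_gives_rho_one(self, catalog):
        plan = [(f"p{k}", k % 4) for k in range(16)]
        records = self._records_with_loops(catalog, plan)
        census = compute_loop_census(records)
        res = loop_burden_association(census, records)
        # loop count is a strictly increasing function of frequency sum here
        assert res.rho == pytest.approx(1.0)
        assert res.defined

    def test_too_few_participants_rejected(self, catalog):
        records = [build_record("p", {1: 1}, catalog=catalog)]
        census = compute_loop_census(records)
        with pytest.raises(ValueError):
            loop_burden_association(census, records)

    def test_edge_control_variant_runs(self, catalog):
        plan = [(f"p{k}", k % 3) for k in range(15)]
        records = self._records_with_loops(catalog, plan)
        census = compute_loop_census(records)
        res = loop_burden_association(census, records, pcr_control="edges")
        assert res.defined
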