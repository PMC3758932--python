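import numpy as np
import pytest

from pcrnet import (
    Missing,
    ParticipantRecord,
    SimulationConfig,
    default_catalog,
    simulate_population,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def build_record(pid, freqs, pcr=None, catalog=None):
    """A valid record from sparse dicts: unlisted items get frequency 0,
    eligible pairs without a rating become missing-by-intention."""
    catalog = catalog or default_catalog()
    frequencies = {i: 0 for i in catalog.ids}
    frequencies.update(freqs)
    record = ParticipantRecord(participant_id=pid, frequencies=frequencies)
    for pair in record.eligible_pairs():
        record.pcr[pair] = Missing.BY_INTENTION
    if pcr:
        for pair, value in pcr.items():
            record.pcr[pair] = value
    return record.validate(catalog)


@pytest.fixture()
def make_record(catalog):
    return lambda pid, freqs, pcr=None: build_record(pid, freqs, pcr, catalog)


@pytest.fixture(scope="session")
def small_population(catalog):
    """One deterministic simulated population shared by read-only tests."""
    records, truth = simulate_population(
        SimulationConfig(n_participants=120, seed=20260928), catalog
    )
    return records, truth


def random_digraph(rng, n_nodes, p_edge, weighted=False):
    """A random simple digraph (no self-edges) as a networkx DiGraph."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(1, n_nodes + 1))
    for u in g.nodes:
        for v in g.nodes:
            if u != v and rng.random() < p_edge:
                w = float(rng.uniform(0.5, 9.5)) if weighted else 1.0
                g.add_edge(u, v, weight=w)
    return g


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
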