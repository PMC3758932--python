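"""Synthetic populations with a known directed causal ground truth.

The original survey data is not deposited, so every analysis stage is tested
against populations simulated from a configurable ground-truth weight matrix
W (40 x 40, non-negative, zero diagonal) with planted feedback loops.

Generative scheme, deterministic given the seed:

1. Latent activations on [0, 1]: each participant starts at
   ``a0 = clip(base + eps, 0, 1)`` where ``base`` encodes the per-item
   endorsement probability and ``eps ~ N(0, noise/10)`` is participant noise,
   then iterates ``a <- clip(base + gain * W a + eps, 0, 1)`` a fixed small
   number of steps (default 3) so planted loops amplify the activation of the
   symptoms they contain.
2. Activation maps to the ordinal 0-7 frequency by eight equally spaced
   thresholds (zero-inflated: activation below 1/8 scores 0).
3. For each eligible ordered pair (both endpoints endorsed), the PCR rating
   is ``clip(round(pcr_fidelity * W[i, j] + N(0, noise)), 0, 10)``;
   ineligible pairs are missing by design.
4. Missing-by-intention is injected at the configured rates (frequencies
   first, so a skipped frequency makes its pairs missing by design).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .catalog import N_ITEMS, SymptomCatalog, default_catalog
from .records import Missing, ParticipantRecord

_FIRST_THRESHOLD = 1.0 / 8.0  # activation needed to endorse at all


@dataclass
class GroundTruth:
    """The directed causal structure a simulated population obeys."""

    causal_weights: np.ndarray  # (40, 40), non-negative, zero diagonal
    planted_loops: list[tuple[int, ...]] = field(default_factory=list)
    base_rates: np.ndarray | None = None  # per-item endorsement probability
    noise: float = 1.0  # rating-noise SD on the 0-10 scale
    pcr_fidelity: float = 1.5  # expected PCR per unit of true weight

    def __post_init__(self) -> None:
        W = np.asarray(self.causal_weights, dtype=float)
        if W.shape != (N_ITEMS, N_ITEMS):
            raise ValueError(f"causal_weights must be {N_ITEMS}x{N_ITEMS}, got {W.shape}")
        if np.any(np.diag(W) != 0):
            raise ValueError("causal_weights must have a zero diagonal")
        if np.any(W < 0):
            raise ValueError("causal_weights must be non-negative")
        self.causal_weights = W
        if self.base_rates is None:
            self.base_rates = np.full(N_ITEMS, 0.30)
        self.base_rates = np.asarray(self.base_rates, dtype=float)
        if self.base_rates.shape != (N_ITEMS,):
            raise ValueError("base_rates must have one entry per item")
        if np.any((self.base_rates < 0) | (self.base_rates > 1)):
            raise ValueError("base_rates must lie in [0, 1]")
        if self.noise < 0 or self.pcr_fidelity < 0:
            raise ValueError("noise and pcr_fidelity must be non-negative")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_weights": self.causal_weights.tolist(),
            "planted_loops": [list(c) for c in self.planted_loops],
            "base_rates": self.base_rates.tolist(),
            "noise": self.noise,
            "pcr_fidelity": self.pcr_fidelity,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            causal_weights=np.asarray(d["causal_weights"]),
            planted_loops=[tuple(c) for c in d["planted_loops"]],
            base_rates=np.asarray(d["base_rates"]),
            noise=float(d["noise"]),
            pcr_fidelity=float(d["pcr_fidelity"]),
        )


#: default planted feedback loops (1-based item ids): two 2-cycles linking
#: reexperiencing and worry/depressed-mood symptoms, two 3-cycles through the
#: depression cluster, and one 4-cycle through guilt-shame
DEFAULT_LOOPS: tuple[tuple[int, ...], ...] = (
    (5, 7),
    (2, 13),
    (13, 24, 25),
    (2, 30, 32),
    (5, 8, 25, 13),
)

LOOP_WEIGHT = 4.0  # ground-truth weight on planted loop edges (PCR ~ 6)


def default_ground_truth(
    seed: int = 0,
    loops: tuple[tuple[int, ...], ...] = DEFAULT_LOOPS,
    background_density: float = 0.08,
    base_rate: float = 0.30,
    noise: float = 1.0,
    pcr_fidelity: float = 1.5,
) -> GroundTruth:
    """A realistic default truth: strong planted loops over weak sparse noise.

    Background edges get weights U(0.5, 2.0) — expected PCR at or below 3,
    under the 4.5 loop cutoff — so the planted cycles are the only structures
    that should survive per-participant thresholding.
    """
    rng = np.random.default_rng(seed)
    W = np.zeros((N_ITEMS, N_ITEMS))
    mask = rng.random((N_ITEMS, N_ITEMS)) < background_density
    np.fill_diagonal(mask, False)
    W[mask] = rng.uniform(0.5, 2.0, mask.sum())
    for cycle in loops:
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            W[a - 1, b - 1] = LOOP_WEIGHT
    return GroundTruth(
        causal_weights=W,
        planted_loops=[tuple(c) for c in loops],
        base_rates=np.full(N_ITEMS, base_rate),
        noise=noise,
        pcr_fidelity=pcr_fidelity,
    )


@dataclass
class SimulationConfig:
    """Everything a reproducible simulated study needs."""

    n_participants: int
    seed: int
    truth: GroundTruth | None = None
    freq_missing_rate: float = 0.02  # frequency ratings skipped "by intention"
    pcr_missing_rate: float = 0.008  # PCR ratings skipped (< 1%)
    activation_gain: float = 0.05  # coupling strength of W in the latent pass
    n_iterations: int = 3  # fixed number of structural iterations

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for rate in (self.freq_missing_rate, self.pcr_missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("missingness rates must lie in [0, 1]")
        if self.truth is None:
            self.truth = default_ground_truth()


def _base_activation(truth: GroundTruth) -> np.ndarray:
    """Per-item latent offset so P(endorse) ~ base_rate absent coupling."""
    rates = np.clip(truth.base_rates, 1e-12, 1 - 1e-12)
    z = norm.ppf(rates)
    base = _FIRST_THRESHOLD + (truth.noise / 10.0) * z
    return np.where(truth.base_rates <= 0, -1.0, base)


def simulate_population(
    config: SimulationConfig, catalog: SymptomCatalog | None = None
) -> tuple[list[ParticipantRecord], GroundTruth]:
    """Draw a validated population of participant records from the truth."""
    catalog = catalog or default_catalog()
    truth = config.truth
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    W = truth.causal_weights
    activation_noise = truth.noise / 10.0

    base = _base_activation(truth)
    eps = rng.normal(0.0, activation_noise, size=(n, N_ITEMS)) if activation_noise > 0 else np.zeros((n, N_ITEMS))
    a = np.clip(base + eps, 0.0, 1.0)
    for _ in range(config.n_iterations):
        a = np.clip(base + config.activation_gain * (a @ W.T) + eps, 0.0, 1.0)
    freq = np.minimum(np.floor(a * 8.0), 7.0).astype(int)

    freq_skip = rng.random((n, N_ITEMS)) < config.freq_missing_rate

    records: list[ParticipantRecord] = []
    width = len(str(n))
    for p in range(n):
        frequencies: dict[int, int | Missing] = {}
        for i in range(N_ITEMS):
            if freq_skip[p, i]:
                frequencies[i + 1] = Missing.BY_INTENTION
            else:
                frequencies[i + 1] = int(freq[p, i])
        record = ParticipantRecord(
            participant_id=f"P{p + 1:0{width}d}", frequencies=frequencies
        )
        pairs = record.eligible_pairs()
        if pairs:
            idx = np.array(pairs) - 1
            expected = truth.pcr_fidelity * W[idx[:, 0], idx[:, 1]]
            pcr_noise = (
                rng.normal(0.0, truth.noise, size=len(pairs))
                if truth.noise > 0
                else np.zeros(len(pairs))
            )
            values = np.clip(np.rint(expected + pcr_noise), 0, 10).astype(int)
            skips = rng.random(len(pairs)) < config.pcr_missing_rate
            for pair, value, skip in zip(pairs, values, skips):
                record.pcr[pair] = Missing.BY_INTENTION if skip else int(value)
        records.append(record.validate(catalog))
    return records, truth


def planted_loop_census(
    truth: GroundTruth, cutoff: float, max_len: int = 4
) -> list[tuple[int, ...]]:
    """All simple directed cycles of length 2..max_len in the thresholded truth.

    Brute force over node subsets and cyclic orders (independent of the
    production cycle enumerator, so it can serve as its oracle).  Cycles are
    canonical — smallest id first, direction preserved — and sorted.
    """
    W = truth.causal_weights
    adj = W > cutoff
    nodes = [i + 1 for i in range(N_ITEMS) if adj[i].any() or adj[:, i].any()]
    found: list[tuple[int, ...]] = []
    for length in range(2, max_len + 1):
        for combo in itertools.combinations(nodes, length):
            first, rest = combo[0], combo[1:]
            for order in itertools.permutations(rest):
                cycle = (first,) + order
                edges = zip(cycle, cycle[1:] + cycle[:1])
                if all(adj[a - 1, b - 1] for a, b in edges):
                    found.append(cycle)
    return sorted(found, key=lambda c: (len(c), c))
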