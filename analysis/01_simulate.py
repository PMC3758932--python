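#!/usr/bin/env python
"""Simulate the study population and write its data files.

Draws 300 participants from the default ground truth (sparse weak background
causal weights plus five planted feedback loops among reexperiencing,
worry/depressed-mood, and guilt-shame symptoms) and writes frequencies.csv,
pcr.csv, catalog.json and truth.json under results/data/.  Later drivers read
these files, so run this one first.
"""

from pathlib import Path

from pcrnet import SimulationConfig, default_catalog, simulate_population
from pcrnet.io import write_frequency_table, write_pcr_table
from pcrnet.records import Missing

SEED = 42
N_PARTICIPANTS = 300
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()
    records, truth = simulate_population(
        SimulationConfig(n_participants=N_PARTICIPANTS, seed=SEED), catalog
    )
    catalog.save(OUT / "catalog.json")
    truth.to_json(OUT / "truth.json")
    write_frequency_table(records, OUT / "frequencies.csv")
    write_pcr_table(records, OUT / "pcr.csv")

    n_endorsed = [len(r.endorsed()) for r in records]
    freq_cells = [v for r in records for v in r.frequencies.values()]
    pcr_cells = [v for r in records for v in r.pcr.values()]
    pct_freq_missing = 100 * sum(
        1 for v in freq_cells if v is Missing.BY_INTENTION
    ) / len(freq_cells)
    pct_pcr_missing = 100 * sum(
        1 for v in pcr_cells if v is Missing.BY_INTENTION
    ) / len(pcr_cells)
    print(f"simulated {len(records)} participants (seed {SEED}) -> {OUT}")
    print(f"endorsed symptoms per participant: "
          f"mean {sum(n_endorsed) / len(n_endorsed):.1f}, "
          f"range {min(n_endorsed)}-{max(n_endorsed)}")
    print(f"missing by intention: {pct_freq_missing:.1f}% of frequencies, "
          f"{pct_pcr_missing:.1f}% of PCR ratings")
    print(f"planted loops: {truth.planted_loops}")


if __name__ == "__main__":
    main()
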