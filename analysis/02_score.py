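#!/usr/bin/env python
"""Cause-vs-effect association scoring over the simulated population.

For each of the 40 symptoms: mean causal association (C, the average PCR the
symptom receives as a cause), mean effect association (E), and the paired
contrast of C against E across participants with Holm-corrected significance.
Writes the full table to results/tables/cause_effect_table.csv and prints the
symptoms most clearly perceived as causes or effects.
"""

from pathlib import Path

from pcrnet import cause_effect_table, default_catalog
from pcrnet.io import load_study

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    if not (data / "frequencies.csv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    catalog = default_catalog()
    records = load_study(data / "frequencies.csv", data / "pcr.csv", catalog)

    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    table = cause_effect_table(records, catalog)
    table.to_csv(out / "cause_effect_table.csv")

    sig = table[table["significant"]]
    print(f"scored {len(records)} participants; "
          f"{len(sig)} of {int(table['defined'].sum())} defined contrasts "
          f"survive the Holm correction")
    if len(sig):
        causes = sig[sig["t_EC"] > 0].sort_values("t_EC", ascending=False)
        effects = sig[sig["t_EC"] < 0].sort_values("t_EC")
        if len(causes):
            print("perceived predominantly as causes (C > E):")
            print(causes[["abbreviation", "C_mean", "E_mean", "t_EC", "d_EC"]]
                  .head(5).to_string())
        if len(effects):
            print("perceived predominantly as effects (E > C):")
            print(effects[["abbreviation", "C_mean", "E_mean", "t_EC", "d_EC"]]
                  .head(5).to_string())
    print(f"table -> {out / 'cause_effect_table.csv'}")


if __name__ == "__main__":
    main()
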