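"""Clonogenic survival: plating efficiency and surviving fractions.

Turns the simulated colony-count table into PE/SF per (dose, GNP)
condition with replicate means ± SD.

Run after 01_simulate.py:  python analysis/05_survival.py
"""

from pathlib import Path

import pandas as pd

from irifkit.viability import aggregate_replicates, survival_table, surviving_fraction

SIM = Path("results/simulated")
OUT = Path("results")


def main() -> None:
    counts = pd.read_csv(SIM / "colony_counts.csv")
    table = survival_table(counts)
    table.to_csv(OUT / "survival.csv", index=False)
    print(table.to_string(index=False))

    # per-experiment SF replicates -> mean +- SD, as survival curves report
    pe = table.loc[(table.dose_Gy == 0) & (~table.gnp), "PE_pct"].iloc[0]
    per_exp = (
        counts.groupby(["dose_Gy", "gnp", "experiment"])
        .agg(colonies=("colonies", "mean"), seeded=("seeded", "mean"))
        .reset_index()
    )
    per_exp["SF_pct"] = [
        surviving_fraction(c, s, pe) for c, s in zip(per_exp["colonies"], per_exp["seeded"])
    ]
    spread = aggregate_replicates(per_exp, value="SF_pct", by=["dose_Gy", "gnp"])
    spread.to_csv(OUT / "survival_replicates.csv", index=False)
    print(spread.to_string(index=False))


if __name__ == "__main__":
    main()
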