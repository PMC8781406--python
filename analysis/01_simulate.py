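"""Simulate the study's raw data at desk scale.

Writes, under results/simulated/:
  * two-channel 3D stacks (TIFF + sidecar) for a small irradiated cell
    population per condition (GNP- / GNP+ emulated as two seeds and a
    shifted G2 fraction, the mechanism the cohort analysis probes),
  * the ground-truth focus tables,
  * SMLM localization tables (clustered gamma-H2AX-like vs CSR patterns),
  * a clonogenic colony-count table.

Run from the repository root:  python analysis/01_simulate.py
"""

import json
from pathlib import Path

import numpy as np

from irifkit import synthetic as syn
from irifkit.stack_io import write_orte, write_stack

OUT = Path("results/simulated")
N_CELLS = 4          # per condition; desk-scale stand-in for 100-200 cells
CONDITIONS = [
    # (label, dose Gy, G2 fraction): GNP+ gets the enlarged G2 subpopulation
    ("gnp0_2Gy", 2.0, 0.25),
    ("gnp1_2Gy", 2.0, 0.35),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []
    for label, dose, g2 in CONDITIONS:
        cells, truth = syn.generate_population(
            n_cells=N_CELLS, dose=dose, focus_rate_per_Gy=4.0, g2_fraction=g2,
            background_rate=0.5, seed=abs(hash(label)) % 2**31,
        )
        truth.to_csv(OUT / f"truth_{label}.csv", index=False)
        for cell_id, (nucleus, foci) in enumerate(cells, start=1):
            stack, focus_truth = syn.generate_nucleus_stack(
                [nucleus], foci, seed=cell_id
            )
            path = OUT / f"stack_{label}_cell{cell_id:02d}.tif"
            write_stack(stack, path)
            focus_truth.to_csv(path.with_suffix(".truth.csv"), index=False)
            manifest.append({"condition": label, "cell_id": cell_id, "stack": path.name})
        print(f"{label}: {N_CELLS} cells, mean true count "
              f"{truth['n_foci'].mean():.1f} (G2 fraction {g2})")

    for label, bg in [("clustered", 0.1), ("csr", 1.0)]:
        for seed in range(5):
            orte = syn.generate_smlm_pattern(
                syn.PointPatternSpec(background_fraction=bg, seed=seed)
            )
            write_orte(orte, OUT / f"orte_{label}_{seed}.csv")
    print("SMLM: 5 clustered + 5 CSR localization tables")

    rng = np.random.default_rng(55)
    rows = ["dose_Gy,gnp,seeded,colonies,experiment,well"]
    sf_true = {0.0: 1.0, 1.0: 0.8, 2.0: 0.55, 4.0: 0.18}
    for dose, sf in sf_true.items():
        for gnp in (False, True):
            scale = 0.93 if (gnp and dose > 0) else 1.0  # mild radiosensitization
            for exp in range(3):
                for well in range(3):
                    colonies = rng.poisson(300 * 0.5 * sf * scale)
                    rows.append(f"{dose},{gnp},300,{colonies},{exp},{well}")
    (OUT / "colony_counts.csv").write_text("\n".join(rows) + "\n")
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print(f"clonogenic counts for {len(sf_true)} doses x 2 GNP conditions -> {OUT}")


if __name__ == "__main__":
    main()
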