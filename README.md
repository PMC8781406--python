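# irifkit

Multiscale quantification of radiation-induced DNA double-strand-break (DSB)
repair in cancer cells, built around the analysis chain used in
gold-nanoparticle radiosensitization studies of SkBr3 breast-carcinoma cells:

* **Microscale** — detection and morphometry of γH2AX/53BP1 repair foci
  (IRIFs, ionizing-radiation-induced foci) in two-channel 3D confocal stacks.
  A focus only counts as a DSB when both markers coincide: each channel is
  min–max normalized per nucleus, the *colocalization image* is their
  voxel-wise product, foreground comes from 3D **maximally stable extremal
  regions** (MSER) of that product, proposal seeds are prominence-filtered
  local maxima, and individual foci are carved out by a **seeded watershed**.
  Nuclei are segmented from the counterstain with an anisotropy-aware
  distance transform + watershed instance split.
* **Nanoscale** — Ripley point-to-point distance-frequency analysis of
  single-molecule localization microscopy (SMLM) coordinate tables
  ("orte matrices"): blinking-event merging within the localization
  precision, per-z-section tag counts, pairwise distance-frequency curves,
  and explicit calling of the intra-cluster peak (position ≈ typical
  intra-cluster distance, width ≈ cluster diameter, area ≈ relative
  in-cluster density; complete spatial randomness gives a linear small-r
  curve and no peak).
* **Population scale** — cohort statistics with a normality-gated test
  protocol (Shapiro–Wilk → Student/Welch t or Mann–Whitney), 1.5×IQR
  condition summaries, a two-component Poisson mixture resolving the G1/G2
  focus-count subpopulations (G2 cells carry roughly twice the G1 count),
  and clonogenic-assay arithmetic (plating efficiency PE, surviving
  fraction SF).

No microscopy data ships with the package: `irifkit.synthetic` renders
confocal-like nuclei with ground-truth foci (Gaussian blobs, Poisson +
read noise, controllable channel offset as a colocalization dial) and
simulates clustered (Neyman–Scott) vs CSR localization patterns, so every
stage is testable from scratch.

## Worked example

```python
from irifkit import synthetic as syn
from irifkit.nucseg import segment_nuclei
from irifkit.irif import detect_foci
from irifkit.features import extract_features

(nucleus, foci), = syn.generate_benchmark_population(
    n_cells=1, n_foci=10, min_separation_um=1.0, seed=11)
stack, truth = syn.generate_nucleus_stack([nucleus], foci, seed=42)

nuclei = segment_nuclei(stack)               # counterstain -> instances
seeds, labels, coloc = detect_foci(stack, nuclei)
focus_table, nucleus_table = extract_features(stack, nuclei, labels)
print(nucleus_table)
```

prints

```
   nucleus_id  n_foci  nucleus_volume_um3  occupied_fraction_pct  coloc_pearson
0           1      10            78.00195               8.906402       0.923103
```

— all 10 rendered foci are recovered, they occupy 8.9% of the 78 µm³
nucleus, and the Pearson colocalization of the two channels over the focus
voxels is 0.92 (the blobs were rendered with zero channel offset; the
value is below 1 only because of shot noise).

On the nanoscale side:

```python
from irifkit.synthetic import PointPatternSpec, generate_smlm_pattern
from irifkit.smlm import curve_from_orte, characterize_peaks

orte = generate_smlm_pattern(PointPatternSpec(cluster_sigma_nm=25.0, seed=0))
peak = characterize_peaks(curve_from_orte(orte))
print(peak.peak_position_nm, peak.peak_width_nm)   # 35.0  64.4
```

a 25-nm Neyman–Scott pattern yields an intra-cluster distance peak at
35 nm (the intra-cluster pairwise-distance law is Rayleigh with scale
σ√2 ≈ 35 nm) with a ~64 nm full width — well below the 150 nm scale
characteristic of γH2AX repair nanoclusters — while CSR patterns yield no
peak.

## Analysis scripts

The `analysis/` directory holds numbered drivers that replay the whole
study on synthetic data and write their tables under `results/`:

1. `01_simulate.py` — render the cell population, SMLM tables, colony counts
2. `02_detect_foci.py` — segmentation + focus detection + morphometry
3. `03_cohort_stats.py` — condition summaries, group tests, G2 mixture, PCA
4. `04_smlm_ripley.py` — blinking merge, tag counts, curves, peak calls, overlay
5. `05_survival.py` — PE/SF tables with replicate means ± SD

Run them in order from the repository root. Step 3, for example, reports
the two-component Poisson mixture on 500 simulated per-cell counts as
`mu_G1 = 10.29, mu_G2 = 20.67, ratio = 2.01` against the construction
value of 2.0.

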