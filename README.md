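# cytolaminar

Quantitative laminar cytoarchitecture for comparative neuroanatomy: given
calibrated grayscale images of Nissl-stained cortical strips (or pre-measured
cell tables), the package segments stained cell bodies, measures per-cell
descriptors in three domains — **size** (area, perimeter), **shape**
(circularity, solidity, extent, inverse aspect ratio) and **density** (number
of neighbouring cells within a 50 µm radius) — stratifies them into cortical
layers L1–L6, and compares groups of specimens (species, phylogenetic
clades, eye-position classes, …) with a nonparametric permutation framework.
A synthetic cortical-column generator with full ground truth makes every
stage testable without histological material.

It is written for comparative neuroanatomists and quantitative histologists
who need laminar morphometry with honest small-sample inference: specimen
counts per species are tiny, distributions are skewed, and parametric
ANOVA assumptions are untenable.

## The statistical core

Per-layer median descriptors are modelled as a one-way layout

```
Y_ij = μ + τ_j + ε_ij
```

where the group effect τ_j and the group scale σ²_j may both differ under
the alternative, and nothing is assumed about the error distribution.
Each variable is tested by permutation under exchangeability with a joint
location+scale statistic; variables are combined within each domain, and
domains into a global test, by nonparametric combination (NPC) with the
Fisher combining function `−2 Σ log p`, evaluated on synchronized
permutations so arbitrary dependence between descriptors is handled
exactly. Pairwise group comparisons use permutations constrained to the
two groups' rows, with Shaffer's logically-constrained step-down
correction. p-values follow the add-one convention `(1 + #{T* ≥ T})/(B+1)`
and switch to exhaustive enumeration whenever the number of distinct
relabelings is at most B, making small-sample p-values exact.

## Worked example

`examples/demo.yaml` defines a three-group synthetic study (4 specimens per
group) in which the `lateral` group has one-third the cell density of the
others — the direction of the density deficit reported for lateral-eyed
species. Run the whole pipeline:

```sh
cytolaminar demo -c examples/demo.yaml
```

which generates the specimens, measures them, runs the inference at
B = 999 permutations, and prints per-layer p-values:

```
L1: global_p=0.0540 size=0.5120 shape=0.2740 density=0.0220
L2: global_p=0.0280 size=0.3400 shape=0.5680 density=0.0070
L3: global_p=0.0110 size=0.2200 shape=0.2190 density=0.0050
L4: global_p=0.2480 size=0.8380 shape=0.8170 density=0.0330
L5: global_p=0.0270 size=0.1970 shape=0.4470 density=0.0090
L6: global_p=0.0050 size=0.3720 shape=0.0050 density=0.0230
```

The density domain rejects in every layer (p ≤ 0.033) — the planted
contrast — while size stays null; the occasional shape/global rejection
(L6) is the expected small-sample noise at these specimen counts.
`demo_out/` then contains `cells.csv` (one row per segmented cell),
`layer_medians.csv` (the observation matrix), `results.csv`/`results.json`
(partial, domain, global and Shaffer-adjusted pairwise p-values), laminar
profile plots with `*`/`**` markers at p ≤ 0.05 / 0.01, and a
`manifest.json` with the resolved config and SHA-256 hashes of every
artifact — identical seed and config reproduce identical bytes.

The stages are also available separately (`simulate`, `measure`, `infer`)
and as a library: `generate_group_study`, `segment_image`,
`build_cell_table`, `summarize_by_layer`, `run_grouping_analysis`.

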