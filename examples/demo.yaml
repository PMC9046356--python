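# Three synthetic groups; the "lateral" group carries a 3x density deficit.
seed: 42
outdir: demo_out
groups:
  - id: frontal
  - id: wide
  - id: lateral
    density_multiplier: 0.33
n_specimens_per_group: 4
n_permutations: 999
use_truth_tables: true
render: false
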