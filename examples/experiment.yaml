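# Full phantom-epistasis density sweep at desk scale.
# All keys are optional; defaults reproduce the shipped study conditions.
simulator:
  n_lines: 500
  p_sites: 30000
  chrom_length_bp: 10000000
densities: [100, 1000, 10000]
kinds: [G, H, K]
fixed_effects: [mu]
maf_threshold: 0.01
h2: 0.6
n_traits: 5
causal_anchor_density: 1000
cv:
  folds: 5
  replicates: 5
n_boot: 5000
decomposition:
  n_samples: 10000
  max_order: 6
master_seed: 1
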