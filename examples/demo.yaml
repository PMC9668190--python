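seed: 42
genome:
  chrom_lengths: [100000]
  n_genes: 25
  gene_length: [1000, 2000]
  intergenic_fraction: 0.6
effects:
  classes:
    sex_required: {count: 4, sex_factor: 0.05}
    growth_advantage: {count: 1, factor: 2.0}
library:
  n_clones: 2000
  depth: 80000
  pcr_mean_copies: 1.5
  runs: 2
test:
  alpha: 0.05
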