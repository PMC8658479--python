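# End-to-end demo: two simulated two-group contrasts (an aging contrast at
# room temperature and a cold-exposure contrast in young animals), the
# integrative resampling DEG statistic, pairwise overlap tables, and
# ORA + preranked GSEA against the bundled demo gene-set collection.
# All paths are relative to this file.
seed: 7
output_dir: ../scratch/demo

datasets:
  aging_rt:
    simulate:
      n_genes: 2000
      group_sizes: {old: 5, young: 5}
      de_fraction: 0.05
      de_log2fc: 2.0
      dispersion: 0.1
    contrast: {a: old, b: young}
  cold_young:
    simulate:
      n_genes: 2000
      group_sizes: {cold: 5, rt: 5}
      de_fraction: 0.05
      de_log2fc: 2.0
      dispersion: 0.1
    contrast: {a: cold, b: rt}

normalization:
  pseudocount: 1.0
  min_cpm: 1.0
  filter: true

deg:
  n_resamples: 1000
  alpha: 0.05
  adjust: BH

enrichment:
  gmt: ../examples/demo_sets.gmt
  n_perm: 2000
  min_size: 3
  max_size: 800
  p_cutoff: 0.05

gene_lists:
  # synthetic stand-in for a curated mitochondrial gene inventory
  mito_like: ../examples/synthetic_mito_like_list.txt
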