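# Demo run: pure simulation through every pipeline stage.
seed: 17
thresholds:
  lfc_min: 0.5
  fdr_max: 0.05
simulate:
  contrasts:
    n_genes: 1500
  gene_sets:
    n_sets: 25
    n_enriched: 5
    enriched_class: LS
  cohort:
    genes: 600
    group_sizes:
      - {genotype: WT, stage: early, n: 20}
      - {genotype: LKB1, stage: early, n: 10}
      - {genotype: SMARCA4, stage: early, n: 10}
      - {genotype: TP53, stage: early, n: 10}
      - {genotype: WT, stage: late, n: 15}
      - {genotype: LKB1, stage: late, n: 8}
    group_shifts:
      - {genotype: LKB1, stage: late, n_genes: 40, log2_shift: 2.0}
      - {genotype: LKB1, stage: early, n_genes: 40, log2_shift: 1.5}
enrich:
  min_hits: 4
  fdr_max: 0.05
  metric: jaccard
cohort:
  stage_dea: true
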