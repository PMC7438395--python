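# Demo pipeline configuration: the default study conditions at a bootstrap
# depth that keeps the full run under a minute.  Run with:
#   chemohf run --config configs/demo.yaml --seed 7 --out demo_run
cohort:
  missing_rate: 0.0
composite:
  B: 20000
  level: carrier
assoc:
  case_group: hf_no_chemo
  control_group: chemo_no_hf
  covariates: [sex, antihtn]
twas:
  n_genes: 8
  snps_per_gene: 6
  panel_n: 159
  causal_gene: gene_00
  expression_noise_sd: 1.0
  expression_effect: -2.0
  covariates: [age, baseline_lvef, antihtn, pc1, pc2]
qc:
  n_duplicate_pairs: 22
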