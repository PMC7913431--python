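# Bundled synthetic-study configuration for an end-to-end run.
# Usage:  exonet run-all --config examples/run_config.yaml --outdir my_run
outdir: exonet_run
seed: 1
stages: [simulate, dea, candidates, select, network, validate]

simulate:
  tissue:                       # tissue RNA-seq cohort (counts)
    n_features_mrna: 1000
    n_features_mirna: 300
    n_tumor: 600
    n_control: 50
    n_planted_de: 60
    n_planted_key: 8
    planted_log2fc: 2.0
    baseline_mean: 100.0
    nb_dispersion: 0.2
  mirna:                        # tissue miRNA overrides
    n_planted_de: 30
    n_planted_key: 5
  exosomal:                     # serum exosome cohort (intensities)
    n_tumor: 88
    n_control: 11
    exo_noise_sd: 1.0
  n_sources: 3
  decoy_rate: 0.002
  clinical:
    hazard_log_hr: 0.6931471805599453   # ln 2 per expression tertile
    msi_log_odds: 1.0

dea:
  log2fc_cutoff: 1.0
  fdr_cutoff: 0.05
  low_expr_min_cpm: 1.0

candidates:
  strip_arm: false

select:
  B_mirna: 200                  # reference analysis scale: 1000
  B_mrna: 200                   # reference analysis scale: 10000
  n_folds: 10
  count_threshold: null         # default: strictly more than B/2
  n_lambda: 100
  lambda_min_ratio: 0.001

network:
  min_class: high
  mrna_hub_cutoff: 3

validate:
  n_boot: 500
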