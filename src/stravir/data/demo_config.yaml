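# Bundled demo: a small but complete longitudinal community.
# Sample structure mirrors the study design (24 samples: 2 RP, 11 AP, 11 RP);
# depth is scaled down so the full pipeline finishes in minutes on one CPU.
outdir: demo_run
seed: 7
community:
  n_bacteria: 5
  n_lytic_phages: 3
  n_prophages: 2
  n_samples: 24
  n_ap: 11
  n_rp: 13
  depth: 5000
  read_length: 150
  error_rate: 0.001
  unmapped_fraction: 0.005
substrain:
  min_depth: 5
  min_alt_frac: 0.2
  min_support: 1
stats:
  fdr: 0.05
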