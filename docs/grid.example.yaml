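# Example grid specification for `cnvassoc power --config grid.yaml`.
# Any omitted key falls back to the package default (shown here).
designs: [cohort, case_control]
frequencies: [0.05, 0.1, 0.2]
cnv_lengths: [10, 30, 50]
methods:
  - pipeline: marker
    setting: {transform: probit}
  - pipeline: marker_nopool
  - pipeline: cnv
    setting: {alpha_call: 0.01}
  - pipeline: oracle
alpha: 0.05
base_config:
  n_subjects: 1000     # subjects per replicate
  n_markers: 200       # markers per replicate (one genomic region)
  snr: 0.8             # spiked LRR shift in units of noise SD
  effect_size: 0.4     # cohort: carrier mean shift in phenotype SDs
  prevalence_f0: 0.01  # case-control: baseline disease risk
  relative_risk: 2.0   # case-control: penetrance = rr * f0
# n_replicates / n_permutations / base_seed come from --reps/--nperm/--seed
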