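# Small synthetic end-to-end configuration: two anchor genes with planted
# co-expression modules, six planted signatures (three positive, three
# negative), exponential survival driven by the first anchor and the
# angiogenesis-like signature.  Run with:
#   degsig run-all --config examples/synthetic_config.yaml --out out
out_dir: out
seed: 11
anchors: [JAG1, NOTCH1]
alpha: 0.75
sam:
  n_permutations: 300
  q_threshold: 0.05
  r_threshold: 0.2
  s0_method: median
  seed: 0
simulate:
  n_samples: 120
  n_background_genes: 300
  anchors: [JAG1, NOTCH1]
  module_size: 40
  target_rho: 0.5
  noise_sd: 1.0
  signatures:
    - {name: ANGIOGENESIS, size: 30, sign: 1, strength: 0.5}
    - {name: HYPOXIA, size: 30, sign: 1, strength: 0.5}
    - {name: KRAS_SIGNALING_UP, size: 30, sign: 1, strength: 0.5}
    - {name: MYC_TARGETS_V1, size: 30, sign: -1, strength: 0.5}
    - {name: E2F_TARGETS, size: 30, sign: -1, strength: 0.5}
    - {name: G2M_CHECKPOINT, size: 30, sign: -1, strength: 0.5}
  survival:
    baseline_hazard: 0.05
    coef_anchor: 0.7
    coef_signature: 0.7
    censoring_fraction: 0.2
combined_pairs:
  - [JAG1, ANGIOGENESIS]
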