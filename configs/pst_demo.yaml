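# Single-pair probabilistic selection demonstration: 0.9 vs 0.2, 10 trials.
task:
  kind: pst
  pairs: [[0.9, 0.2]]
  n_trials: 10
execution:
  seeds: [1]
  out_dir: runs/pst_demo
  snapshot_trials: [1, 2]
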