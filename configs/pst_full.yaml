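# Canonical three-pair probabilistic selection task: AB 80/20, CD 70/30, EF 60/40.
task:
  kind: pst
  pairs: [[0.8, 0.2], [0.7, 0.3], [0.6, 0.4]]
  n_trials: 60
execution:
  seeds: [1]
  out_dir: runs/pst_full
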