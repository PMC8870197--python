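# Instructed probabilistic selection: 0.9/0.2 with a misleading instruction
# biasing the worse (20%-rewarded) stimulus, 30 trials.
task:
  kind: instructed
  p_first: 0.9
  p_second: 0.2
  instructed: 1
  n_trials: 30
execution:
  seeds: [1]
  out_dir: runs/instructed
  snapshot_trials: [1, 2, 30]
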