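# Probabilistic reversal learning: 0.9/0.2 swapped every 20 trials, 100 trials.
task:
  kind: reversal
  p_first: 0.9
  p_second: 0.2
  block: 20
  n_trials: 100
execution:
  seeds: [1]
  out_dir: runs/reversal
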