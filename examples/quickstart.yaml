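# Minimal end-to-end plan: two policies x two seeds on a reduced dataset.
# Finishes in about a minute on one CPU core.
dataset:
  classes: 6
  train: 24
  test: 8
  size: 32
  cue_per_pair: 1
conditions:
  - name: snet
    policy: {kind: S}
    config: {epochs: 3, batch_size: 32}
    seeds: [0, 1]
  - name: bsnet
    policy: {kind: B+S, sigma: 4}
    config: {epochs: 3, batch_size: 32}
    seeds: [0, 1]
evaluations: [lowpass, shapebias]
master_seed: 0
output: quickstart_out
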