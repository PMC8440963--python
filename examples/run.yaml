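# Example configuration for `eegrefine run --config examples/run.yaml --out runs/demo`
source: simulate          # or set data_path to an EDF/GDF file or exchange dir
sim:
  n_trials_per_class: 40
  seed: 0
crop_seconds: 1.25
n_folds: 10
stages: 2                 # 1 = raw training only; >2 iterates the refinement
leaky: false              # true = select frequencies once on all data (leaks)
network:
  epochs: 30
  batch_size: 32
  learning_rate: 0.001
  dense_nodes: 32
selection:
  k_bad: 20
  m_good: 100
  sample_fraction: 0.1
  band: [0.5, 100.0]
filter:
  family: iir-notch
  q: 30.0
  min_gap: 1.0
gradcam_threshold: 0.35
gradcam_min_run: 64
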