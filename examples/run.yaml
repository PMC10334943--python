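# phenoforge end-to-end run configuration
seed: 42
output_dir: runs/demo
simulation:
  preset: validation_like
  n_persons: 20000
diagnostics:
  characterization_window: [31, 365]
evaluation:
  eval_sample_size: 10000
  n_bootstrap: 200
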