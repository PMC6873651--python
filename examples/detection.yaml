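# Sweep-vs-neutral detection on synthetic fixtures, desk scale.
# Run the stages in order:
#   sweepnet simulate  --config examples/detection.yaml --outdir run/
#   sweepnet images    --config examples/detection.yaml --outdir run/
#   sweepnet train     --config examples/detection.yaml --outdir run/
#   sweepnet predict   --config examples/detection.yaml --outdir run/
#   sweepnet summarize --config examples/detection.yaml --outdir run/
seed: 7
outdir: run

simulate:
  mode: fixture            # "command" writes an msms invocation instead
  n_replicates_per_class: 200
  n_haplotypes: 64
  target_sites: 96
  sweep_intensities: [0.0, 0.8]   # class 0 neutral, class 1 sweep
  core_width: 1.0          # footprint spans the window (strong recent sweep)

images:
  polarization: major-minor
  maf_threshold: 0.01
  sorting: rows_and_columns
  target_height: 64
  target_width: 64
  test_fraction: 0.1
  validation_fraction: 0.1

labels:
  kind: categorical        # gaussian / perturbed for soft targets
  n_classes: 11            # S range binning used by the predict stage

train:
  conv_filters: [32, 32, 32]
  kernel_size: 3
  dense_units: null        # double-sorted images need no dense layer
  learning_rate: 0.001
  n_epochs: 6
  batch_size: 32
  schedule: epochs         # or "one-pass" with n_chunks

predict:
  alpha: 0.05
  n_samples: 100000
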