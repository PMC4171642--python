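# Full pipeline on a simulated cohort: `cafsig run --config examples/pipeline.yaml`
outdir: cafsig_out
seed: 1
simulate: true
synthetic:
  n_samples: 135
stability:
  n_iterations: 200
run_discovery: true
run_validation: true
run_posttest: true
make_plots: false
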