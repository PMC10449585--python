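# Demonstration run: a 304-patient phantom cohort with a planted
# visceral-adiposity effect (VATI) and a planted radiomics effect on the
# maximum visceral-fat HU, analysed with a scaled-down bootstrap
# (B=100, pool cutoff 50).
#
#   bodyrad run-all --config examples/demo.yaml
cohort:
  n_patients: 304
  seed: 42
  image_shape: [96, 96]
  planted_betas:
    vati: 0.6
    VAT_original_firstorder_Maximum: 1.2
selection:
  B: 100
  pool_cutoff: 50
eval_bootstrap: 200
out_dir: scratch/demo
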