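# 21-day media-drift assay, runnable with:
#   activelight simulate-assay --config examples/temporal_assay.yaml --out-dir out/
scenario: temporal_media
days: 21
seed: 1
scene:
  n_worms: 5
controller:
  k_p: 0.9
  ref: 48
  T_sa: 0.11
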