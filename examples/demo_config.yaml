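# Demo run: six synthetic chambers spanning the observed net-production
# range, one microprofile, the artifact screen, a synthetic voltage survey
# and the comparative statistics.  Runs in well under two minutes.
seed: 1
output_dir: demo_results
chamber:
  log_interval: 30.0   # coarser logging keeps the demo quick
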