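# Full analysis configuration.  Defaults reproduce the reference protocol:
# order-4 Butterworth at 7 Hz (zero phase) on the six channels, SampEn with
# m=3 and r=0.2 on the COP increment series, alpha = 0.05.
manifest: cohort/manifest.csv
out_dir: results
filter:
  order: 4
  cutoff_hz: 7.0
  zero_phase: true
sampen:
  m: 3
  r: 0.2
alpha: 0.05
filter_target: channels
seed: 0
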