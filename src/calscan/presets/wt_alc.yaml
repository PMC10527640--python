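# Wild-type, 2-month alcohol-exposed group.
#
# tau_decay_ms and the per-pacing-frequency wave rates are the published
# group means for this cohort; the remaining parameters are generator
# defaults shared with wt_sham (see docs/methods.md).  Leak/load ground
# truths are representative (raised vs sham), not published numbers.
name: wt_alc
kinetics:
  amplitude_dff0: 0.8
  rise_ms: 3.0
  tau_decay_ms: 55.9
  f0_counts: 500.0
  diastolic_dff0: 0.0
waves:
  rate_per_mm_s: {0: 0.0, 8: 10.20, 10: 15.38, 20: 24.05}
  velocity_mm_s: 2.0
  amplitude_dff0: 0.6
  extent_um: 150.0
  duration_ms: 60.0
noise:
  shot_scale: 1.0
  drift_per_s: 0.0
  bleach_tau_s: .inf
leak_dff0: 0.25
load_dff0: 2.0
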