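# Wild-type sham (saline) group.
#
# tau_decay_ms and the per-pacing-frequency wave rates are the published
# group means for this cohort; every other number (amplitude, rise time,
# baseline counts, noise, wave geometry) is a representative default of the
# synthetic generator, documented in docs/methods.md, and is NOT a
# published value.
name: wt_sham
kinetics:
  amplitude_dff0: 0.8
  rise_ms: 3.0
  tau_decay_ms: 30.03
  f0_counts: 500.0
  diastolic_dff0: 0.0
waves:
  # waves/(mm*s) keyed by pacing frequency in Hz; 0 = intrinsic sinus rhythm
  rate_per_mm_s: {0: 0.0, 8: 1.99, 10: 4.84, 20: 7.59}
  velocity_mm_s: 2.0
  amplitude_dff0: 0.6
  extent_um: 150.0
  duration_ms: 60.0
noise:
  shot_scale: 1.0
  drift_per_s: 0.0
  bleach_tau_s: .inf
leak_dff0: 0.10
load_dff0: 1.5
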