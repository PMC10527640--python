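# Cardiac-specific dominant-negative JNK2 transgenic, 2-month alcohol.
#
# Wave rates are the published group means.  The decay constant for this
# group was reported only as "normalized to control levels" with no printed
# number, so the sham mean is adopted (documented in docs/methods.md).
name: jnk2dn_alc
kinetics:
  amplitude_dff0: 0.8
  rise_ms: 3.0
  tau_decay_ms: 30.03
  f0_counts: 500.0
  diastolic_dff0: 0.0
waves:
  rate_per_mm_s: {0: 0.0, 8: 2.71, 10: 3.11, 20: 7.34}
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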