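# Package-default generator presets.  These are thetadyn's own defaults:
# the directions of the planted effects follow the phenomenology the
# pipeline is built to measure (hippocampal theta/delta imbalance, elevated
# cross-frequency coupling and inter-area theta hypersynchrony in the
# hyperglycemic group), but every number here is a package choice, not a
# measured quantity.
cohort:
  n_subjects: {control: 3, STZ: 5}
  n_sessions_per_subject: 4
  n_trials: 30
  delay_range_s: [5, 45]
  accuracy:
    control: {short: 0.90, long: 0.85}
    STZ: {short: 0.85, long: 0.60}

phenotypes:
  control:
    HPC:
      theta_amp: 1.0
      delta_amp: 0.35
      pac_depth: {delta_theta: 0.05, theta_slow_gamma: 0.15, theta_fast_gamma: 0.10}
      speed_coupling: {theta: 1.0, delta: -0.8}
      coherence_mix: 0.45
      coherence_outcome_shift: -0.25
      coherence_long_delay_mult: 1.0
      noise_exponent: 1.0
      noise_amp: 0.5
    ACC:
      theta_amp: 0.80
      delta_amp: 0.60
      pac_depth: {delta_theta: 0.05, theta_slow_gamma: 0.12, theta_fast_gamma: 0.08}
      speed_coupling: {theta: 0.8, delta: -0.7}
      coherence_mix: 0.45
      coherence_outcome_shift: -0.25
      coherence_long_delay_mult: 1.0
      noise_exponent: 1.3
      noise_amp: 0.5
  STZ:
    HPC:
      theta_amp: 0.55
      delta_amp: 0.85
      pac_depth: {delta_theta: 0.30, theta_slow_gamma: 0.45, theta_fast_gamma: 0.30}
      speed_coupling: {theta: 1.0, delta: -0.25}
      coherence_mix: 0.60
      coherence_outcome_shift: 0.25
      coherence_long_delay_mult: 1.5
      noise_exponent: 1.0
      noise_amp: 0.5
    ACC:
      theta_amp: 0.85
      delta_amp: 0.70
      pac_depth: {delta_theta: 0.08, theta_slow_gamma: 0.35, theta_fast_gamma: 0.10}
      speed_coupling: {theta: 1.2, delta: -0.30}
      coherence_mix: 0.60
      coherence_outcome_shift: 0.25
      coherence_long_delay_mult: 1.5
      noise_exponent: 1.3
      noise_amp: 0.5
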