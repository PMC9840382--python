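# Default generative parameters for synthetic cohorts.
#
# These values are FABRICATED: they are chosen so that a default cohort
# displays the qualitative structure the analyses expect (risky choice falling
# across punishment-probability blocks with a steeper fall in aged subjects,
# more omissions and lower progressive-ratio breakpoints in aged subjects, no
# group difference in learning rate, choice stochasticity, or flinch
# threshold).  They are not estimates from any animal data.  Means/SDs are for
# per-subject Gaussian draws, clipped to each field's valid range.
#
# Units: shock_aversion_kappa, utility units per unit punishment probability;
# softmax_beta_rdt, inverse temperature on the utility scale; omission_prob,
# probability per trial; rl_alpha/rl_beta, delta-rule learning rate and
# softmax inverse temperature; pr_base_rate, lever presses per minute;
# pr_giving_up_hazard, quit hazard per minute; threshold_mu / slope_sigma,
# microamps (flinch psychometric location / spread); locomotor_rate, activity
# counts per inter-trial interval; latency_scale, multiplier on response
# latencies.
young:
  shock_aversion_kappa: {mean: 1.2, sd: 0.15}
  softmax_beta_rdt: {mean: 2.5, sd: 0.3}
  omission_prob: {mean: 0.017, sd: 0.010}
  rl_alpha: {mean: 0.45, sd: 0.15}
  rl_beta: {mean: 3.0, sd: 1.0}
  pr_base_rate: {mean: 30.0, sd: 8.0}
  pr_giving_up_hazard: {mean: 0.10, sd: 0.03}
  threshold_mu: {mean: 150.0, sd: 20.0}
  slope_sigma: {mean: 20.0, sd: 5.0}
  locomotor_rate: {mean: 9.7, sd: 2.0}
  latency_scale: {mean: 1.0, sd: 0.15}
aged:
  shock_aversion_kappa: {mean: 2.2, sd: 0.30}
  softmax_beta_rdt: {mean: 2.5, sd: 0.3}
  omission_prob: {mean: 0.086, sd: 0.030}
  rl_alpha: {mean: 0.45, sd: 0.15}
  rl_beta: {mean: 3.0, sd: 1.0}
  pr_base_rate: {mean: 18.0, sd: 6.0}
  pr_giving_up_hazard: {mean: 0.25, sd: 0.08}
  threshold_mu: {mean: 150.0, sd: 20.0}
  slope_sigma: {mean: 20.0, sd: 5.0}
  locomotor_rate: {mean: 6.1, sd: 1.5}
  latency_scale: {mean: 1.5, sd: 0.20}
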