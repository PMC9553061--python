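# Versioned default parameters for all filters and experiments.
# Units: time in seconds unless a key is suffixed _ms; variances in s^2;
# sigma in phase/sqrt(s); rates in events/s.
filter:
  dt: 0.001
  sigma: 0.02
  event_noise_scale: 0.02      # eta_e, SD of onset perturbation (s)
  phase_noise_scale: 0.03      # eta_mu, scale of sqrt(dt) perturbation on d(mu)
  initial_mean: 0.0
  initial_variance: 0.0002
templates:
  background_rate: 0.01        # lambda_0
  strength: 0.02               # lambda_i for hand-built two-interval templates
  variance_even: 0.0001        # v_i of the 1:1 template (precise)
  variance_uneven: 0.002       # v_i of the 2:1 and 4:3 templates (imprecise)
bank:
  max_strength: 1.0            # lambda_max in lambda^m = p0^m * lambda_max
  max_variance: 0.0005         # v_max in v^m = (1 - p0^m) * v_max
  restriction_size: 22         # N nearest templates kept per stimulus
  constant_strength: 0.02      # used when strengths/variances are held constant
  constant_variance: 0.001
experiment1:
  period_ms: 1000.0
  repetitions: 25
  runs_per_condition: 26
experiment2:
  total_ms: 2000.0
  min_interval_ms: 300.0
  resolution_ms: 10.0
experiment3:
  trials: 2000
  iterations: 5
  repetitions: 10
mixture:
  bootstrap: 250
  max_iter: 200
  tol: 1.0e-8
fixtures:
  hierarchical_concentration: 1.2
  flattened_concentration: 0.4
  jitter: 0.05
  planted_sd_ms: 60.0
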