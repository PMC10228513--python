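# Built-in simulation scenarios.
#
# The running example is a glycemic-control trial: L0 is baseline HbA1c (%),
# L1 interim HbA1c, the ICE is initiation of rescue medication, and Y is
# final HbA1c.  Rescue uptake depends strongly on the interim marker, which
# also drives the outcome, so the interim marker confounds the ICE; an
# analysis that simply discards patients after rescue without adjustment is
# biased, which is the situation the adjustment methods exist for.
#
# rescue_k1    one ICE timepoint, stochastic (logistic) rescue mechanism
# rescue_k2    two ICE timepoints, stochastic at both
# threshold_k1 deterministic protocol rule: rescue iff interim HbA1c > 8.3
#              (positivity violated by design)
# null_k1      no treatment effect on anything (for null-recovery checks)

rescue_k1:
  n: 1000
  k_ice_times: 1
  rand_prob: 0.5
  l0: [{mean: 8.0, sd: 1.0}]
  l1:
    - intercept: 1.2
      coef: {L0: 0.85, A0: -0.5}
      sd: 0.7
  ice1:
    kind: logistic
    intercept: -14.0
    coef: {L1: 1.7}
  y:
    intercept: 0.6
    coef: {L0: 0.35, L1: 0.65, A0: -0.45, A1: -1.2}
    sd: 0.5

rescue_k2:
  n: 1000
  k_ice_times: 2
  rand_prob: 0.5
  l0: [{mean: 8.0, sd: 1.0}]
  l1:
    - intercept: 1.2
      coef: {L0: 0.85, A0: -0.5}
      sd: 0.7
  ice1:
    kind: logistic
    intercept: -14.0
    coef: {L1: 1.7}
  l2:
    - intercept: 0.8
      coef: {L0: 0.35, L1: 0.55, A0: -0.35, A1: -0.4}
      sd: 0.6
  ice2:
    kind: logistic
    intercept: -13.5
    coef: {L2: 1.6}
  y:
    intercept: 0.5
    coef: {L0: 0.25, L1: 0.3, L2: 0.55, A0: -0.35, A1: -0.8, A2: -0.7}
    sd: 0.5

threshold_k1:
  n: 1000
  k_ice_times: 1
  rand_prob: 0.5
  l0: [{mean: 8.0, sd: 1.0}]
  l1:
    - intercept: 1.2
      coef: {L0: 0.85, A0: -0.5}
      sd: 0.7
  ice1:
    kind: threshold
    var: L1
    threshold: 8.3
  y:
    intercept: 0.6
    coef: {L0: 0.35, L1: 0.65, A0: -0.45, A1: -1.2}
    sd: 0.5

null_k1:
  n: 1000
  k_ice_times: 1
  rand_prob: 0.5
  l0: [{mean: 8.0, sd: 1.0}]
  l1:
    - intercept: 1.2
      coef: {L0: 0.85}
      sd: 0.7
  ice1:
    kind: logistic
    intercept: -14.0
    coef: {L1: 1.7}
  y:
    intercept: 0.6
    coef: {L0: 0.35, L1: 0.65, A1: -1.2}
    sd: 0.5
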