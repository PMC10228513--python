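"""Certify that 'missing data' and 'causal inference' estimators coincide.

The factored-normal MLE under MAR (fitted after deleting post-ICE outcomes)
is algebraically identical to the G-formula estimator whose outcome model is
fitted among ICE-free patients, with matched arm pooling — on every dataset,
not merely on average.  The certificate below evaluates both estimators and
prints the gap, which sits at double-precision rounding error.
"""

import hypoestimand as he

data = he.simulate_trial(he.builtin_scenario("rescue_k2", n=800, seed=42))

for pooling in ("per_arm", "pooled"):
    report = he.certify_equivalence(data, he.EstimatorSpec(arm_pooling=pooling))
    print(report)
    print()

# negative control: a mismatched pairing is NOT covered by the identity
report = he.certify_equivalence(
    data, gformula_pooling="per_arm", mle_pooling="pooled", strict=False
)
print(report)
print(
    "\nMatched pairings agree to ~1e-15 (the identity is exact algebra);\n"
    "the mismatched pairing compares genuinely different estimators and the\n"
    "gap is orders of magnitude larger."
)
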