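"""Simulate a rescue-medication trial and estimate the hypothetical effect.

The scenario mimics a glycemic-control trial: interim HbA1c (L1) drives both
rescue initiation (the intercurrent event, A1) and final HbA1c (Y).  The
target is the treatment effect had rescue been prevented, E(Y^{1,0}) −
E(Y^{0,0}), which the simulator knows exactly.
"""

import hypoestimand as he

scenario = he.builtin_scenario("rescue_k1", n=2000, seed=7)
data = he.simulate_trial(scenario)
truth = he.true_estimand(scenario, he.EstimandSpec(contrast=True))

print(f"simulated {data.n} patients; rescue rate {data.df['A1'].mean():.1%}")
print(f"true hypothetical effect (closed form): {truth:.4f}\n")

for method in ("gformula", "ipw", "mle_mar", "mi", "naive"):
    spec = he.EstimatorSpec(
        method=method,
        arm_pooling="pooled" if method == "ipw" else "per_arm",
        n_imputations=200,
        seed=11,
    )
    res = he.estimate_contrast(data, spec)
    print(f"{method:8s} estimate {res.point:+.4f}   (error {res.point - truth:+.4f})")

boot = he.bootstrap_ci(data, he.EstimatorSpec(), B=200, seed=5)
print(f"\nG-formula bootstrap SE {boot.se:.4f}, 95% CI ({boot.ci[0]:.4f}, {boot.ci[1]:.4f})")
print(
    "All adjusted estimators sit close to the truth; the naive ICE-free\n"
    "difference is visibly off because rescue uptake depends on the interim\n"
    "marker, which also predicts the final outcome."
)
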