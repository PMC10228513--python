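"""A small replication study: bias, SD, bootstrap SE and coverage.

Replays the confounded rescue scenario and the null scenario over simulated
trials, comparing the adjusted estimators against the naive ICE-free
contrast.  Coverage is evaluated against the exact simulator truth, so a
biased estimator shows up as under-coverage.  (Desk-scale settings; raise
n_reps/bootstrap_B for smoother numbers.)
"""

import hypoestimand as he

config = he.StudyConfig(
    scenarios=(
        he.builtin_scenario("rescue_k1", n=400),
        he.builtin_scenario("null_k1", n=400),
    ),
    estimators=(
        ("gformula", he.EstimatorSpec()),
        ("gformula_all_data", he.EstimatorSpec(model_scope="all_data")),
        ("ipw", he.EstimatorSpec(method="ipw", arm_pooling="pooled")),
        ("mle_mar", he.EstimatorSpec(method="mle_mar")),
        ("naive", he.EstimatorSpec(method="naive")),
    ),
    n_reps=40,
    bootstrap_B=60,
    seed=2024,
)

results = he.run_simulation_study(config)
print(he.format_results_table(results))
print(
    "\nReading the table: 'bias' compares the mean estimate with the exact\n"
    "truth (its Monte-Carlo SE is 'mc_se_bias').  The adjusted estimators\n"
    "are unbiased within Monte-Carlo error; the naive contrast is biased in\n"
    "the confounded scenario and its coverage drops well below 95%.  At this\n"
    "desk scale the all_data-vs-ICE-free SD difference is within noise; run\n"
    "~1000 replicates to see the all_data variant's precision advantage\n"
    "separate cleanly."
)
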