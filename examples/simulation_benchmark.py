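"""A miniature estimator benchmark on a 6-component mixture.

Simulates replicates from a bidirectional truth and compares the
unpenalized single-direction estimator (m1), its joint-validation
variant (m2), quantile g-computation (m3) and the penalized two-index
model (m4), printing median error and weight-selection rates per
direction.  Uses a small 6-component mixture so it runs in seconds;
see the README for the full 38-component configuration.
"""

from wqs2i import (Scenario, TruthSpec, exchangeable_correlation,
                   run_benchmark)

truth = TruthSpec(beta1p=0.6, beta1n=-0.6,
                  wp=[0.6, 0.4, 0, 0, 0, 0], wn=[0, 0, 0.5, 0.5, 0, 0])
scenario = Scenario(corr=exchangeable_correlation(6, 0.3), truth=truth,
                    n=800, n_replicates=5, H=8, B=10, lambda_policy=0.0)

result = run_benchmark(scenario, methods=("m1", "m2", "m3", "m4"), seed=3)
print(result.metrics.to_string(index=False))
# median_error is the median over replicates of (estimate - truth);
# sensitivity / specificity report how often true-support components
# exceed the 1/c weight threshold and null components stay below it.
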