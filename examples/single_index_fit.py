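"""Single-index WQS regression on a synthetic exposure mixture.

Builds a small dataset where two of five correlated exposures raise the
outcome, runs the two-step WQS estimator (bootstrap ensemble on a
training split, GLM on the validation split) and prints the index
coefficient and the estimated weights.
"""

import numpy as np

from wqs2i import MixtureData, quantize_columns, fit_wqs

rng = np.random.default_rng(1)
n, c = 1500, 5
L = np.linalg.cholesky(0.3 + 0.7 * np.eye(c))
X = rng.standard_normal((n, c)) @ L.T
Q = quantize_columns(X, q=4)
# truth: components 1 and 2 act with weights 0.7 / 0.3
y = 0.6 * (0.7 * Q[:, 0] + 0.3 * Q[:, 1]) + rng.normal(0, 1.0, n)
data = MixtureData(y=y, Q=Q, q=4)

ensemble, final = fit_wqs(data, direction="positive", lam=0.0, B=50, seed=7)

print(f"index coefficient beta1 = {final.coef('wqs'):.3f} "
      f"(SE {final.se('wqs'):.3f}, p = {final.pvalue('wqs'):.2g})")
print(f"informative bootstraps: {ensemble.n_informative}")
print("estimated weights (truth 0.7, 0.3, 0, 0, 0):")
for name, wgt in zip(data.component_names, ensemble.w_bar):
    print(f"  {name}: {wgt:.3f}")
# beta1 is the outcome change per simultaneous one-quantile-group
# increase of the weighted mixture; weights near the truth mean the
# ensemble attributed the effect to the right components.
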