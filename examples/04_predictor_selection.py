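"""Reduce a collinear predictor set by iterative VIF then pairwise |r|.

Builds a matrix with one near-duplicate pair and one moderately correlated
pair, and shows which variables each stage removes and why (the statistic
that condemned them).
"""

import numpy as np
import pandas as pd

from shaderange import compute_vif, select_predictors

rng = np.random.default_rng(4)
b = rng.standard_normal((600, 6))
X = pd.DataFrame({
    "BIO1": b[:, 0],
    "BIO10": b[:, 0] * 0.97 + 0.2 * b[:, 4],      # near-duplicate of BIO1
    "BIO12": b[:, 1],
    "BIO16": 0.8 * b[:, 1] + 0.55 * b[:, 5],      # correlated with BIO12
    "phh2o": b[:, 2],
    "cec": b[:, 3],
})

print("initial VIF:")
print(compute_vif(X).round(2).to_string())

result = select_predictors(X, vif_threshold=8.0, r_max=0.7)
print(f"\nkept: {result.kept}")
for name, stage, stat in result.dropped:
    print(f"dropped {name:6s} at stage {stage:11s} (statistic {stat:.2f})")
# the near-duplicate falls to the VIF stage (variance inflation > 8); the
# r~0.8 pair is resolved by the correlation stage, keeping the member that
# is more independent of everything else
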