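"""Robust low-variance feature filtering with rMAD and rIQR.

Both statistics are dimensionless dispersion measures: rMAD is the median
absolute deviation divided by |median|, rIQR the interquartile range
divided by |lower quartile| (upper quartile if the lower one is zero).
Used as lower bounds they drop features too flat to separate the groups,
and being median/quartile-based they ignore isolated outliers.
"""

import numpy as np

from stroopsense import apply_variance_thresholds, compute_variance_stats, riqr, rmad

print(f"rmad([1,2,3,4,5]) = {rmad([1, 2, 3, 4, 5]):.4f}  (median 3, MAD 1 -> 1/3)")
print(f"riqr([1,2,3,4,5]) = {riqr([1, 2, 3, 4, 5]):.4f}  (p25 2, p75 4 -> 2/2)")

# outlier robustness: one wild value barely moves either statistic
v = np.random.default_rng(0).normal(10, 1, 50)
w = v.copy()
w[0] = 1e6
print(f"\nrMAD before/after 1e6 outlier: {rmad(v):.4f} / {rmad(w):.4f}")
print(f"variance before/after:          {np.var(v):.1f} / {np.var(w):.3g}")

# threshold filtering on a mixed-dispersion feature matrix
rng = np.random.default_rng(1)
matrix = rng.normal(5, 1, (60, 10)) * rng.uniform(0.01, 2.0, 10)
matrix[:, 4] = 3.0  # a constant feature
stats = compute_variance_stats(matrix)
mask = apply_variance_thresholds(matrix, theta_rmad=0.02, theta_riqr=0.03)
print("\nfeature  rMAD    rIQR    kept")
for name, rm, ri, keep in zip(stats.feature_names, stats.rmad, stats.riqr, mask.mask):
    print(f"{name:<8} {rm:<7.4f} {ri:<7.4f} {bool(keep)}")
# The constant feature (rMAD = rIQR = 0) and any feature below either lower
# bound are dropped; during cross-validation these statistics are recomputed
# on training rows only.
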