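"""Transform a signal into its multidistance level differences.

The MSLD level at distance d is y_d(i) = |x(i) - x(i+d)|. Unlike
coarse-graining (window averaging), the transform keeps the variance of a
white signal roughly constant across distances.
"""

import numpy as np

from msld_sampen import coarse_grain, msld_set, msld_transform

rng = np.random.default_rng(0)
x = rng.standard_normal(4096)

print("first differences of (3, 1, 4, 1, 5):",
      msld_transform(np.array([3.0, 1, 4, 1, 5]), 1).values)

levels = msld_set(x, 1, 20)
print("\nMSLD of 4096-sample white noise:")
print("level lengths:", len(levels[1]), "...", len(levels[20]))
for d in (1, 5, 20):
    print(f"  var(MSLD d={d:2d}) / var(x) = {levels[d].values.var() / x.var():.3f}")
for s in (5, 20):
    print(f"  var(coarse-grained s={s:2d}) / var(x) = "
          f"{coarse_grain(x, s).var() / x.var():.3f}   <- shrinks like 1/s")
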