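"""The two significance procedures, on the published count tables.

Both are one-sided (upper tail): only enrichment is biologically tested.
"""

import numpy as np

from swrseq.stats import one_sample_ztest, proportion_ztest

# 1. Noise-model Z-test: is a signal larger than an empirical noise sample?
rng = np.random.default_rng(0)
noise = rng.normal(5.0, 2.0, size=1000)  # e.g. mutant-strain counts
for x in (5.0, 9.0, 15.0):
    res = one_sample_ztest(x, noise)
    print(f"x = {x:5.1f}: z = {res.statistic:6.2f}, p = {res.p_value:.4f}")

# 2. Proportion Z-test: does an observed overlap rate beat a baseline?
# 243 of the 1,777 top-ranked in vitro substrates fall on +1 nucleosomes;
# random picks would hit +1 at 8.02%.
res = proportion_ztest(243, 1777, 0.0802)
print(f"\n+1 overlap: p_hat = {100 * 243 / 1777:.1f}%, SE = {res.sigma:.4f}, "
      f"z = {res.statistic:.2f}, p = {res.p_value:.2e}")

# against the 18% genome-wide H2A.Z baseline the SE is 0.0091
res18 = proportion_ztest(622, 1777, 0.18)
print(f"18% baseline: SE = {res18.sigma:.4f} (sample size n = {res18.n})")
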