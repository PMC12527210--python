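"""Compute response ratios and run a contingency-sensitivity test.

The ratio compares baseline (training) to test responding:
ratio = mean baseline responses / (mean baseline + mean test responses).
0.5 means responding carried on unchanged under the degraded contingency
(habit-like persistence); values near 1 mean goal-directed suppression.
"""

import numpy as np

from operant import one_sample_t, simulate_cohort
from operant.measures import participant_ratio

for preset in ("goal_directed", "habitual"):
    cohort = simulate_cohort("exp1", n_participants=50, preset=preset, seed=3)
    ratios = [participant_ratio(p, "standard").ratio for p in cohort]
    ratios = [r for r in ratios if not np.isnan(r)]
    res = one_sample_t(ratios, mu0=0.5, alternative="greater")
    print(f"{preset:14s}: mean ratio = {np.mean(ratios):.3f}, "
          f"t({res.df:.0f}) = {res.statistic:.2f}, one-tailed p = {res.p_one_tailed:.2g}, "
          f"BF10 = {res.bf10:.3g}")
# The goal-directed cohort rejects ratio = 0.5 decisively; the habitual
# cohort sits at ~0.5, the signature of contingency-blind responding.
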