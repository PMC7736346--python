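"""Within-group variance comparison via covariance matrices on 6 PCs.

For each group pair: a maximum-likelihood test of covariance
proportionality (are the two groups' variation patterns the same up to a
scalar?) and the ratio of generalized variances (how much more overall
variation does one group express?).  The analysis is re-run with the
planted outlier DV3 excluded, which shrinks the MUP group's variance.
"""

import craniomorph as cm

cfg = cm.RunConfig(n_permutations=99, seed=1)
report = cm.run_variance(cfg)

full = report["vcv_full"]
print("generalized-variance ratios (row / column):")
print(full.ratio_frame().round(3))
print("\nproportionality-test p-values:")
print(full.prop_p_frame().round(3))

excl = report["vcv_excluded"]
print("\nMUP/AmNat ratio with DV3:   "
      f"{full.ratio_frame().loc['MUP', 'AmNat']:.3f}")
print("MUP/AmNat ratio without DV3: "
      f"{excl.ratio_frame().loc['MUP', 'AmNat']:.3f}")
# At n=11 per group a generalized variance is a noisy statistic (about
# 1.6 log-units standard error), so single-run ratios scatter widely
# around the planted values; orderings of widely separated groups persist.
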