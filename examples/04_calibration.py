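"""Decision-rule calibration under the null, at reduced scale.

Reproduces both simulation assessments: the ROPE false-positive rate for
null paired ratings at public-sample size, and the expected percentage of
null comparisons selected by the cumulative c-value budget at
personnel-sample size.  (The acceptance script runs the full-scale
versions.)
"""

import mrpsup as m

rope_cfg = m.CalibrationConfig(replicates=200, n_respondents=1500, scale=7,
                               seed=1)
rope = m.simulate_rope_fpr(rope_cfg)
print(f"ROPE false positives: {rope.value:.2f}% of {rope.replicates} null "
      f"comparisons (MC SE {rope.mc_se:.2f}) -- expected < 1%")

budget_cfg = m.CalibrationConfig(replicates=100, n_respondents=20, scale=5,
                                 n_items=7, seed=2)
budget = m.simulate_permutation_fdr(budget_cfg)
print(f"budget-rule selections: {budget.value:.2f}% per null set of 21 "
      f"pairs (MC SE {budget.mc_se:.2f}) -- expected < 5%")
print()
print("Both rates stay under their targets: a 95% HDI rarely clears the")
print(".47-.53 ROPE when items are exchangeable, and the cumulative 5%")
print("c-value budget keeps expected false selections per set below 5%.")
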