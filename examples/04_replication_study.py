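"""Simulated two-arm group study with injected effect sizes.

Generates control and treated phantom cohorts (n = 6 per arm) whose
structure abundances differ by fixed treated/control ratios, measures every
phantom with the full pipeline, and compares groups by percent change with
a preparation-day-stratified permutation test.
"""
from thmorph import run_replication_study, FIG_EFFECT_RATIOS

print("injected treated/control ratios:", FIG_EFFECT_RATIOS)
for c in run_replication_study(n_per_group=6, seed=1):
    print(f"{c.name:14s} control {c.control_mean:7.2f} +- {c.control_se:.2f}   "
          f"treated {c.treated_mean:7.2f} +- {c.treated_se:.2f}   "
          f"change {c.percent_change:+6.1f}%   p = {c.p_value:.4f}")
# The estimated percent changes recover the injected effect structure
# (fascicle deficit ~ -73%, SN surplus ~ +83%, VTA ~ -43%, A11-13 ~ -38%)
# and the stratified permutation test flags each at its minimum attainable
# two-sided p (2 of 216 admissible within-day relabelings).
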