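"""APOE genotype and the placebo cognitive trajectory.

APOE4 homozygotes carry 20 % fewer cortical synapses and clear amyloid
more slowly (1.5 vs 0.5 units/13 weeks against the heterozygote's 1.0).
The model predicts that genotype sets the baseline ADAS-Cog (at least 1.5
points between the homozygote extremes) but leaves the 78-week
progression slope nearly unchanged — pairwise slope differences stay
within 10 %.
"""

from abqsp import AbetaLoad, FINAL_PARAMS, apoe_slope_analysis, default_params

surrogate, _ = default_params()
table = apoe_slope_analysis(AbetaLoad(4, 4), FINAL_PARAMS, surrogate)

print(table.to_string(index=False))
print(f"\nweek-0 gap (+/+ minus -/-): {table.attrs['week0_gap_pp_mm']:.2f} ADAS points")
print(f"max pairwise slope difference: {table.attrs['max_pairwise_rel_diff']:.1%}")
# Genotype drives the baseline difference, not the progression rate:
# the slope spread stays under the 10 % clinical-constraint threshold.
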