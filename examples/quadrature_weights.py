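"""The fractional-load weighting of a treated arm, worked by hand.

An untreated APOE4 heterozygote accrues 1 unit of each isoform per 13
weeks.  A low-dose BACE inhibitor suppresses 80 % of Abeta40 and 60 % of
Abeta42 accrual, so one step from integer load 4 lands at the fractional
loads 4.2 and 4.4.  Matrix values there are read through three-point
weights constrained to sum to 1, have centre weight 1/3, and reproduce
the load as their weighted mean — which forces a small negative weight
(linear extrapolation) on the far cell for the slower axis.
"""

from abqsp import INTERVENTION_LIBRARY, deposition_rate, quadrature_weights
from abqsp.pharmacodynamics import treated_center

bace_low = INTERVENTION_LIBRARY["BACE-I-low"]
schedule = deposition_rate("APOE4+/-", bace_low)
print(f"deposition under {bace_low.label}: "
      f"{schedule.rate_x:.2f} (Abeta40), {schedule.rate_y:.2f} (Abeta42) units/13wk")

for axis, rate in [("Abeta40", schedule.rate_x), ("Abeta42", schedule.rate_y)]:
    load = 4.0 + rate
    q = quadrature_weights(load, center=treated_center(load, reduced=True))
    w = ", ".join(f"{v:+.2f}" for v in q.weights)
    print(f"{axis}: effective load {load:.1f} on cells {q.support} -> weights ({w})")
# Abeta40: cells (4, 5, 6) weighted (+0.73, +0.33, -0.07); Abeta42: third
# weight +0.03 — the printed weighting factors of the worked example.
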