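"""Scan the coupling-parameter grid against the three clinical constraints.

Every (delta, alpha, alpha*, beta) cell at fixed x0 = 2 is scored against:
(1) the MCI region averages, (2) the scopolamine sensitivity ordering and
(3) APOE trajectory parallelism.  A reduced grid keeps this example quick;
`abqsp scan-sensitivity` runs the full default grid.
"""

from abqsp import default_params, grid_scan
from abqsp.sensitivity import summarize_scan

surrogate, receptor = default_params()
grid = {
    "delta": (0.0, 0.015, 0.025),
    "alpha": (0.001, 0.002),
    "alpha_star": (0.001, 0.002),
    "beta": (0.015, 0.03),
}
table = grid_scan(surrogate, receptor, grid=grid)
print(table[["delta", "alpha", "alpha_star", "beta", "c1", "c2", "c3", "all_met"]]
      .to_string(index=False))
print("\nsummary:", summarize_scan(table))
# The all-met cells sit at nonzero Abeta40 benefit (delta >= 0.015 here);
# with delta = 0 the amyloid-positive MCI average leaves the clinical band
# and the scopolamine ordering weakens, so the constraint set argues for a
# neurostimulatory short-isoform effect.
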