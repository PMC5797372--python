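"""Clinical-constraint evaluation over the coupling-parameter grid.

Three clinical data sets constrain the coupling constants (delta, alpha,
alpha*, beta) at fixed x0:

1. absolute MCI ADAS-Cog region averages — 8.5 +/- 1 points for the
   amyloid-negative and 10.7 +/- 1 for the amyloid-positive population at
   some integer cutoff below 4;
2. a steeper scopolamine dose-response in the amyloid-positive MCI
   population;
3. near-parallel APOE placebo trajectories — pairwise slope differences of
   at most 10 % with an APOE4+/+ baseline at least 1.5 ADAS points worse
   than APOE4-/-.

The exhaustive grid scan reproduces the headline mechanistic result: the
set of parameter cells meeting all three conditions requires a beneficial
Abeta40 effect (it is empty whenever delta = 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupling import CouplingParams
from .receptors import ReceptorParams, scopolamine_dose_response
from .surrogate import (
    DEFAULT_EVAL_WEEKS,
    SurrogateParams,
    mci_region_means,
    placebo_adas_trajectory,
)

__all__ = [
    "ConditionReport",
    "evaluate_conditions",
    "grid_scan",
    "default_grid",
    "DEFAULT_EVAL_WEEKS",
]

#: Condition-1 target bands (ADAS-Cog points).
C1_NEG_TARGET = 8.5
C1_POS_TARGET = 10.7
C1_TOL = 1.0
C1_CUTOFFS = (1, 2, 3)

#: Condition-3 thresholds.
C3_MAX_SLOPE_DIFF = 0.10
C3_MIN_BASELINE_GAP = 1.5


@dataclass(frozen=True)
class ConditionReport:
    """Outcome of the three clinical constraints for one parameter cell."""

    params: CouplingParams
    c1: bool
    c2: bool
    c3: bool
    metrics: dict

    @property
    def all_met(self) -> bool:
        return self.c1 and self.c2 and self.c3


def _condition1(coupling: CouplingParams, surrogate: SurrogateParams) -> tuple[bool, dict]:
    best = None
    ok = False
    for cutoff in C1_CUTOFFS:
        neg, pos = mci_region_means(coupling, cutoff, surrogate)
        dev = max(abs(neg - C1_NEG_TARGET), abs(pos - C1_POS_TARGET))
        if best is None or dev < best["c1_deviation"]:
            best = {
                "c1_cutoff": cutoff,
                "c1_neg_mean": neg,
                "c1_pos_mean": pos,
                "c1_deviation": dev,
            }
        if abs(neg - C1_NEG_TARGET) <= C1_TOL and abs(pos - C1_POS_TARGET) <= C1_TOL:
            ok = True
            best = {
                "c1_cutoff": cutoff,
                "c1_neg_mean": neg,
                "c1_pos_mean": pos,
                "c1_deviation": dev,
            }
            break
    return ok, best


def _condition2(
    coupling: CouplingParams, surrogate: SurrogateParams, receptor: ReceptorParams
) -> tuple[bool, dict]:
    dr = scopolamine_dose_response(coupling=coupling, surrogate=surrogate, receptor=receptor)
    neg, pos = dr.slopes["Abeta-"], dr.slopes["Abeta+"]
    return abs(pos) > abs(neg), {"c2_slope_neg": neg, "c2_slope_pos": pos}


def _condition3(coupling: CouplingParams, surrogate: SurrogateParams) -> tuple[bool, dict]:
    weeks = np.asarray(DEFAULT_EVAL_WEEKS)
    slopes = {}
    week0 = {}
    for geno in ("APOE4-/-", "APOE4+/-", "APOE4+/+"):
        adas = placebo_adas_trajectory(weeks, geno, surrogate, coupling)
        slopes[geno] = float(np.polyfit(weeks, adas, 1)[0])
        week0[geno] = float(adas[0])
    vals = list(slopes.values())
    max_rel = max(
        abs(a - b) / max(abs(a), abs(b)) for a, b in itertools.combinations(vals, 2)
    )
    gap = week0["APOE4+/+"] - week0["APOE4-/-"]
    ok = max_rel <= C3_MAX_SLOPE_DIFF and gap >= C3_MIN_BASELINE_GAP
    return ok, {
        "c3_slope_mm": slopes["APOE4-/-"],
        "c3_slope_het": slopes["APOE4+/-"],
        "c3_slope_pp": slopes["APOE4+/+"],
        "c3_max_rel_diff": max_rel,
        "c3_week0_gap": gap,
    }


def evaluate_conditions(
    coupling: CouplingParams,
    surrogate: SurrogateParams,
    receptor: ReceptorParams,
) -> ConditionReport:
    """Evaluate the three clinical constraints at one coupling-parameter cell."""
    c1, m1 = _condition1(coupling, surrogate)
    c2, m2 = _condition2(coupling, surrogate, receptor)
    c3, m3 = _condition3(coupling, surrogate)
    return ConditionReport(params=coupling, c1=c1, c2=c2, c3=c3, metrics={**m1, **m2, **m3})


def default_grid() -> dict[str, tuple[float, ...]]:
    """Default scan values spanning every coupling value quoted in the text."""
    return {
        "delta": (0.0, 0.005, 0.01, 0.015, 0.02, 0.025, 0.03),
        "alpha": (0.0005, 0.001, 0.0015, 0.002, 0.0025),
        "alpha_star": (0.0005, 0.001, 0.0015, 0.002, 0.0025),
        "beta": (0.005, 0.015, 0.025, 0.035),
    }


def grid_scan(
    surrogate: SurrogateParams,
    receptor: ReceptorParams,
    grid: dict | None = None,
    x0: float = 2.0,
) -> pd.DataFrame:
    """Exhaustive Cartesian scan of the coupling grid at fixed x0.

    Pure map over cells: one row per parameter combination with the c1/c2/c3
    flags and their underlying metrics.
    """
    grid = grid if grid is not None else default_grid()
    for key in ("delta", "alpha", "alpha_star", "beta"):
        if key not in grid or len(grid[key]) == 0:
            raise ValueError(f"grid must provide non-empty values for {key!r}")
    rows = []
    for delta, alpha, alpha_star, beta in itertools.product(
        grid["delta"], grid["alpha"], grid["alpha_star"], grid["beta"]
    ):
        cp = CouplingParams(x0=x0, delta=delta, alpha=alpha, alpha_star=alpha_star, beta=beta)
        rep = evaluate_conditions(cp, surrogate, receptor)
        rows.append(
            {
                "x0": x0,
                "delta": delta,
                "alpha": alpha,
                "alpha_star": alpha_star,
                "beta": beta,
                "c1": rep.c1,
                "c2": rep.c2,
                "c3": rep.c3,
                "all_met": rep.all_met,
                **rep.metrics,
            }
        )
    return pd.DataFrame(rows)


def summarize_scan(table: pd.DataFrame) -> dict:
    """Frontier summary of a grid scan: where are all three conditions met?"""
    met = table[table["all_met"]]
    out = {
        "n_cells": int(len(table)),
        "n_all_met": int(len(met)),
        "delta0_all_met": int(len(met[met["delta"] == 0.0])),
    }
    if len(met):
        out["min_delta_all_met"] = float(met["delta"].min())
        out["min_alpha_sum_all_met"] = float((met["alpha"] + met["alpha_star"]).min())
    return out
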