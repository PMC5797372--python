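"""Isoform-specific coupling of amyloid-beta load to synaptic transmission.

The model tracks two low-order-aggregate pools (monomer/dimer/trimer):
``x`` is the Abeta40 load and ``y`` the Abeta42 load, each on an arbitrary
0..16 unit scale (1 unit = the amyloid accrued in 13 weeks by an untreated
APOE4 heterozygote).  Abeta40 is biphasic on NMDA conductance: it stimulates
excitatory-excitatory NMDA conductance up to a peak load ``x0`` (maximal
relative benefit ``delta``) and depresses it beyond the peak with slope
``alpha``.  Abeta42 depresses NMDA conductance monotonically with slope
``alpha_star``.  Both isoforms reduce alpha7 nicotinic receptor activation
with a common coupling factor ``beta``.

Evaluating the two point relations on every integer (x, y) pair yields a
17x17 effect matrix; region partitions of that grid define the amyloid-
negative / amyloid-positive virtual populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

GRID_MAX = 16
GRID_SIZE = GRID_MAX + 1

__all__ = [
    "GRID_MAX",
    "GRID_SIZE",
    "CouplingParams",
    "AbetaLoad",
    "EffectMatrix",
    "RegionPartition",
    "glu_conductance_factor",
    "a7_activation_factor",
    "build_effect_matrix",
    "region_partition",
]


@dataclass(frozen=True)
class CouplingParams:
    """Coupling constants of the amyloid-transmission relations.

    Parameters
    ----------
    x0 : float
        Abeta40 load (units) at which the NMDA benefit peaks.  ``x0 = 0``
        collapses the rising branch: the peak sits at the origin.
    delta : float
        Maximal relative NMDA conductance benefit (dimensionless).
    alpha : float
        Post-peak Abeta40 slope (per unit of load).
    alpha_star : float
        Abeta42 slope on NMDA conductance (per unit).
    beta : float
        Common Abeta40/42 coupling on alpha7 nAChR activation (per unit).
    g_floor : float
        Lower bound applied to the conductance ratio (conductances cannot
        be negative); no ceiling is applied.
    """

    x0: float = 2.0
    delta: float = 0.025
    alpha: float = 0.002
    alpha_star: float = 0.002
    beta: float = 0.03
    g_floor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x0", "delta", "alpha", "alpha_star", "beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"CouplingParams.{name} must be >= 0")
        if not 0 <= self.x0 <= GRID_MAX:
            raise ValueError(f"x0 must lie in [0, {GRID_MAX}], got {self.x0}")


# Final constrained parameter set used for the intervention analyses.
FINAL_PARAMS = CouplingParams(x0=2, delta=0.025, alpha=0.002, alpha_star=0.002, beta=0.03)
# Parameter set used for the MCI region-average (SUVR calibration) analysis.
MCI_CALIBRATION_PARAMS = CouplingParams(
    x0=2, delta=0.015, alpha=0.0015, alpha_star=0.00035, beta=0.025
)


@dataclass(frozen=True)
class AbetaLoad:
    """A point in the (Abeta40, Abeta42) load plane, in model units."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= GRID_MAX) or not (0 <= self.y <= GRID_MAX):
            raise ValueError(
                f"Abeta load ({self.x}, {self.y}) outside the [0, {GRID_MAX}] grid"
            )


def glu_conductance_factor(load: AbetaLoad, params: CouplingParams) -> float:
    """Relative NMDA conductance g/g0 at a given amyloid load.

    Piecewise-linear in the Abeta40 load: ``1 + delta*(x/x0) - y*alpha_star``
    on the rising branch (x <= x0), ``1 + delta + (x0-x)*alpha - y*alpha_star``
    beyond the peak.  With ``x0 = 0`` only the declining branch is used
    (peak at the origin), which avoids the x/x0 division.  The result is
    floored at ``params.g_floor``.
    """
    x, y = load.x, load.y
    if params.x0 > 0 and x <= params.x0:
        g = 1.0 + params.delta * (x / params.x0) - y * params.alpha_star
    else:
        g = 1.0 + params.delta + (params.x0 - x) * params.alpha - y * params.alpha_star
    return max(params.g_floor, g)


def a7_activation_factor(load: AbetaLoad, params: CouplingParams) -> float:
    """Relative alpha7 nAChR activation, ``max(0, 1 - beta*(x+y))``.

    Baseline activation is normalised to 1; both isoforms contribute
    symmetrically through the coupling factor beta.
    """
    return max(0.0, 1.0 - params.beta * (load.x + load.y))


def _glu_grid(params: CouplingParams) -> np.ndarray:
    """Vectorised g/g0 over the integer grid; [i, j] = (x=i, y=j)."""
    x = np.arange(GRID_SIZE, dtype=float)[:, None]
    y = np.arange(GRID_SIZE, dtype=float)[None, :]
    rising = 1.0 + (params.delta * (x / params.x0) if params.x0 > 0 else 0.0) - y * params.alpha_star
    falling = 1.0 + params.delta + (params.x0 - x) * params.alpha - y * params.alpha_star
    g = np.where((params.x0 > 0) & (x <= params.x0), rising, falling)
    return np.maximum(params.g_floor, g)


def _a7_grid(params: CouplingParams) -> np.ndarray:
    x = np.arange(GRID_SIZE, dtype=float)[:, None]
    y = np.arange(GRID_SIZE, dtype=float)[None, :]
    return np.maximum(0.0, 1.0 - params.beta * (x + y))


@dataclass(frozen=True, eq=False)
class EffectMatrix:
    """17x17 grid of (g_ratio, a7_factor) over integer amyloid loads.

    ``g_ratio[i, j]`` and ``a7_factor[i, j]`` hold the values at
    ``(x=i, y=j)``.
    """

    params: CouplingParams
    g_ratio: np.ndarray = field(repr=False)
    a7_factor: np.ndarray = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.g_ratio.size

    def cell(self, x: int, y: int) -> tuple[float, float]:
        return float(self.g_ratio[x, y]), float(self.a7_factor[x, y])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns x, y, g_ratio, a7_factor."""
        x, y = np.meshgrid(np.arange(GRID_SIZE), np.arange(GRID_SIZE), indexing="ij")
        return pd.DataFrame(
            {
                "x": x.ravel(),
                "y": y.ravel(),
                "g_ratio": self.g_ratio.ravel(),
                "a7_factor": self.a7_factor.ravel(),
            }
        )


def build_effect_matrix(params: CouplingParams) -> EffectMatrix:
    """Evaluate both coupling relations on every integer (x, y) cell."""
    return EffectMatrix(params=params, g_ratio=_glu_grid(params), a7_factor=_a7_grid(params))


PartitionMode = Literal["both-axes", "complement"]


@dataclass(frozen=True)
class RegionPartition:
    """Amyloid-negative / amyloid-positive split of the integer grid.

    ``both-axes`` follows the population definition used throughout the
    analyses: Abeta- requires x < cutoff and y < cutoff, Abeta+ requires
    x >= cutoff and y >= cutoff, mixed cells belong to neither.
    ``complement`` instead takes Abeta+ as everything outside the Abeta- box.
    """

    cutoff: int
    mode: PartitionMode
    neg_cells: frozenset[tuple[int, int]]
    pos_cells: frozenset[tuple[int, int]]

    def neg_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return _cells_to_indices(self.neg_cells)

    def pos_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return _cells_to_indices(self.pos_cells)


def _cells_to_indices(cells: frozenset[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array(sorted(cells), dtype=int)
    return arr[:, 0], arr[:, 1]


def _iter_grid() -> Iterator[tuple[int, int]]:
    for x in range(GRID_SIZE):
        for y in range(GRID_SIZE):
            yield x, y


def region_partition(cutoff: int, mode: PartitionMode = "both-axes") -> RegionPartition:
    """Split the grid into Abeta- and Abeta+ populations at a unit cutoff."""
    if not 1 <= cutoff <= GRID_MAX:
        raise ValueError(f"cutoff must lie in [1, {GRID_MAX}], got {cutoff}")
    if mode not in ("both-axes", "complement"):
        raise ValueError(f"unknown partition mode {mode!r}")
    neg = frozenset((x, y) for x, y in _iter_grid() if x < cutoff and y < cutoff)
    if mode == "both-axes":
        pos = frozenset((x, y) for x, y in _iter_grid() if x >= cutoff and y >= cutoff)
    else:
        pos = frozenset(_iter_grid()) - neg
    return RegionPartition(cutoff=cutoff, mode=mode, neg_cells=neg, pos_cells=pos)
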