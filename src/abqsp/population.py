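"""Synthetic virtual-patient cohorts for trial enrollment.

No patient-level data exist for this model; cohorts are generated with
configurable baseline (Abeta40, Abeta42) load distributions, APOE genotype
frequencies and optional ADAS-Cog measurement noise, so that every
pipeline stage can be exercised end to end.  All randomness flows from a
single integer seed through ``numpy.random.default_rng``.

Noise is applied post hoc to outcomes only, never to loads: the
pharmacology itself is deterministic, and the noise exists to exercise
cohort-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coupling import GRID_MAX, AbetaLoad, RegionPartition
from .pharmacodynamics import GENOTYPES
from .trial import Patient

__all__ = ["CohortSpec", "generate_cohort", "add_measurement_noise", "cohort_frame"]

#: Default genotype mix (-/-, +/-, +/+): symmetric around the heterozygote.
DEFAULT_GENOTYPE_FREQS = (0.25, 0.50, 0.25)


@dataclass(frozen=True)
class CohortSpec:
    """Composition of a synthetic cohort.

    ``baseline`` selects the load distribution:

    * ``("fixed", x, y)`` — every patient at one load;
    * ``("uniform-region", partition, which)`` — uniform over the integer
      cells of a region (``which`` in {"neg", "pos"});
    * ``("table", probs)`` — an arbitrary 17x17 probability table over the
      integer grid.
    """

    n: int
    baseline: tuple = ("fixed", 4.0, 4.0)
    genotype_freqs: tuple[float, float, float] = DEFAULT_GENOTYPE_FREQS
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if abs(sum(self.genotype_freqs) - 1.0) > 1e-9:
            raise ValueError("genotype frequencies must sum to 1")
        if any(f < 0 for f in self.genotype_freqs):
            raise ValueError("genotype frequencies must be >= 0")


def _draw_baselines(spec: CohortSpec, rng: np.random.Generator) -> list[AbetaLoad]:
    kind = spec.baseline[0]
    if kind == "fixed":
        _, x, y = spec.baseline
        return [AbetaLoad(float(x), float(y))] * spec.n
    if kind == "uniform-region":
        _, partition, which = spec.baseline
        if not isinstance(partition, RegionPartition):
            raise ValueError("uniform-region baseline needs a RegionPartition")
        cells = sorted(partition.neg_cells if which == "neg" else partition.pos_cells)
        idx = rng.integers(0, len(cells), size=spec.n)
        return [AbetaLoad(float(cells[i][0]), float(cells[i][1])) for i in idx]
    if kind == "table":
        _, probs = spec.baseline
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (GRID_MAX + 1, GRID_MAX + 1):
            raise ValueError("probability table must be 17x17")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probability table must be non-negative and sum to 1")
        flat = probs.ravel()
        idx = rng.choice(len(flat), size=spec.n, p=flat)
        return [AbetaLoad(float(i // (GRID_MAX + 1)), float(i % (GRID_MAX + 1))) for i in idx]
    raise ValueError(f"unknown baseline distribution {kind!r}")


def generate_cohort(spec: CohortSpec) -> list[Patient]:
    """Draw a reproducible cohort of virtual patients."""
    rng = np.random.default_rng(spec.seed)
    genotypes = rng.choice(len(GENOTYPES), size=spec.n, p=list(spec.genotype_freqs))
    baselines = _draw_baselines(spec, rng)
    return [
        Patient(patient_id=i, genotype=GENOTYPES[genotypes[i]], baseline=baselines[i])
        for i in range(spec.n)
    ]


def cohort_frame(cohort: Sequence[Patient]) -> pd.DataFrame:
    """Cohort as a delimited-table-ready frame (patient_id, genotype, x, y)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "genotype": [p.genotype for p in cohort],
            "x": [p.baseline.x for p in cohort],
            "y": [p.baseline.y for p in cohort],
        }
    )


def add_measurement_noise(
    trajectories: pd.DataFrame, noise_sd: float, seed: int
) -> pd.DataFrame:
    """Additive independent ADAS measurement noise, clipped to [0, 70].

    Only the ``adas`` column is perturbed; ``noise_sd = 0`` returns an
    identical copy.  Loads are never perturbed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = trajectories.copy()
    if noise_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(out))
    out["adas"] = np.clip(out["adas"].to_numpy() + noise, 0.0, 70.0)
    return out
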