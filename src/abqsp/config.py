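"""Run configuration (YAML) and table/report writers.

A single structured config file drives every pipeline stage; every block
is validated against its module's invariants before any computation runs,
and validation errors name the offending key and the violated constraint.
Outputs are comma-delimited tables with period decimal separators plus a
run manifest (config hash, seed, package version); re-running with the
same config and seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .coupling import CouplingParams, region_partition
from .pharmacodynamics import INTERVENTION_LIBRARY, InterventionPD
from .population import DEFAULT_GENOTYPE_FREQS, CohortSpec
from .sensitivity import default_grid
from .surrogate import DEFAULT_EVAL_WEEKS
from .trial import TrialSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "write_outputs", "default_config_dict"]

DEFAULT_SEED = 12345


class ConfigError(ValueError):
    """A config key violated its constraint."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for one run."""

    coupling: CouplingParams
    cohort: CohortSpec
    trial: TrialSpec
    scopolamine_doses: tuple
    scopolamine_cutoff: int
    sensitivity_grid: dict
    sensitivity_x0: float
    output_dir: Path
    seed: int
    log_level: str = "INFO"


def default_config_dict() -> dict:
    """The shipped default configuration as a plain dictionary."""
    return {
        "seed": DEFAULT_SEED,
        "log_level": "INFO",
        "output_dir": "results",
        "coupling": {
            "x0": 2,
            "delta": 0.025,
            "alpha": 0.002,
            "alpha_star": 0.002,
            "beta": 0.03,
        },
        "cohort": {
            "n": 20,
            "baseline": {"kind": "fixed", "x": 8, "y": 8},
            "genotype_freqs": list(DEFAULT_GENOTYPE_FREQS),
            "noise_sd": 0.0,
        },
        "trial": {
            "arms": [
                "placebo",
                "BACE-I-low",
                "BACE-I-high",
                "GSI-low",
                "GSI-high",
                "solanezumab-low",
                "solanezumab-high",
            ],
            "eval_weeks": list(DEFAULT_EVAL_WEEKS),
        },
        "scopolamine": {"doses": [float(d) for d in range(0, 11)], "cutoff": 3},
        "sensitivity": {"x0": 2, "grid": "default"},
    }


def _coupling_from(block: dict) -> CouplingParams:
    try:
        return CouplingParams(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"coupling: {exc}") from exc


def _cohort_from(block: dict, seed: int) -> CohortSpec:
    base = block.get("baseline", {"kind": "fixed", "x": 4, "y": 4})
    kind = base.get("kind", "fixed")
    if kind == "fixed":
        baseline = ("fixed", float(base.get("x", 4)), float(base.get("y", 4)))
    elif kind == "uniform-region":
        cutoff = int(base.get("cutoff", 3))
        baseline = ("uniform-region", region_partition(cutoff), base.get("which", "neg"))
    else:
        raise ConfigError(f"cohort.baseline.kind: unknown kind {kind!r}")
    try:
        return CohortSpec(
            n=int(block.get("n", 20)),
            baseline=baseline,
            genotype_freqs=tuple(block.get("genotype_freqs", DEFAULT_GENOTYPE_FREQS)),
            noise_sd=float(block.get("noise_sd", 0.0)),
            seed=seed,
        )
    except ValueError as exc:
        raise ConfigError(f"cohort: {exc}") from exc


def _arm_from(entry, interventions: dict) -> tuple[str, InterventionPD | None]:
    if isinstance(entry, str):
        if entry == "placebo":
            return entry, None
        if entry in interventions:
            return entry, interventions[entry]
        raise ConfigError(
            f"trial.arms: unknown arm {entry!r}; known: placebo, "
            + ", ".join(sorted(interventions))
        )
    name = entry.get("name", "custom")
    try:
        pd_ = InterventionPD(
            name=name,
            reduction_x=float(entry["reduction_x"]),
            reduction_y=float(entry["reduction_y"]),
            dose_label=str(entry.get("dose_label", "")),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(
            f"trial.arms[{name}]: reductions must be given and lie in [0, 1] ({exc})"
        ) from exc
    return pd_.label, pd_


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    With ``path=None`` the shipped defaults are used.  A seed given on the
    command line overrides the config; a config without a seed gets the
    deterministic default (logged).
    """
    if path is None:
        raw = default_config_dict()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")

    if seed is not None:
        the_seed = int(seed)
    elif "seed" in raw:
        the_seed = int(raw["seed"])
    else:
        the_seed = DEFAULT_SEED
        logger.info("config omits seed; using deterministic default %d", the_seed)

    coupling = _coupling_from(raw.get("coupling", default_config_dict()["coupling"]))
    cohort = _cohort_from(raw.get("cohort", default_config_dict()["cohort"]), the_seed)

    trial_block = raw.get("trial", default_config_dict()["trial"])
    arms = {}
    for entry in trial_block.get("arms", ["placebo"]):
        label, pd_ = _arm_from(entry, INTERVENTION_LIBRARY)
        arms[label] = pd_
    try:
        trial = TrialSpec(
            arms=arms,
            eval_weeks=tuple(float(w) for w in trial_block.get("eval_weeks", DEFAULT_EVAL_WEEKS)),
            coupling=coupling,
            seed=the_seed,
        )
    except ValueError as exc:
        raise ConfigError(f"trial: {exc}") from exc

    scop = raw.get("scopolamine", default_config_dict()["scopolamine"])
    doses = tuple(float(d) for d in scop.get("doses", list(range(11))))
    cutoff = int(scop.get("cutoff", 3))
    if not 1 <= cutoff <= 16:
        raise ConfigError(f"scopolamine.cutoff: {cutoff} outside [1, 16]")

    sens = raw.get("sensitivity", default_config_dict()["sensitivity"])
    grid = sens.get("grid", "default")
    grid = default_grid() if grid == "default" else {k: tuple(v) for k, v in grid.items()}

    return RunConfig(
        coupling=coupling,
        cohort=cohort,
        trial=trial,
        scopolamine_doses=doses,
        scopolamine_cutoff=cutoff,
        sensitivity_grid=grid,
        sensitivity_x0=float(sens.get("x0", 2)),
        output_dir=Path(raw.get("output_dir", "results")),
        seed=the_seed,
        log_level=str(raw.get("log_level", "INFO")),
    )


_TABLE_HEADER = (
    "# abqsp output; loads in model units (1 unit = 13-week accrual of an "
    "untreated APOE4 heterozygote), ADAS-Cog in points (0-70, higher = worse), "
    "accuracy in % correct, doses in nM\n"
)


def write_outputs(
    results: dict[str, pd.DataFrame],
    directory: str | Path,
    config: RunConfig | None = None,
    extra: dict | None = None,
) -> dict:
    """Write result tables and a run manifest; returns the manifest.

    Tables are CSV with a unit-documenting comment header and fixed column
    order; the manifest records the config hash, seed and package version
    (timestamps are excluded from the tables so reruns are byte-identical).
    """
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for name, frame in results.items():
        path = directory / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(_TABLE_HEADER)
            frame.to_csv(fh, index=False)
        files.append(path.name)
    manifest = {
        "files": files,
        "n_tables": len(files),
        "seed": config.seed if config is not None else None,
        "package_version": __version__,
        "config_sha256": (
            hashlib.sha256(
                json.dumps(_manifest_config(config), sort_keys=True).encode()
            ).hexdigest()
            if config is not None
            else None
        ),
        "written_at_unix": int(time.time()),
    }
    if extra:
        manifest.update(extra)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if not files:
        logger.warning("no data files written to %s", directory)
    return manifest


def _manifest_config(config: RunConfig) -> dict:
    return {
        "coupling": {
            "x0": config.coupling.x0,
            "delta": config.coupling.delta,
            "alpha": config.coupling.alpha,
            "alpha_star": config.coupling.alpha_star,
            "beta": config.coupling.beta,
        },
        "seed": config.seed,
        "cohort_n": config.cohort.n,
        "arms": sorted(config.trial.arms),
    }


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_outputs` (full precision)."""
    return pd.read_csv(path, comment="#")
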