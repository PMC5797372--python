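"""Shipped calibrated parameters and their (re)generation.

The surrogate and receptor constants are fitted once by
:func:`abqsp.surrogate.calibrate_surrogate` and
:func:`abqsp.receptors.calibrate_receptor` and serialized, with their
anchor residuals, to ``params/defaults.yaml`` inside the package, so
downstream analyses need no refit.  ``abqsp calibrate`` regenerates the
file.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

import yaml

from .receptors import ReceptorParams, calibrate_receptor
from .surrogate import SurrogateParams, calibrate_surrogate

__all__ = ["default_params", "run_calibration", "write_params_file"]

_RESOURCE = "defaults.yaml"


@functools.lru_cache(maxsize=1)
def default_params() -> tuple[SurrogateParams, ReceptorParams]:
    """Load the shipped calibrated surrogate and receptor parameters."""
    ref = resources.files("abqsp").joinpath("params", _RESOURCE)
    data = yaml.safe_load(ref.read_text())
    surrogate = SurrogateParams.from_dict(data["surrogate"])
    receptor = ReceptorParams(**data["receptor"])
    return surrogate, receptor


def run_calibration() -> dict:
    """Run the full two-stage calibration; returns a serializable bundle."""
    surrogate, sur_report = calibrate_surrogate()
    receptor, surrogate, rec_report = calibrate_receptor(surrogate)
    return {
        "surrogate": surrogate.to_dict(),
        "receptor": {
            "gamma": float(receptor.gamma),
            "w_m1": float(receptor.w_m1),
            "w_gaba": float(receptor.w_gaba),
        },
        "provenance": {
            "surrogate_anchors": [
                {k: (float(v) if isinstance(v, (int, float)) else v) for k, v in e.items()}
                for e in sur_report["anchors"]
            ],
            "receptor_fit": {
                "slopes_with_benefit": {
                    k: float(v) for k, v in rec_report["slopes_with_benefit"].items()
                },
                "slopes_delta0": {k: float(v) for k, v in rec_report["slopes_delta0"].items()},
                "baseline_accuracy": float(rec_report["baseline_accuracy"]),
            },
        },
    }


def write_params_file(path: str | Path | None = None) -> Path:
    """Regenerate the shipped parameter file (used by ``abqsp calibrate``)."""
    if path is None:
        path = Path(__file__).parent / "params" / _RESOURCE
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bundle = run_calibration()
    path.write_text(yaml.safe_dump(bundle, sort_keys=False))
    default_params.cache_clear()
    return path
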