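"""Reduced-form cognition surrogate: neurophysiological state -> ADAS-Cog.

The original platform evaluates amyloid effects inside a biophysical
cortical network; this package replaces that network with a calibrated
latent-reserve surrogate.  A scalar "network reserve" (percent-equivalent
units, 0 = healthy cognitively normal) aggregates the neurophysiological
state linearly; logistic links map reserve to ADAS-Cog (0-70, decreasing
in reserve) and 2-back accuracy (0-100 %, increasing).  The logistic link
is the minimal structure that reproduces both the mid-pathology peak in
ADAS sensitivity to glutamate conductance and the reversal of scopolamine
slope ordering when the Abeta40 benefit is removed.

Amyloid enters through two channels:

* static stages (MCI) — an instantaneous term: ``g_mci`` reserve points per
  % NMDA conductance change plus a saturating penalty in the alpha7
  activation deficit (half-effect at ``a7_half``).  It represents the
  consolidated effect of living at that amyloid level.
* staged AD trials — a cumulative "functional burden": the week-profiled
  integral of the transmission deficit over trial time, saturating at
  ``burden_sat`` reserve points (network redundancy is finite).  A purely
  instantaneous map cannot reproduce the trial contrasts: at equal trial
  week a treated arm's amyloid state is component-wise no worse than
  placebo's, so only the accumulated early-trial deficit can make an
  amyloid-lowering arm end worse.

Week-indexed glutamate sensitivities (``glu_profile``) and the printed
APOE-genotype multipliers modulate the glutamate channel; synapse density
(+/-20 % by APOE genotype), neuron density and cholinergic tone enter the
reserve linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .coupling import (
    FINAL_PARAMS,
    MCI_CALIBRATION_PARAMS,
    CouplingParams,
    region_partition,
)
from .pharmacodynamics import BASE_RATES, Genotype

__all__ = [
    "DiseaseState",
    "SurrogateParams",
    "Anchor",
    "default_anchor_set",
    "disease_state",
    "network_reserve",
    "adas_from_reserve",
    "accuracy_from_reserve",
    "glu_slope",
    "calibrate_surrogate",
    "mci_adas_grid",
    "amyloid_burden",
    "placebo_reserve",
]

Stage = Literal["MCI", "AD"]

#: Weeks at which the glutamate sensitivity profile is anchored.
PROFILE_WEEKS = np.array([0.0, 12.0, 26.0, 52.0, 78.0])

#: Default clinic-visit weeks of a 78-week virtual trial.
DEFAULT_EVAL_WEEKS = (0.0, 12.0, 26.0, 52.0, 78.0)

#: APOE genotype modifiers on cortical synapse density.
SYNAPSE_MOD: dict[Genotype, float] = {"APOE4-/-": 1.2, "APOE4+/-": 1.0, "APOE4+/+": 0.8}

#: APOE4+/+ over APOE4-/- glutamate-sensitivity ratios at the profile weeks
#: (greater early in the trial, smaller late); heterozygotes midway.
_PP_OVER_MM = np.array([1.11, 1.03, 1.01, 0.92, 0.90])
APOE_GLU_MULT: dict[Genotype, np.ndarray] = {
    "APOE4-/-": np.ones(5),
    "APOE4+/-": (np.ones(5) + _PP_OVER_MM) / 2.0,
    "APOE4+/+": _PP_OVER_MM,
}

# Disease-stage constants: MCI compensates cholinergic tone (+30 %) with a
# 3 % density decrement; AD has a 30 % cholinergic deficit and loses
# synapses at 0.04 %/week and neurons at 0.35 %/week of trial time.
MCI_DENSITY_DECREMENT = 0.03
MCI_TONE = 1.3
AD_TONE = 0.7
SYNAPSE_LOSS_PER_WEEK = 0.0004
NEURON_LOSS_PER_WEEK = 0.0035


@dataclass(frozen=True)
class DiseaseState:
    """Structural/neuromodulatory state of the cortical network."""

    stage: Stage
    week: float
    synapse_density: float
    neuron_density: float
    cholinergic_tone: float
    genotype: Genotype = "APOE4+/-"

    def __post_init__(self) -> None:
        for name in ("synapse_density", "neuron_density"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.3:
                raise ValueError(f"{name}={v} outside (0, 1.3]")


def disease_state(stage: Stage, week: float = 0.0, genotype: Genotype = "APOE4+/-") -> DiseaseState:
    """Canonical disease state for a stage, trial week and APOE genotype."""
    if stage == "MCI":
        return DiseaseState(
            stage="MCI",
            week=week,
            synapse_density=1.0 - MCI_DENSITY_DECREMENT,
            neuron_density=1.0 - MCI_DENSITY_DECREMENT,
            cholinergic_tone=MCI_TONE,
            genotype=genotype,
        )
    if stage == "AD":
        if not 0 <= week <= 78:
            raise ValueError("AD trial week must lie in [0, 78]")
        syn = SYNAPSE_MOD[genotype] * (1.0 - SYNAPSE_LOSS_PER_WEEK * week)
        neu = 1.0 - NEURON_LOSS_PER_WEEK * week
        return DiseaseState(
            stage="AD",
            week=week,
            synapse_density=min(syn, 1.3),
            neuron_density=neu,
            cholinergic_tone=AD_TONE,
            genotype=genotype,
        )
    raise ValueError(f"unknown stage {stage!r}")


@dataclass(frozen=True)
class SurrogateParams:
    """Calibrated constants of the reserve model and its logistic links.

    Reserve weights are points of latent reserve per percent change of the
    corresponding quantity.  ``glu_profile`` holds the week-indexed
    glutamate sensitivity (reserve points per % conductance per 13-week
    step) at weeks 0/12/26/52/78 for the heterozygote genotype, linearly
    interpolated in between.
    """

    adas_scale: float
    adas_mid: float
    w_syn: float
    w_neu: float
    w_chol: float
    ad_offset: float
    g_mci: float
    a7_max: float
    a7_half: float
    a7_half_slow: float
    a7_frac_fast: float
    mci_gain_frac: float
    a7_burden: float
    burden_sat: float
    glu_profile: tuple[float, float, float, float, float]
    lost_stim_weight: float = 0.5
    attn_load_half: float = 12.0
    benefit_cap: float = 4.5
    acc_scale: float = 25.0
    acc_mid: float = -40.0

    def to_dict(self) -> dict:
        d = {k: float(v) for k, v in asdict(self).items() if k != "glu_profile"}
        d["glu_profile"] = [float(v) for v in self.glu_profile]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurrogateParams":
        d = dict(d)
        d["glu_profile"] = tuple(float(v) for v in d["glu_profile"])
        return cls(**d)


# ----------------------------------------------------------------------
# vectorised coupling helpers (accept scalars or arrays)


def _gpct(x, y, cp: CouplingParams):
    """Percent NMDA conductance change, 100*(g/g0 - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rising = (cp.delta * (x / cp.x0) if cp.x0 > 0 else cp.delta) - y * cp.alpha_star
    falling = cp.delta + (cp.x0 - x) * cp.alpha - y * cp.alpha_star
    g = np.where((x <= cp.x0) & (cp.x0 > 0), rising, falling)
    g = np.maximum(cp.g_floor - 1.0, g)
    return 100.0 * g


def _a7_deficit(x, y, cp: CouplingParams):
    """Fractional alpha7 activation deficit, 1 - a7_factor, in [0, 1]."""
    return np.clip(cp.beta * (np.asarray(x, dtype=float) + np.asarray(y, dtype=float)), 0.0, 1.0)


def _sat(d, half: float):
    """Saturating response d/(d+half)."""
    d = np.asarray(d, dtype=float)
    return d / (d + half)


def _a7_response(d, params: "SurrogateParams"):
    """Two-component saturating alpha7 deficit response, in [0, 1).

    A high-affinity component (half-effect ``a7_half``) captures the steep
    loss at the first units of load; a low-affinity component (half-effect
    ``a7_half_slow``) keeps the response graded across the full grid.
    """
    f = params.a7_frac_fast
    return f * _sat(d, params.a7_half) + (1.0 - f) * _sat(d, params.a7_half_slow)


# ----------------------------------------------------------------------
# reserve and links


def structural_reserve(state: DiseaseState, params: SurrogateParams):
    """Reserve contribution of densities and cholinergic tone (0 = healthy)."""
    r = (
        -params.w_syn * 100.0 * (1.0 - state.synapse_density)
        - params.w_neu * 100.0 * (1.0 - state.neuron_density)
        + params.w_chol * 100.0 * (state.cholinergic_tone - 1.0)
    )
    if state.stage == "AD":
        r += params.ad_offset
    return r


def mci_amyloid_reserve(gpct, a7_def, params: SurrogateParams, attn=1.0):
    """Instantaneous amyloid term used for static stages.

    ``attn`` is the load attenuation of the glutamate channel (see
    :func:`load_attenuation`); the alpha7 term saturates on its own.
    Conductance gains above baseline are discounted by ``mci_gain_frac``:
    a nearly intact network has little headroom for enhancement, while
    deficits register in full.
    """
    gpct = np.asarray(gpct, dtype=float)
    gain = np.where(gpct > 0, params.mci_gain_frac, 1.0)
    return params.g_mci * gain * gpct * attn - params.a7_max * _a7_response(a7_def, params)


def network_reserve(
    state: DiseaseState,
    g_ratio: float = 1.0,
    a7_factor: float = 1.0,
    params: SurrogateParams | None = None,
    *,
    amyloid_burden: float | None = None,
    load: tuple[float, float] | None = None,
    cholinergic_reserve: float = 0.0,
):
    """Latent network reserve for a full neurophysiological state.

    For static stages the amyloid effect is evaluated instantaneously from
    ``(g_ratio, a7_factor)`` (with load attenuation if ``load`` is given);
    for staged trials the caller passes the accumulated ``amyloid_burden``
    (reserve points) instead.  ``cholinergic_reserve`` carries
    receptor-level terms (scopolamine).
    """
    if params is None:
        raise TypeError("params is required")
    r = structural_reserve(state, params)
    if amyloid_burden is None:
        gpct = 100.0 * (np.asarray(g_ratio, dtype=float) - 1.0)
        a7_def = np.clip(1.0 - np.asarray(a7_factor, dtype=float), 0.0, 1.0)
        attn = load_attenuation(load[0], load[1], params) if load is not None else 1.0
        r = r + mci_amyloid_reserve(gpct, a7_def, params, attn)
    else:
        r = r - amyloid_burden
    return r + cholinergic_reserve


def adas_from_reserve(reserve, params: SurrogateParams):
    """ADAS-Cog (0-70 points, higher = worse), monotone decreasing in reserve."""
    z = (np.asarray(reserve, dtype=float) - params.adas_mid) / params.adas_scale
    return 70.0 * expit(-z)


def accuracy_from_reserve(reserve, params: SurrogateParams):
    """2-back accuracy (% correct, 0-100), monotone increasing in reserve."""
    z = (np.asarray(reserve, dtype=float) - params.acc_mid) / params.acc_scale
    return 100.0 * expit(z)


# ----------------------------------------------------------------------
# week-indexed glutamate sensitivity


def glu_sensitivity(week, params: SurrogateParams, genotype: Genotype = "APOE4+/-"):
    """Reserve points per % conductance per 13-week step at a trial week."""
    base = np.interp(week, PROFILE_WEEKS, np.asarray(params.glu_profile))
    mult = np.interp(week, PROFILE_WEEKS, APOE_GLU_MULT[genotype])
    return base * mult


def load_attenuation(x, y, params: SurrogateParams):
    """Attenuation of glutamate sensitivity at high amyloid load.

    At greater loads the conductance is already strongly modulated and the
    range available to express a further % change shrinks; modelled as
    ``1 / (1 + (x+y)/attn_load_half)``.
    """
    total = np.asarray(x, dtype=float) + np.asarray(y, dtype=float)
    return 1.0 / (1.0 + total / params.attn_load_half)


def _burden_slack(b: float, params: SurrogateParams) -> float:
    """Two-sided saturation of the cumulative burden.

    Accumulated deficit saturates at ``burden_sat`` (network redundancy is
    finite) and accumulated net benefit at ``benefit_cap`` (treatment
    effects saturate at a couple of ADAS points).
    """
    if b >= 0.0:
        return max(0.0, 1.0 - b / params.burden_sat)
    return max(0.0, 1.0 + b / params.benefit_cap)


def amyloid_burden(
    weeks,
    x,
    y,
    genotype: Genotype,
    coupling: CouplingParams,
    params: SurrogateParams,
):
    """Cumulative amyloid functional burden (reserve points) on a weekly grid.

    ``weeks`` must be an ascending grid starting at 0 with ``x``/``y`` the
    load trajectory on that grid.  The transmission deficit

        D(t) = a7_burden * a7_max * sat(d) - mult(t) * attn(x+y) * gpct

    feeds the burden through two week-profiled components.  *Increments* of
    the deficit are stamped in at the sensitivity of the week they occur
    (the consolidation memory that makes the burden path-dependent).  On
    top of that, time spent below the achievable Abeta40 stimulation is
    charged as a *lost-stimulation* level term

        L(t) = mult(t) * attn * 100*delta * (1 - min(x, x0)/x0),

    which is nonzero only while the Abeta40 load sits under the peak
    position x0 — the regime in which suppressing deposition forfeits the
    stimulatory effect.  Both saturate through the two-sided slack
    (explicit Euler; the integrand is smooth and weekly resolution ample):

        dB = p(t) * slack(B) * [ lost_stim_weight * L(t) * dstep + dD ]
    """
    weeks = np.asarray(weeks, dtype=float)
    x = np.asarray(x, dtype=float)
    gp = _gpct(x, y, coupling)
    sat = _a7_response(_a7_deficit(x, y, coupling), params)
    attn = load_attenuation(x, y, params)
    prof = np.interp(weeks, PROFILE_WEEKS, np.asarray(params.glu_profile))
    mult = np.interp(weeks, PROFILE_WEEKS, APOE_GLU_MULT[genotype])
    deficit = params.a7_burden * params.a7_max * sat - mult * attn * gp
    if coupling.x0 > 0:
        lost = 100.0 * coupling.delta * (1.0 - np.minimum(x, coupling.x0) / coupling.x0)
    else:
        lost = np.zeros_like(x)
    lost = params.lost_stim_weight * mult * attn * lost
    out = np.empty_like(weeks)
    b = 0.0
    out[0] = 0.0
    for k in range(1, len(weeks)):
        dstep = (weeks[k] - weeks[k - 1]) / 13.0
        p_mid = 0.5 * (prof[k - 1] + prof[k])
        level = 0.5 * (lost[k - 1] + lost[k]) * dstep
        increment = deficit[k] - deficit[k - 1]
        b += p_mid * _burden_slack(b, params) * (level + increment)
        out[k] = b
    return out


def placebo_reserve(
    week: float,
    genotype: Genotype,
    params: SurrogateParams,
    coupling: CouplingParams = FINAL_PARAMS,
    baseline: tuple[float, float] = (4.0, 4.0),
):
    """Reserve of an untreated AD patient at a trial week (weekly burden grid)."""
    wk = np.arange(0.0, float(week) + 1.0)
    if wk[-1] != week:
        wk = np.append(wk, week)
    rate = BASE_RATES[genotype]
    x = np.minimum(baseline[0] + rate * wk / 13.0, 16.0)
    y = np.minimum(baseline[1] + rate * wk / 13.0, 16.0)
    burden = amyloid_burden(wk, x, y, genotype, coupling, params)[-1]
    state = disease_state("AD", week, genotype)
    return network_reserve(state, params=params, amyloid_burden=burden), burden


def placebo_adas_trajectory(
    eval_weeks,
    genotype: Genotype,
    params: SurrogateParams,
    coupling: CouplingParams = FINAL_PARAMS,
    baseline: tuple[float, float] = (4.0, 4.0),
) -> np.ndarray:
    """Untreated ADAS-Cog at the evaluation weeks (weekly burden grid)."""
    eval_weeks = np.asarray(eval_weeks, dtype=float)
    wk = np.arange(0.0, eval_weeks.max() + 1.0)
    rate = BASE_RATES[genotype]
    x = np.minimum(baseline[0] + rate * wk / 13.0, 16.0)
    y = np.minimum(baseline[1] + rate * wk / 13.0, 16.0)
    burden = amyloid_burden(wk, x, y, genotype, coupling, params)
    out = []
    for w in eval_weeks:
        state = disease_state("AD", w, genotype)
        r = network_reserve(state, params=params, amyloid_burden=burden[int(w)])
        out.append(float(adas_from_reserve(r, params)))
    return np.asarray(out)


def arm_adas_trajectory(
    eval_weeks,
    genotype: Genotype,
    params: SurrogateParams,
    coupling: CouplingParams = FINAL_PARAMS,
    baseline: tuple[float, float] = (4.0, 4.0),
    reduction_x: float = 0.0,
    reduction_y: float = 0.0,
) -> np.ndarray:
    """ADAS-Cog at the evaluation weeks for an arm with reduced deposition."""
    eval_weeks = np.asarray(eval_weeks, dtype=float)
    wk = np.arange(0.0, eval_weeks.max() + 1.0)
    rate = BASE_RATES[genotype]
    x = np.minimum(baseline[0] + rate * (1.0 - reduction_x) * wk / 13.0, 16.0)
    y = np.minimum(baseline[1] + rate * (1.0 - reduction_y) * wk / 13.0, 16.0)
    burden = amyloid_burden(wk, x, y, genotype, coupling, params)
    out = []
    for w in eval_weeks:
        state = disease_state("AD", w, genotype)
        r = network_reserve(state, params=params, amyloid_burden=burden[int(w)])
        out.append(float(adas_from_reserve(r, params)))
    return np.asarray(out)


def apoe_slope_spread(
    params: SurrogateParams,
    coupling: CouplingParams,
    baseline: tuple[float, float] = (4.0, 4.0),
    eval_weeks=(0.0, 12.0, 26.0, 52.0, 78.0),
) -> float:
    """Relative spread, (max-min)/mean, of per-genotype ADAS trajectory slopes."""
    wk = np.asarray(eval_weeks, dtype=float)
    slopes = []
    for geno in ("APOE4-/-", "APOE4+/-", "APOE4+/+"):
        adas = placebo_adas_trajectory(wk, geno, params, coupling, baseline)
        slopes.append(np.polyfit(wk, adas, 1)[0])
    slopes = np.asarray(slopes)
    return float((slopes.max() - slopes.min()) / slopes.mean())


def glu_slope(
    week: float,
    genotype: Genotype,
    params: SurrogateParams,
    coupling: CouplingParams = FINAL_PARAMS,
    baseline: tuple[float, float] = (4.0, 4.0),
    h: float = 1e-3,
) -> float:
    """ADAS-Cog points per % NMDA conductance change at the placebo state.

    Numerically differentiates the surrogate: a 1 % conductance reduction
    sustained for one 13-week step removes one step of glutamate-weighted
    reserve; the finite difference of the ADAS link gives the slope.
    """
    reserve, burden = placebo_reserve(week, genotype, params, coupling, baseline)
    rate = BASE_RATES[genotype]
    xw = min(baseline[0] + rate * week / 13.0, 16.0)
    yw = min(baseline[1] + rate * week / 13.0, 16.0)
    dr = (
        glu_sensitivity(week, params, genotype)
        * float(load_attenuation(xw, yw, params))
        * _burden_slack(burden, params)
    )
    base = adas_from_reserve(reserve, params)
    pert = adas_from_reserve(reserve - dr * h, params)
    return float((pert - base) / h)


# ----------------------------------------------------------------------
# MCI grid evaluation


def mci_adas_grid(coupling: CouplingParams, params: SurrogateParams) -> np.ndarray:
    """ADAS-Cog over the 17x17 integer load grid in the MCI state."""
    xg, yg = np.meshgrid(np.arange(17), np.arange(17), indexing="ij")
    state = disease_state("MCI")
    base = structural_reserve(state, params)
    r = base + mci_amyloid_reserve(
        _gpct(xg, yg, coupling),
        _a7_deficit(xg, yg, coupling),
        params,
        load_attenuation(xg, yg, params),
    )
    return adas_from_reserve(r, params)


def mci_region_means(
    coupling: CouplingParams, cutoff: int, params: SurrogateParams
) -> tuple[float, float]:
    """Unweighted mean MCI ADAS over the Abeta- and Abeta+ grid regions."""
    grid = mci_adas_grid(coupling, params)
    part = region_partition(cutoff, "both-axes")
    return (
        float(grid[part.neg_indices()].mean()),
        float(grid[part.pos_indices()].mean()),
    )


# ----------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class Anchor:
    """One calibration target: a named model quantity and its clinical value.

    ``mode`` is "eq" for a two-sided target, "le" for an upper bound
    (only positive deviations are penalised) or "ge" for a lower bound.
    """

    name: str
    target: float
    weight: float = 1.0
    tol: float = 0.5
    mode: str = "eq"


def default_anchor_set() -> list[Anchor]:
    """Shipped anchors: the clinical values the reduced network is fit to.

    MCI region averages are calibration anchors, so downstream checks of
    those numbers are consistency checks, not independent predictions.
    """
    return [
        Anchor("healthy_adas", 4.5, weight=2.0, tol=0.3),
        Anchor("mci_zero_adas", 4.1, weight=12.0, tol=0.1),
        Anchor("mci_neg_mean", 7.4, weight=5.0, tol=1.0),
        Anchor("mci_pos_mean", 10.4, weight=5.0, tol=1.0),
        Anchor("mci_neg_mean_delta0", 8.4, weight=1.5, tol=1.5),
        Anchor("mci_pos_mean_delta0", 13.0, weight=8.0, tol=1.2),
        Anchor("mci_neg_mean_final", 7.8, weight=6.0, tol=1.2),
        Anchor("mci_pos_mean_final", 11.35, weight=8.0, tol=0.5),
        Anchor("c1_final_neg_margin", 7.6, weight=15.0, tol=0.15, mode="ge"),
        Anchor("c1_final_pos_margin", 11.6, weight=15.0, tol=0.15, mode="le"),
        Anchor("ad_baseline_mm", 20.2, weight=2.0, tol=0.8),
        Anchor("ad_baseline_het", 21.0, weight=2.0, tol=0.8),
        Anchor("ad_baseline_pp", 22.0, weight=2.0, tol=0.8),
        Anchor("apoe_week0_gap", 1.8, weight=8.0, tol=0.25),
        Anchor("placebo_worsening_78", 9.25, weight=5.0, tol=0.75),
        Anchor("placebo_worsening_78_low", 8.5, weight=1.0, tol=1.5),
        Anchor("placebo_worsening_78_high", 10.0, weight=1.0, tol=1.7),
        Anchor("apoe_spread_final", 0.078, weight=60.0, tol=0.032),
        Anchor("apoe_spread_delta0", 0.10, weight=20.0, tol=0.05, mode="le"),
        Anchor("bace_contrast_low_base", -1.5, weight=4.0, tol=0.6),
        Anchor("glu_slope_0", 0.525, weight=6.0, tol=0.12),
        Anchor("glu_slope_12", 0.65, weight=6.0, tol=0.1),
        Anchor("glu_slope_26", 0.65, weight=9.0, tol=0.1),
        Anchor("glu_slope_52", 0.40, weight=10.0, tol=0.1),
        Anchor("glu_slope_78", 0.40, weight=10.0, tol=0.1),
    ]


#: Coupling set with the Abeta40 benefit removed (Fig.-2-style variant).
_DELTA0_PARAMS = replace(MCI_CALIBRATION_PARAMS, delta=0.0)

_FIT_FIELDS = (
    "adas_scale",
    "adas_mid",
    "w_syn",
    "w_neu",
    "w_chol",
    "ad_offset",
    "g_mci",
    "a7_max",
    "a7_half",
    "a7_half_slow",
    "a7_frac_fast",
    "mci_gain_frac",
    "a7_burden",
    "burden_sat",
    "lost_stim_weight",
    "attn_load_half",
    "p0",
    "p12",
    "p26",
    "p52",
    "p78",
)

# Start points for the deterministic multi-start fit; the neuron weight is
# bounded below because the platform attributes the bulk of placebo
# worsening to nonamyloid neuron/synapse loss.
_X0 = np.array(
    [25.0, -65.0, 0.10, 0.40, 0.35, -30.0, 8.0, 28.0, 0.04, 0.30, 0.6, 0.5, 0.06, 25.0, 0.5, 8.0, 1.3, 1.6, 1.6, 1.1, 1.1]
)
_X0_ALT = np.array(
    [32.0, -85.0, 0.10, 0.45, 0.16, -54.0, 7.9, 34.0, 0.03, 0.25, 0.5, 0.4, 0.05, 25.0, 0.3, 7.0, 1.8, 2.6, 2.7, 2.3, 2.5]
)
_X0_ALT2 = np.array(
    [20.0, -55.0, 0.08, 0.30, 0.25, -25.0, 6.0, 25.0, 0.05, 0.35, 0.7, 0.6, 0.10, 35.0, 0.7, 9.0, 0.8, 1.2, 1.4, 1.0, 1.0]
)
_X0_ALT3 = np.array(
    [60.0, -160.0, 0.14, 1.08, 0.32, -100.0, 18.7, 64.5, 0.03, 0.30, 0.6, 0.5, 0.01, 20.0, 0.31, 9.0, 2.97, 4.0, 4.22, 3.55, 4.37]
)
_STARTS = (_X0, _X0_ALT, _X0_ALT2, _X0_ALT3)
_LOWER = np.array(
    [8.0, -250.0, 0.0, 0.25, 0.0, -120.0, 0.0, 0.0, 0.02, 0.08, 0.2, 0.1, 0.0, 20.0, 0.0, 4.0, 0.0, 0.0, 0.0, 0.0, 0.0]
)
_UPPER = np.array(
    [60.0, -10.0, 2.0, 1.5, 2.0, 0.0, 40.0, 150.0, 0.5, 0.60, 1.0, 1.0, 1.0, 60.0, 2.0, 9.0, 6.0, 6.0, 6.0, 6.0, 6.0]
)

def _theta_to_params(theta: np.ndarray) -> SurrogateParams:
    t = dict(zip(_FIT_FIELDS, (float(v) for v in theta)))
    return SurrogateParams(
        adas_scale=t["adas_scale"],
        adas_mid=t["adas_mid"],
        w_syn=t["w_syn"],
        w_neu=t["w_neu"],
        w_chol=t["w_chol"],
        ad_offset=t["ad_offset"],
        g_mci=t["g_mci"],
        a7_max=t["a7_max"],
        a7_half=t["a7_half"],
        a7_half_slow=t["a7_half_slow"],
        a7_frac_fast=t["a7_frac_fast"],
        mci_gain_frac=t["mci_gain_frac"],
        a7_burden=t["a7_burden"],
        burden_sat=t["burden_sat"],
        lost_stim_weight=t["lost_stim_weight"],
        attn_load_half=t["attn_load_half"],
        glu_profile=(t["p0"], t["p12"], t["p26"], t["p52"], t["p78"]),
    )


def evaluate_anchor(name: str, params: SurrogateParams) -> float:
    """Model value of a named calibration quantity."""
    if name == "healthy_adas":
        return float(adas_from_reserve(0.0, params))
    if name == "mci_zero_adas":
        r = structural_reserve(disease_state("MCI"), params)
        return float(adas_from_reserve(r, params))
    if name in ("mci_neg_mean", "mci_pos_mean"):
        neg, pos = mci_region_means(MCI_CALIBRATION_PARAMS, 3, params)
        return neg if name == "mci_neg_mean" else pos
    if name in ("mci_neg_mean_delta0", "mci_pos_mean_delta0"):
        neg, pos = mci_region_means(_DELTA0_PARAMS, 3, params)
        return neg if name.startswith("mci_neg") else pos
    if name in ("mci_pos_weak_delta0", "c1_weak_delta0_excl"):
        weak = CouplingParams(x0=2, delta=0.0, alpha=0.0005, alpha_star=0.0005, beta=0.025)
        return mci_region_means(weak, 3, params)[1]
    if name in ("mci_neg_mean_final", "mci_pos_mean_final"):
        neg, pos = mci_region_means(FINAL_PARAMS, 3, params)
        return neg if name.startswith("mci_neg") else pos
    if name in ("c1_final_neg_margin", "c1_final_pos_margin"):
        neg, pos = mci_region_means(FINAL_PARAMS, 3, params)
        return neg if "neg" in name else pos
    if name.startswith("ad_baseline"):
        geno: Genotype = {
            "ad_baseline_mm": "APOE4-/-",
            "ad_baseline_het": "APOE4+/-",
            "ad_baseline_pp": "APOE4+/+",
        }[name]
        r = structural_reserve(disease_state("AD", 0.0, geno), params)
        return float(adas_from_reserve(r, params))
    if name.startswith("placebo_worsening_78"):
        baseline = {
            "placebo_worsening_78": (4.0, 4.0),
            "placebo_worsening_78_low": (1.0, 1.0),
            "placebo_worsening_78_high": (8.0, 8.0),
        }[name]
        adas = placebo_adas_trajectory([0.0, 78.0], "APOE4+/-", params, baseline=baseline)
        return float(adas[1] - adas[0])
    if name == "apoe_week0_gap":
        r_mm = structural_reserve(disease_state("AD", 0.0, "APOE4-/-"), params)
        r_pp = structural_reserve(disease_state("AD", 0.0, "APOE4+/+"), params)
        return float(adas_from_reserve(r_pp, params) - adas_from_reserve(r_mm, params))
    if name == "apoe_spread_delta0":
        return apoe_slope_spread(params, replace(FINAL_PARAMS, delta=0.0))
    if name == "apoe_spread_final":
        return apoe_slope_spread(params, FINAL_PARAMS)
    if name.startswith("bace_contrast"):
        baseline = (0.0, 0.0) if name.endswith("low_base") else (8.0, 8.0)
        wk = [0.0, 78.0]
        pla = placebo_adas_trajectory(wk, "APOE4+/-", params, baseline=baseline)
        trt = arm_adas_trajectory(
            wk, "APOE4+/-", params, baseline=baseline, reduction_x=0.80, reduction_y=0.60
        )
        return float(pla[1] - trt[1])
    if name.startswith("glu_slope_"):
        week = float(name.rsplit("_", 1)[1])
        return glu_slope(week, "APOE4+/-", params)
    raise KeyError(f"unknown anchor {name!r}")


def calibrate_surrogate(
    anchors: Sequence[Anchor] | None = None,
    x0: np.ndarray | None = None,
    residual_tol: float = 1.0,
) -> tuple[SurrogateParams, dict]:
    """Weighted least-squares fit of the surrogate to the anchor set.

    Deterministic given the fixed start point and optimizer settings.
    Returns the fitted parameters and a report with per-anchor residuals;
    raises ``RuntimeError`` listing the worst anchors if any weighted
    residual exceeds ``residual_tol`` times its anchor tolerance.
    """
    anchors = list(anchors) if anchors is not None else default_anchor_set()
    starts = [np.asarray(x0, dtype=float)] if x0 is not None else [s.copy() for s in _STARTS]

    # weak priors keep the two soft directions (a7 knee, synapse weight)
    # from drifting; they carry negligible weight next to the anchors
    priors = [("a7_half", 0.05, 0.05), ("w_syn", 0.10, 0.05), ("attn_load_half", 8.0, 0.05)]
    prior_idx = [_FIT_FIELDS.index(n) for n, _, _ in priors]

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _theta_to_params(theta)
        res = []
        for a in anchors:
            diff = evaluate_anchor(a.name, p) - a.target
            if a.mode == "le":
                diff = max(0.0, diff)
            elif a.mode == "ge":
                diff = min(0.0, diff)
            res.append(a.weight * diff)
        for (name, target, w), idx in zip(priors, prior_idx):
            res.append(w * (theta[idx] - target))
        return np.asarray(res)

    fit = min(
        (
            least_squares(
                residuals, s, bounds=(_LOWER, _UPPER), method="trf", xtol=1e-12, ftol=1e-12
            )
            for s in starts
        ),
        key=lambda f: f.cost,
    )
    params = _theta_to_params(fit.x)
    report = {
        "anchors": [
            {
                "name": a.name,
                "target": a.target,
                "value": evaluate_anchor(a.name, params),
                "tol": a.tol,
            }
            for a in anchors
        ],
        "cost": float(fit.cost),
        "success": bool(fit.success),
    }
    worst = []
    for a, e in zip(anchors, report["anchors"]):
        diff = e["value"] - e["target"]
        if a.mode == "le":
            diff = max(0.0, diff)
        elif a.mode == "ge":
            diff = min(0.0, diff)
        if abs(diff) > residual_tol * e["tol"]:
            worst.append(e)
    report["out_of_tolerance"] = worst
    if worst:
        names = ", ".join(f"{e['name']} ({e['value']:.2f} vs {e['target']})" for e in worst)
        raise RuntimeError(f"surrogate calibration failed for anchors: {names}")
    return params, report
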