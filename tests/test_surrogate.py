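"""Cognition surrogate: links, reserve structure and calibration."""

import numpy as np
import pytest

from abqsp.coupling import FINAL_PARAMS, MCI_CALIBRATION_PARAMS
from abqsp.params import run_calibration
from abqsp.surrogate import (
    accuracy_from_reserve,
    adas_from_reserve,
    calibrate_surrogate,
    default_anchor_set,
    disease_state,
    glu_slope,
    mci_region_means,
    network_reserve,
    placebo_adas_trajectory,
)


def test_disease_state_constants():
    mci = disease_state("MCI")
    assert mci.synapse_density == pytest.approx(0.97)
    assert mci.neuron_density == pytest.approx(0.97)
    assert mci.cholinergic_tone == pytest.approx(1.3)
    ad = disease_state("AD", 78, "APOE4+/-")
    assert ad.synapse_density == pytest.approx(1 - 0.0004 * 78)
    assert ad.neuron_density == pytest.approx(1 - 0.0035 * 78)
    assert ad.cholinergic_tone == pytest.approx(0.7)
    # genotype synapse modifiers of +/-20 %
    assert disease_state("AD", 0, "APOE4+/+").synapse_density == pytest.approx(0.8)
    assert disease_state("AD", 0, "APOE4-/-").synapse_density == pytest.approx(1.2)


def test_links_bounded_and_monotone(surrogate):
    reserves = np.linspace(-300, 150, 400)
    adas = adas_from_reserve(reserves, surrogate)
    acc = accuracy_from_reserve(reserves, surrogate)
    assert np.all((adas >= 0) & (adas <= 70))
    assert np.all((acc >= 0) & (acc <= 100))
    assert np.all(np.diff(adas) <= 0)  # more reserve, better cognition
    assert np.all(np.diff(acc) >= 0)
    # saturation at the extremes
    assert adas_from_reserve(1e6, surrogate) == pytest.approx(0.0, abs=1e-6)
    assert accuracy_from_reserve(1e6, surrogate) == pytest.approx(100.0, abs=1e-6)


def test_reserve_linear_in_deficits(surrogate):
    state = disease_state("MCI")
    base = network_reserve(state, 1.0, 1.0, surrogate)
    up = network_reserve(state, 1.01, 1.0, surrogate)
    up2 = network_reserve(state, 1.02, 1.0, surrogate)
    assert up > base  # a conductance gain increases reserve
    assert up2 - up == pytest.approx(up - base)  # and does so linearly


def test_monotonicity_in_each_deficit(surrogate):
    """More amyloid deficit never improves ADAS, never raises accuracy."""
    state = disease_state("MCI")
    for g in (1.0, 0.99, 0.97):
        r_better = network_reserve(state, g, 0.9, surrogate)
        r_worse = network_reserve(state, g, 0.7, surrogate)
        assert adas_from_reserve(r_worse, surrogate) >= adas_from_reserve(r_better, surrogate)
        assert accuracy_from_reserve(r_worse, surrogate) <= accuracy_from_reserve(
            r_better, surrogate
        )


def test_accuracy_sensitivity_peaks_at_intermediate_impairment(surrogate):
    """d(accuracy)/d(deficit) is maximal at mid impairment, not the extremes."""
    state = disease_state("MCI")
    h = 1.0

    def deriv(extra_deficit):
        r = network_reserve(state, 1.0, 1.0, surrogate) - extra_deficit
        return accuracy_from_reserve(r, surrogate) - accuracy_from_reserve(r - h, surrogate)

    low, mid, high = deriv(0.0), deriv(-surrogate.acc_mid), deriv(-2.5 * surrogate.acc_mid)
    assert mid > low and mid > high


def test_shipped_anchor_residuals_within_tolerance(surrogate):
    """The shipped fit reproduces every anchor within its stated tolerance."""
    from abqsp.surrogate import evaluate_anchor

    for anchor in default_anchor_set():
        value = evaluate_anchor(anchor.name, surrogate)
        diff = value - anchor.target
        if anchor.mode == "le":
            diff = max(0.0, diff)
        elif anchor.mode == "ge":
            diff = min(0.0, diff)
        assert abs(diff) <= anchor.tol, f"{anchor.name}: {value} vs {anchor.target}"


def test_recalibration_reproduces_shipped_parameters(surrogate, receptor):
    """The calibration is deterministic: refitting regenerates the shipped file."""
    bundle = run_calibration()
    for key, value in bundle["surrogate"].items():
        shipped_value = getattr(surrogate, key)
        if key == "glu_profile":
            assert np.allclose(value, shipped_value, rtol=1e-6)
        else:
            assert value == pytest.approx(shipped_value, rel=1e-6, abs=1e-9)
    assert bundle["receptor"]["w_m1"] == pytest.approx(receptor.w_m1, rel=1e-6)


def test_mci_region_means_and_healthy_anchors(surrogate):
    """Calibration-consistency: the MCI anchor values are reproduced."""
    state_r = network_reserve(disease_state("MCI"), 1.0, 1.0, surrogate)
    assert adas_from_reserve(state_r, surrogate) == pytest.approx(4.1, abs=0.1)
    neg, pos = mci_region_means(MCI_CALIBRATION_PARAMS, 3, surrogate)
    assert neg == pytest.approx(7.4, abs=1.0)
    assert pos == pytest.approx(10.4, abs=1.0)
    # removing the Abeta40 benefit drives the amyloid-positive mean far out
    from dataclasses import replace

    neg0, pos0 = mci_region_means(replace(MCI_CALIBRATION_PARAMS, delta=0.0), 3, surrogate)
    assert pos0 > pos + 1.5
    # at cutoff 2 without the benefit the amyloid-positive group stays high
    _, pos0_c2 = mci_region_means(replace(MCI_CALIBRATION_PARAMS, delta=0.0), 2, surrogate)
    assert pos0_c2 > 11.0


def test_glu_slope_week_profile(surrogate):
    """ADAS sensitivity to conductance peaks mid-trial and decays late."""
    s12 = glu_slope(12, "APOE4+/-", surrogate)
    s26 = glu_slope(26, "APOE4+/-", surrogate)
    s52 = glu_slope(52, "APOE4+/-", surrogate)
    s78 = glu_slope(78, "APOE4+/-", surrogate)
    s0 = glu_slope(0, "APOE4+/-", surrogate)
    assert s12 == pytest.approx(0.65, abs=0.1)
    assert s26 == pytest.approx(0.65, abs=0.1)
    assert s52 == pytest.approx(0.40, abs=0.1)
    assert s78 == pytest.approx(0.40, abs=0.1)
    assert min(s52, s78) < s0 < max(s12, s26)  # week 0 intermediate


def test_placebo_trajectories_nondecreasing(surrogate):
    """Untreated ADAS never improves with trial time, any genotype/baseline."""
    weeks = np.arange(0.0, 79.0, 6.0)
    for geno in ("APOE4-/-", "APOE4+/-", "APOE4+/+"):
        for base in ((0.0, 0.0), (4.0, 4.0), (12.0, 12.0)):
            adas = placebo_adas_trajectory(weeks, geno, surrogate, FINAL_PARAMS, base)
            assert np.all(np.diff(adas) >= -1e-9), (geno, base)


def test_apoe_baseline_ordering_without_fitting_it(surrogate):
    """APOE4+/+ starts at least 1.5 points worse than APOE4-/- at week 0."""
    weeks = np.array([0.0])
    mm = placebo_adas_trajectory(weeks, "APOE4-/-", surrogate)[0]
    het = placebo_adas_trajectory(weeks, "APOE4+/-", surrogate)[0]
    pp = placebo_adas_trajectory(weeks, "APOE4+/+", surrogate)[0]
    assert mm < het < pp
    assert pp - mm >= 1.5


def test_calibration_failure_reports_worst_anchors():
    from abqsp.surrogate import Anchor

    impossible = [Anchor("healthy_adas", 40.0, weight=1.0, tol=0.1)]
    with pytest.raises(RuntimeError, match="healthy_adas"):
        calibrate_surrogate(anchors=impossible, residual_tol=0.01)
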