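"""Virtual trial engine: trajectories, contrasts, SUVR map, APOE slopes."""

import numpy as np
import pandas as pd
import pytest

from abqsp.coupling import FINAL_PARAMS, AbetaLoad
from abqsp.pharmacodynamics import INTERVENTION_LIBRARY, InterventionPD
from abqsp.trial import (
    Patient,
    SuvrMap,
    TrialSpec,
    apoe_slope_analysis,
    mci_region_averages,
    simulate_patient,
    simulate_trial,
    suvr_to_units,
    units_to_suvr,
)


@pytest.fixture(scope="module")
def het_patient():
    return Patient(patient_id=0, genotype="APOE4+/-", baseline=AbetaLoad(4, 4))


@pytest.fixture(scope="module")
def basic_spec():
    return TrialSpec(arms={"placebo": None})


class TestSuvrMap:
    def test_anchors(self):
        assert units_to_suvr(0) == pytest.approx(1.0)
        assert units_to_suvr(3) == pytest.approx(1.34)

    def test_round_trip_identity(self):
        for units in (0.0, 2.7, 3.0, 11.4, 16.0):
            assert suvr_to_units(units_to_suvr(units)) == pytest.approx(units, abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            units_to_suvr(17)
        with pytest.raises(ValueError):
            suvr_to_units(0.9)
        with pytest.raises(ValueError):
            suvr_to_units(units_to_suvr(16) + 0.5)

    def test_custom_map(self):
        flat = SuvrMap(intercept=1.0, slope=0.1)
        assert units_to_suvr(5, flat) == pytest.approx(1.5)


class TestSimulatePatient:
    def test_zero_reduction_arm_identical_to_placebo(self, het_patient, basic_spec, surrogate):
        placebo = simulate_patient(het_patient, "placebo", None, basic_spec, surrogate)
        sham = InterventionPD("sham", 0.0, 0.0)
        treated = simulate_patient(het_patient, "sham", sham, basic_spec, surrogate)
        assert np.array_equal(placebo.adas, treated.adas)
        assert np.array_equal(placebo.load_x, treated.load_x)

    def test_placebo_worsening_in_printed_range(self, het_patient, basic_spec, surrogate):
        rec = simulate_patient(het_patient, "placebo", None, basic_spec, surrogate)
        change = rec.adas[-1] - rec.adas[0]
        assert 8.5 <= change <= 10.0

    def test_determinism(self, het_patient, basic_spec, surrogate):
        a = simulate_patient(het_patient, "placebo", None, basic_spec, surrogate)
        b = simulate_patient(het_patient, "placebo", None, basic_spec, surrogate)
        assert np.array_equal(a.adas, b.adas)

    def test_treated_arm_week13_uses_printed_weights(self, surrogate):
        """The engine's effect read after one 13-week step on low-dose BACE-I
        equals the weighted sum with the printed factors on cells {4,5,6}."""
        from abqsp.coupling import build_effect_matrix
        from abqsp.pharmacodynamics import quadrature_weights, treated_center

        spec = TrialSpec(arms={"placebo": None}, eval_weeks=(0.0, 13.0))
        patient = Patient(0, "APOE4+/-", AbetaLoad(4, 4))
        bace = INTERVENTION_LIBRARY["BACE-I-low"]
        rec = simulate_patient(patient, "bace", bace, spec, surrogate)
        assert rec.load_x[1] == pytest.approx(4.2)
        assert rec.load_y[1] == pytest.approx(4.4)
        matrix = build_effect_matrix(spec.coupling)
        qx = quadrature_weights(4.2, center=treated_center(4.2, True))
        qy = quadrature_weights(4.4, center=treated_center(4.4, True))
        assert qx.weights == pytest.approx((0.7333, 0.3333, -0.0667), abs=5e-4)
        expected = sum(
            wx * wy * matrix.g_ratio[sx, sy]
            for wx, sx in zip(qx.weights, qx.support)
            for wy, sy in zip(qy.weights, qy.support)
        )
        assert rec.g_ratio[1] == pytest.approx(expected, abs=1e-12)

    def test_record_frame_columns(self, het_patient, basic_spec, surrogate):
        frame = simulate_patient(het_patient, "placebo", None, basic_spec, surrogate).to_frame()
        assert list(frame.columns) == [
            "patient_id", "arm", "genotype", "week", "load_x", "load_y", "suvr", "adas",
        ]


class TestSimulateTrial:
    def test_all_placebo_arms_contrast_zero(self, surrogate):
        spec = TrialSpec(arms={"placebo": None, "placebo2": None})
        cohort = [Patient(0, "APOE4+/-", AbetaLoad(6, 6))]
        res = simulate_trial(spec, cohort, surrogate)
        assert np.allclose(res.summaries["points_better_than_placebo"], 0.0)

    def test_missing_placebo_rejected(self):
        with pytest.raises(ValueError):
            TrialSpec(arms={"BACE-I-low": INTERVENTION_LIBRARY["BACE-I-low"]})

    def test_high_baseline_all_arms_improve_with_ordering(self, surrogate):
        """At baseline 8 every intervention beats placebo at 78 weeks, with
        BACE-I >= GSI >= solanezumab."""
        arms = {"placebo": None}
        arms.update({k: INTERVENTION_LIBRARY[k] for k in (
            "BACE-I-low", "GSI-low", "solanezumab-low")})
        spec = TrialSpec(arms=arms)
        cohort = [Patient(0, "APOE4+/-", AbetaLoad(8, 8))]
        res = simulate_trial(spec, cohort, surrogate)
        final = res.summaries[res.summaries.week == 78].set_index("arm")
        bace = final.loc["BACE-I-low", "points_better_than_placebo"]
        gsi = final.loc["GSI-low", "points_better_than_placebo"]
        sola = final.loc["solanezumab-low", "points_better_than_placebo"]
        assert bace > 0 and gsi > 0 and sola > 0
        assert bace >= gsi >= sola

    def test_contrast_saturates_at_extreme_baseline(self, surrogate):
        spec = TrialSpec(arms={"placebo": None, "BACE-I-high": INTERVENTION_LIBRARY["BACE-I-high"]})
        cohort = [Patient(0, "APOE4+/-", AbetaLoad(12, 12))]
        res = simulate_trial(spec, cohort, surrogate)
        final = res.summaries[(res.summaries.week == 78) & (res.summaries.arm == "BACE-I-high")]
        assert float(final["points_better_than_placebo"].iloc[0]) <= 2.5

    def test_low_baseline_bace_worsens(self, surrogate):
        """From an amyloid-negative start, suppressing Abeta40 deposition
        forfeits its stimulatory range and worsens cognition by 1-2 points."""
        spec = TrialSpec(arms={"placebo": None, "BACE-I-low": INTERVENTION_LIBRARY["BACE-I-low"]})
        cohort = [Patient(0, "APOE4+/-", AbetaLoad(0, 0))]
        res = simulate_trial(spec, cohort, surrogate)
        final = res.summaries[(res.summaries.week == 78) & (res.summaries.arm == "BACE-I-low")]
        contrast = float(final["points_better_than_placebo"].iloc[0])
        assert -2.5 <= contrast <= -0.5


class TestMciRegionAverages:
    def test_positive_exceeds_negative_when_abeta42_harms(self, surrogate):
        neg, pos = mci_region_averages(FINAL_PARAMS, 3, surrogate)
        assert pos > neg

    def test_empty_region_rejected(self, surrogate):
        with pytest.raises(ValueError):
            mci_region_averages(FINAL_PARAMS, 0, surrogate)


class TestApoeSlopes:
    def test_slope_spread_and_gap_at_final_params(self, surrogate):
        table = apoe_slope_analysis(AbetaLoad(4, 4), FINAL_PARAMS, surrogate)
        assert table.attrs["max_pairwise_rel_diff"] <= 0.10
        assert table.attrs["week0_gap_pp_mm"] >= 1.5

    def test_identical_without_genotype_mechanisms(self, surrogate):
        """With equal deposition and no synapse modifiers the genotypes
        collapse onto one trajectory (glutamate multipliers aside, week 0)."""
        table = apoe_slope_analysis(AbetaLoad(4, 4), FINAL_PARAMS, surrogate)
        # week-0 ordering comes from the synapse modifier alone
        w0 = table.set_index("genotype")["week0_adas"]
        assert w0["APOE4-/-"] < w0["APOE4+/-"] < w0["APOE4+/+"]
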