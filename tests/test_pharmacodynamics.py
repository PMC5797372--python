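"""Deposition schedules, intervention pharmacodynamics and quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abqsp.coupling import AbetaLoad, CouplingParams, build_effect_matrix
from abqsp.pharmacodynamics import (
    INTERVENTION_LIBRARY,
    DepositionSchedule,
    InterventionPD,
    deposition_rate,
    load_trajectory,
    quadrature_weights,
    sample_matrix_average,
    treated_center,
)


@pytest.mark.parametrize(
    "genotype, intervention, expected",
    [
        ("APOE4+/-", None, (1.0, 1.0)),
        ("APOE4+/-", INTERVENTION_LIBRARY["GSI-low"], (0.6, 0.8)),
        ("APOE4+/+", None, (1.5, 1.5)),
        ("APOE4-/-", None, (0.5, 0.5)),
        ("APOE4+/-", INTERVENTION_LIBRARY["BACE-I-high"], (0.1, 0.2)),
    ],
)
def test_deposition_rates(genotype, intervention, expected):
    sched = deposition_rate(genotype, intervention)
    assert sched.rate_x == pytest.approx(expected[0])
    assert sched.rate_y == pytest.approx(expected[1])


def test_reduction_out_of_range_rejected():
    with pytest.raises(ValueError):
        InterventionPD("bad", 1.2, 0.5)


def test_load_trajectory_linear_growth_and_clamp():
    start = AbetaLoad(4, 4)
    placebo = deposition_rate("APOE4+/-")
    loads = load_trajectory(start, placebo, [0, 13, 78])
    assert (loads[1].x, loads[1].y) == (5, 5)
    assert (loads[2].x, loads[2].y) == (10, 10)
    fast = deposition_rate("APOE4+/+")
    clamped = load_trajectory(AbetaLoad(13, 13), fast, [78])
    assert clamped[0].x == 16  # saturates at the top of the grid

    zero = DepositionSchedule(0.0, 0.0, "APOE4+/-")
    for load in load_trajectory(start, zero, [0, 26, 78]):
        assert (load.x, load.y) == (4, 4)


def test_deposition_monotone_across_genotypes():
    start = AbetaLoad(2, 2)
    weeks = [0, 12, 26, 52, 78]
    mm = load_trajectory(start, deposition_rate("APOE4-/-"), weeks)
    het = load_trajectory(start, deposition_rate("APOE4+/-"), weeks)
    pp = load_trajectory(start, deposition_rate("APOE4+/+"), weeks)
    for a, b, c in zip(mm, het, pp):
        assert a.x <= b.x <= c.x and a.y <= b.y <= c.y


class TestQuadratureWeights:
    def test_printed_low_dose_bace_weights(self):
        """80 % Abeta40 suppression from load 4: effective load 4.2 on {4,5,6}."""
        effective = 4 + 1.0 * (1 - 0.80)  # one 13-week step
        q = quadrature_weights(effective, center=treated_center(effective, reduced=True))
        assert q.support == (4, 5, 6)
        assert q.weights == pytest.approx((0.7333, 0.3333, -0.0667), abs=5e-4)
        # Abeta42 axis: 60 % suppression gives effective load 4.4
        q42 = quadrature_weights(4.4, center=treated_center(4.4, reduced=True))
        assert q42.weights == pytest.approx((0.6333, 0.3333, 0.0333), abs=5e-4)

    def test_integer_load_gives_equal_thirds(self):
        q = quadrature_weights(5.0)
        assert q.support == (4, 5, 6)
        assert q.weights == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_mass_and_normalisation_identities(self):
        """Sum-to-one and mass-mean identities hold to 1e-12 everywhere."""
        rng = np.random.default_rng(7)
        for load in rng.uniform(0, 16, size=1000):
            q = quadrature_weights(load)
            assert abs(sum(q.weights) - 1.0) < 1e-12
            mean = sum(w * s for w, s in zip(q.weights, q.support))
            assert abs(mean - load) < 1e-12
            assert q.weights[1] == pytest.approx(1 / 3)

    def test_edges_shift_support_inward(self):
        assert quadrature_weights(0.3).support == (0, 1, 2)
        assert quadrature_weights(15.9).support == (14, 15, 16)
        with pytest.raises(ValueError):
            quadrature_weights(16.5)

    def test_placebo_arms_keep_round_anchoring(self):
        assert treated_center(4.2, reduced=False) is None
        assert treated_center(5.0, reduced=True) is None
        assert treated_center(4.2, reduced=True) == 5


class TestSampleMatrixAverage:
    def test_constant_matrix_returns_constant(self):
        assert sample_matrix_average(lambda x, y: (3.5, 0.25), AbetaLoad(4, 4)) == pytest.approx(
            (3.5, 0.25)
        )

    def test_integer_load_is_plain_block_mean(self):
        """At (4, 4) the sample equals the mean over 3<=x<=5, 3<=y<=5."""
        matrix = build_effect_matrix(CouplingParams())
        g, a7 = sample_matrix_average(matrix, AbetaLoad(4, 4))
        block_g = matrix.g_ratio[3:6, 3:6].mean()
        block_a7 = matrix.a7_factor[3:6, 3:6].mean()
        assert g == pytest.approx(block_g, abs=1e-12)
        assert a7 == pytest.approx(block_a7, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        x=st.floats(1, 15), y=st.floats(1, 15),
        a=st.floats(-2, 2), b=st.floats(-2, 2), c=st.floats(-2, 2),
    )
    def test_affine_functions_reproduced_exactly(self, x, y, a, b, c):
        """The mass-mean constraint makes the sampling exact on affine cells."""
        g, _ = sample_matrix_average(lambda i, j: (a * i + b * j + c, 0.0), AbetaLoad(x, y))
        assert g == pytest.approx(a * x + b * y + c, abs=1e-9)

    def test_oracle_brute_force_equivalence(self):
        """Engine sampling equals an independently recomputed weighted sum."""
        params = CouplingParams(x0=2, delta=0.025, alpha=0.002, alpha_star=0.002, beta=0.03)
        matrix = build_effect_matrix(params)
        rng = np.random.default_rng(11)
        for _ in range(100):
            load = AbetaLoad(rng.uniform(1, 15), rng.uniform(1, 15))
            got = sample_matrix_average(matrix, load)
            qx = quadrature_weights(load.x)
            qy = quadrature_weights(load.y)
            expect_g = sum(
                wx * wy * matrix.g_ratio[sx, sy]
                for wx, sx in zip(qx.weights, qx.support)
                for wy, sy in zip(qy.weights, qy.support)
            )
            expect_a7 = sum(
                wx * wy * matrix.a7_factor[sx, sy]
                for wx, sx in zip(qx.weights, qx.support)
                for wy, sy in zip(qy.weights, qy.support)
            )
            assert got[0] == pytest.approx(expect_g, abs=1e-12)
            assert got[1] == pytest.approx(expect_a7, abs=1e-12)
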