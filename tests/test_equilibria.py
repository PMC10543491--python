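"""Equilibrium enumeration, Jacobian, stability labels, regimes, area rule."""

import numpy as np
import pytest

from fraudgame import (
    NotAnEquilibriumError,
    RegimeError,
    StrategyState,
    area_rule,
    bracket_coefficients,
    classify_case,
    classify_equilibria,
    classify_point,
    condition_values,
    enumerate_equilibria,
    interior_equilibrium,
    jacobian,
    predict_attractor,
    replicator_rhs,
)

#: Expected (det sign, trace sign or None, label) per corner E, S, N, K and
#: the interior point, for each regime.  None means the trace sign is not
#: constrained.
REGIME_PATTERNS = {
    "case1": {
        (0.0, 0.0): (1, -1, "ESS"),
        (0.0, 1.0): (-1, None, "saddle"),
        (1.0, 0.0): (-1, None, "saddle"),
        (1.0, 1.0): (1, 1, "unstable"),
    },
    "case2": {
        (0.0, 0.0): (1, 1, "unstable"),
        (0.0, 1.0): (-1, None, "saddle"),
        (1.0, 0.0): (-1, None, "saddle"),
        (1.0, 1.0): (1, -1, "ESS"),
    },
    "case3": {
        (0.0, 0.0): (1, -1, "ESS"),
        (0.0, 1.0): (1, 1, "unstable"),
        (1.0, 0.0): (1, 1, "unstable"),
        (1.0, 1.0): (1, -1, "ESS"),
        "interior": (-1, 0, "saddle"),
    },
}


class TestInteriorEquilibrium:
    def test_baseline_condition_values_and_coordinates(self, baseline):
        ie = interior_equilibrium(baseline)
        assert ie.A2 == pytest.approx(3.3)
        assert ie.B2 == pytest.approx(7.9)
        assert ie.A1 == pytest.approx(4.4)
        assert ie.B1 == pytest.approx(9.1)
        assert ie.x_star == pytest.approx(3.3 / 7.9)
        assert ie.y_star == pytest.approx(4.4 / 9.1)
        assert ie.exists

    def test_interior_point_is_a_fixed_point(self, baseline):
        ie = interior_equilibrium(baseline)
        v = replicator_rhs(baseline, StrategyState(ie.x_star, ie.y_star))
        assert abs(v.F) < 1e-10 and abs(v.G) < 1e-10

    def test_condition_values_match_bracket_coefficients(self, any_samples):
        """A1 = -a1, B1 = b1, A2 = -a2, B2 = b2: the regime conditions are
        the negated intercepts and the slopes of the replicator brackets."""
        for p in any_samples[:50]:
            a1, b1, a2, b2 = bracket_coefficients(p)
            A1, B1, A2, B2 = condition_values(p)
            assert A1 == pytest.approx(-a1, abs=1e-12)
            assert B1 == pytest.approx(b1, abs=1e-12)
            assert A2 == pytest.approx(-a2, abs=1e-12)
            assert B2 == pytest.approx(b2, abs=1e-12)

    def test_honesty_dominant_regime_has_no_interior_point(self, case1_samples):
        for p in case1_samples[:50]:
            ie = interior_equilibrium(p)
            assert not ie.exists
            assert ie.x_star > 1.0 and ie.y_star > 1.0
            assert len(enumerate_equilibria(p)) == 4

    def test_baseline_has_five_equilibria(self, baseline):
        assert len(enumerate_equilibria(baseline)) == 5


class TestJacobian:
    def test_baseline_origin(self, baseline):
        J = jacobian(baseline, StrategyState(0.0, 0.0))
        assert J[0, 0] == pytest.approx(-4.4)
        assert J[1, 1] == pytest.approx(-3.3)
        assert J[0, 1] == 0.0 and J[1, 0] == 0.0

    def test_baseline_collusion_corner(self, baseline):
        J = jacobian(baseline, StrategyState(1.0, 1.0))
        assert J[0, 0] == pytest.approx(-(-4.4 + 9.1))  # -4.7
        assert J[1, 1] == pytest.approx(-(-3.3 + 7.9))  # -4.6

    def test_half_frequency_kills_the_diagonal(self, any_samples):
        """At x = 1/2 the (1-2x) factor annihilates dF/dx regardless of the
        bracket value (and symmetrically at y = 1/2)."""
        for p in any_samples[:20]:
            J = jacobian(p, StrategyState(0.5, 0.5))
            assert J[0, 0] == 0.0 and J[1, 1] == 0.0

    def test_matches_finite_differences(self, any_samples, rng):
        h = 1e-6
        for p in any_samples[:40]:
            x, y = 0.05 + 0.9 * rng.random(2)
            J = jacobian(p, StrategyState(x, y))

            def F(x, y):
                v = replicator_rhs(p, StrategyState(x, y))
                return np.array([v.F, v.G])

            fd = np.column_stack([
                (F(x + h, y) - F(x - h, y)) / (2 * h),
                (F(x, y + h) - F(x, y - h)) / (2 * h),
            ])
            assert np.allclose(J, fd, atol=1e-6)


class TestClassifyPoint:
    def test_baseline_corner_labels(self, baseline):
        r = classify_point(baseline, (0.0, 0.0))
        assert r.det == pytest.approx(14.52)
        assert r.trace == pytest.approx(-7.7)
        assert r.label == "ESS"
        r = classify_point(baseline, (0.0, 1.0))
        assert r.det == pytest.approx(4.7 * 3.3)
        assert r.trace == pytest.approx(8.0)
        assert r.label == "unstable"

    def test_baseline_interior_saddle(self, baseline):
        ie = interior_equilibrium(baseline)
        r = classify_point(baseline, (ie.x_star, ie.y_star))
        assert r.det < 0
        assert r.trace == pytest.approx(0.0, abs=1e-9)
        assert r.label == "saddle"

    def test_non_equilibrium_is_rejected_with_magnitude(self, baseline):
        with pytest.raises(NotAnEquilibriumError, match=r"\|\(F, G\)\|"):
            classify_point(baseline, (0.5, 0.5))


class TestRegimes:
    def test_baseline_is_bistable(self, baseline):
        assert classify_case(baseline).case_id == "case3"

    def test_prohibitive_fraud_costs_give_honesty_dominance(self, baseline):
        p = baseline.replace(C1=30.0, C2=30.0)
        label = classify_case(p)
        assert label.case_id == "case1"
        assert label.A1 == pytest.approx(31.4)
        assert label.A2 == pytest.approx(31.3)

    def test_no_costs_no_penalties_give_fraud_dominance(self, baseline):
        p = baseline.replace(C1=0.0, C2=0.0, P1=0.0, P2=0.0)
        label = classify_case(p)
        assert label.case_id == "case2"
        assert label.A1 == pytest.approx(-3.6)
        assert label.A2 == pytest.approx(-1.7)

    def test_sampled_regimes_are_recognised(self, case1_samples, case2_samples,
                                            case3_samples):
        for samples, case_id in [(case1_samples, "case1"),
                                 (case2_samples, "case2"),
                                 (case3_samples, "case3")]:
            for p in samples:
                assert classify_case(p).case_id == case_id


@pytest.mark.parametrize("case_id", ["case1", "case2", "case3"])
def test_stability_sign_patterns_per_regime(case_id, case1_samples,
                                            case2_samples, case3_samples):
    """Each regime's det/trace sign pattern at every fixed point matches the
    theoretical census: honesty-dominant regimes have a unique ESS at the
    origin, fraud-dominant at (1,1), and the bistable regime has stable
    corners E and K, unstable S and N, and an interior saddle."""
    samples = {"case1": case1_samples, "case2": case2_samples,
               "case3": case3_samples}[case_id]
    pattern = REGIME_PATTERNS[case_id]
    for p in samples:
        reports = classify_equilibria(p)
        assert len(reports) == (5 if case_id == "case3" else 4)
        for r in reports:
            key = r.point if r.point in pattern else "interior"
            det_sign, trace_sign, label = pattern[key]
            assert np.sign(r.det) == det_sign
            if trace_sign == 0:
                assert abs(r.trace) < 1e-9
            elif trace_sign is not None:
                assert np.sign(r.trace) == trace_sign
            assert r.label == label


class TestAttractorPrediction:
    def test_baseline_predicts_collusion_corner(self, baseline):
        pred = predict_attractor(baseline)
        assert pred.area_PSEN == pytest.approx((3.3 / 7.9 + 4.4 / 9.1) / 2)
        assert pred.area_PSEN + pred.area_PSKN == pytest.approx(1.0)
        assert pred.corner == (1.0, 1.0)

    def test_costly_doctor_fraud_predicts_honest_corner(self, baseline):
        p = baseline.replace(C1=7.0)
        pred = predict_attractor(p)
        assert pred.area_PSEN == pytest.approx((3.3 / 7.9 + 8.4 / 9.1) / 2)
        assert pred.area_PSEN > 0.5
        assert pred.corner == (0.0, 0.0)

    def test_centre_saddle_is_undetermined(self):
        pred = area_rule(0.5, 0.5)
        assert pred.corner is None
        assert pred.area_PSEN == pytest.approx(0.5)

    def test_area_rule_is_shoelace_of_the_quadrilateral(self, rng):
        for x_star, y_star in rng.random((20, 2)):
            pred = area_rule(x_star, y_star)
            assert pred.area_PSEN == pytest.approx((x_star + y_star) / 2)
            assert pred.area_PSEN + pred.area_PSKN == pytest.approx(1.0)

    def test_rule_requires_bistable_regime(self, baseline):
        with pytest.raises(RegimeError, match="case1"):
            predict_attractor(baseline.replace(C1=30.0, C2=30.0))
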