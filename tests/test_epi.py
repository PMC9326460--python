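"""Epidemiological primitives: RR curves, PAF, marginal DRF, strata."""

import math

import numpy as np
import pytest
from pydantic import ValidationError

from heni.epi import (
    BurdenRate,
    IntakeDistribution,
    RRCurve,
    TMRELRange,
    aggregate_strata,
    marginal_drf,
    paf,
    rr_evaluate,
)


class TestRREvaluate:
    def test_unity_inside_tmrel(self, loglinear_curve):
        curve, t, _ = loglinear_curve
        for x in (0.0, t / 2, t):
            assert rr_evaluate(curve, x) == 1.0

    def test_loglinear_closed_form_at_upper_knot(self, loglinear_curve):
        curve, t, beta = loglinear_curve
        assert rr_evaluate(curve, t + 1.0 / beta) == pytest.approx(math.e, rel=1e-12)

    def test_loglinear_midpoint(self, loglinear_curve):
        curve, t, beta = loglinear_curve
        x = t + 0.5 / beta
        assert rr_evaluate(curve, x) == pytest.approx(math.exp(0.5), rel=1e-12)

    def test_constant_extrapolation_beyond_last_knot(self, loglinear_curve):
        curve, t, beta = loglinear_curve
        assert rr_evaluate(curve, 1e6) == pytest.approx(
            rr_evaluate(curve, t + 1.0 / beta)
        )

    @pytest.mark.parametrize(
        "knots",
        [
            ((1.0, 1.0), (1.0, 2.0)),  # non-increasing intakes
            ((0.0, -1.0),),  # non-positive RR
            (),  # no knots
        ],
    )
    def test_malformed_curve_rejected_at_construction(self, knots):
        with pytest.raises(ValidationError):
            RRCurve(component_id="sodium", knots=knots)

    def test_tmrel_low_above_high_rejected(self):
        with pytest.raises(ValidationError):
            TMRELRange(low=5.0, high=1.0)


class TestPAF:
    def test_rr_identically_one_gives_zero(self):
        curve = RRCurve(
            component_id="sodium",
            knots=((0.0, 1.0), (10.0, 1.0)),
            tmrel=TMRELRange(low=0.0, high=0.0),
        )
        d = IntakeDistribution(kind="point", point_intake=4.0)
        assert paf(curve, d) == pytest.approx(0.0, abs=1e-15)

    def test_point_mass_rr_two_gives_half(self):
        curve = RRCurve(
            component_id="sodium",
            knots=((0.0, 1.0), (1.0, 2.0)),
            tmrel=TMRELRange(low=0.0, high=0.0),
        )
        d = IntakeDistribution(kind="point", point_intake=1.0)
        assert paf(curve, d) == pytest.approx(0.5, rel=1e-12)

    def test_histogram_against_monte_carlo_oracle(self, loglinear_curve):
        curve, _, _ = loglinear_curve
        dist = IntakeDistribution(
            kind="histogram", bin_edges=(0.0, 2.0, 5.0, 8.0), bin_probs=(0.2, 0.5, 0.3)
        )
        n = 10**6
        rng = np.random.default_rng(12345)
        rr = np.asarray(curve.evaluate(dist.sample(rng, n)))
        e_mc, se = rr.mean(), rr.std(ddof=1) / math.sqrt(n)
        e_exact = 1.0 / (1.0 - paf(curve, dist))
        assert abs(e_exact - e_mc) < 3 * se

    def test_lognormal_against_monte_carlo_oracle(self, loglinear_curve):
        curve, _, _ = loglinear_curve
        dist = IntakeDistribution(kind="lognormal", mu=1.0, sigma=0.5)
        n = 10**6
        rng = np.random.default_rng(999)
        rr = np.asarray(curve.evaluate(dist.sample(rng, n)))
        e_mc, se = rr.mean(), rr.std(ddof=1) / math.sqrt(n)
        e_exact = 1.0 / (1.0 - paf(curve, dist))
        assert abs(e_exact - e_mc) < 3 * se

    def test_histogram_refinement_invariance(self, loglinear_curve):
        """Splitting a bin into equal halves must not move the PAF."""
        curve, _, _ = loglinear_curve
        coarse = IntakeDistribution(
            kind="histogram", bin_edges=(0.0, 2.0, 5.0, 8.0), bin_probs=(0.2, 0.5, 0.3)
        )
        fine = IntakeDistribution(
            kind="histogram",
            bin_edges=(0.0, 1.0, 2.0, 3.5, 5.0, 6.5, 8.0),
            bin_probs=(0.1, 0.1, 0.25, 0.25, 0.15, 0.15),
        )
        assert abs(paf(curve, coarse) - paf(curve, fine)) <= 1e-12

    def test_unnormalized_histogram_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            IntakeDistribution(
                kind="histogram", bin_edges=(0.0, 1.0, 2.0), bin_probs=(0.5, 0.4)
            )

    def test_population_below_tmrel_is_protective(self):
        """Intake below a beneficial component's TMREL means negative PAF is
        impossible here (RR clamps to raw curve); a rising curve above the
        TMREL gives positive PAF, a population inside gives exactly zero."""
        curve = RRCurve(
            component_id="fruit",
            knots=((0.0, 2.0), (100.0, 1.0)),
            tmrel=TMRELRange(low=100.0, high=math.inf),
        )
        inside = IntakeDistribution(kind="point", point_intake=150.0)
        below = IntakeDistribution(kind="point", point_intake=0.0)
        assert paf(curve, inside) == 0.0
        assert paf(curve, below) == pytest.approx(0.5, rel=1e-12)


class TestMarginalDRF:
    BURDENS = [BurdenRate(outcome="IHD", rate=0.02)]

    def test_flat_curve_gives_zero(self):
        curve = RRCurve(
            component_id="sodium",
            knots=((0.0, 1.0), (10.0, 1.0)),
            tmrel=TMRELRange(low=0.0, high=0.0),
        )
        d = IntakeDistribution(kind="point", point_intake=5.0)
        res = marginal_drf(curve, d, self.BURDENS)
        assert res.drf_udaly_per_g == pytest.approx(0.0, abs=1e-9)

    def test_point_mass_matches_analytic_derivative(self, loglinear_curve):
        """AB(x) = (1 − e^{−β(x−t)})·B above the TMREL; the finite
        difference must match dAB/dx / 365 × 1e6 to 1e-4 relative."""
        curve, t, beta = loglinear_curve
        x0 = 3.0
        d = IntakeDistribution(kind="point", point_intake=x0)
        res = marginal_drf(curve, d, self.BURDENS, delta=1e-3)
        analytic = beta * math.exp(-beta * (x0 - t)) * 0.02 / 365.0 * 1e6
        assert res.drf_udaly_per_g == pytest.approx(analytic, rel=1e-4)

    def test_distribution_inside_tmrel_gives_zero(self, loglinear_curve):
        curve, t, _ = loglinear_curve
        d = IntakeDistribution(kind="point", point_intake=t / 2)
        res = marginal_drf(curve, d, self.BURDENS, delta=0.1)
        assert res.drf_udaly_per_g == 0.0

    def test_sign_matches_slope_direction(self, loglinear_curve):
        rising, t, beta = loglinear_curve
        falling = RRCurve(
            component_id="fruit",
            knots=((0.0, math.e), (1.0 / beta, 1.0)),
            tmrel=TMRELRange(low=1.0 / beta, high=math.inf),
        )
        d_up = IntakeDistribution(kind="point", point_intake=3.0)
        d_down = IntakeDistribution(kind="point", point_intake=1.0)
        assert marginal_drf(rising, d_up, self.BURDENS).drf_udaly_per_g >= 0
        assert marginal_drf(falling, d_down, self.BURDENS).drf_udaly_per_g <= 0

    def test_halving_delta_converges_quadratically(self, loglinear_curve):
        """Central difference: error(δ/2) ≈ error(δ)/4 for smooth curves."""
        curve, t, beta = loglinear_curve
        x0 = 3.0
        d = IntakeDistribution(kind="point", point_intake=x0)
        analytic = beta * math.exp(-beta * (x0 - t)) * 0.02 / 365.0 * 1e6
        err = []
        for delta in (0.4, 0.2, 0.1):
            v = marginal_drf(curve, d, self.BURDENS, delta=delta).drf_udaly_per_g
            err.append(abs(v - analytic))
        assert err[1] < err[0] / 3.0 and err[2] < err[1] / 3.0

    def test_convergence_check_reports_half_delta(self, loglinear_curve):
        curve, _, _ = loglinear_curve
        d = IntakeDistribution(kind="point", point_intake=3.0)
        res = marginal_drf(curve, d, self.BURDENS, delta=0.5)
        assert res.drf_at_half_delta is not None
        assert res.drf_at_half_delta == pytest.approx(res.drf_udaly_per_g, rel=0.05)

    def test_negative_delta_rejected(self, loglinear_curve):
        curve, _, _ = loglinear_curve
        d = IntakeDistribution(kind="point", point_intake=3.0)
        with pytest.raises(ValueError, match="delta"):
            marginal_drf(curve, d, self.BURDENS, delta=-1.0)

    def test_downward_shift_past_zero_sets_clamped_flag(self, loglinear_curve):
        curve, _, _ = loglinear_curve
        d = IntakeDistribution(kind="point", point_intake=0.05)
        res = marginal_drf(curve, d, self.BURDENS, delta=0.5)
        assert res.clamped


class TestAggregateStrata:
    def test_equal_weights_mean(self):
        drfs = {("a", "f"): 2.0, ("b", "m"): 4.0}
        w = {("a", "f"): 0.5, ("b", "m"): 0.5}
        assert aggregate_strata(drfs, w) == pytest.approx(3.0)

    def test_single_stratum_identity(self):
        assert aggregate_strata({("a", "f"): 7.5}, {("a", "f"): 1.0}) == 7.5

    def test_unequal_weights_hand_value(self):
        drfs = {("a", "f"): 0.0, ("b", "m"): 8.0}
        w = {("a", "f"): 0.25, ("b", "m"): 0.75}
        assert aggregate_strata(drfs, w) == pytest.approx(6.0)

    def test_bounded_by_stratum_extremes(self):
        drfs = {("a", "f"): -3.0, ("b", "m"): 5.0, ("c", "f"): 1.0}
        w = {("a", "f"): 0.2, ("b", "m"): 0.3, ("c", "f"): 0.5}
        agg = aggregate_strata(drfs, w)
        assert min(drfs.values()) <= agg <= max(drfs.values())

    def test_missing_weight_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            aggregate_strata({("a", "f"): 1.0}, {})

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            aggregate_strata({("a", "f"): 1.0}, {("a", "f"): 0.8})
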