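"""The statistical core: Wald ratios, IVW, weighted median, MR-Egger."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from gdf15mr import (
    RatioEstimate,
    ivw,
    mr_egger,
    to_odds_ratio,
    two_sided_p,
    wald_ratio,
    weighted_median,
)
from gdf15mr.estimators import EstimationError, _weighted_median
from conftest import hinst


def ratios_from(estimates, ses):
    return [
        RatioEstimate(rsid=f"rs{i}", estimate=e, se=s)
        for i, (e, s) in enumerate(zip(estimates, ses))
    ]


class TestWaldRatio:
    def test_first_order_closed_form(self):
        r = wald_ratio(hinst(bx=0.1, by=0.02, sy=0.01), order="first")
        assert r.estimate == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)
        assert r.weight == pytest.approx(r.se**-2)

    def test_unit_exposure_is_identity(self):
        r = wald_ratio(hinst(bx=1.0, by=0.37, sy=0.04))
        assert r.estimate == pytest.approx(0.37)
        assert r.se == pytest.approx(0.04)

    def test_second_order_closed_form(self):
        r = wald_ratio(hinst(bx=0.1, by=0.02, sy=0.01, sx=0.05), order="second")
        assert r.se == pytest.approx(math.sqrt(0.01 + 0.01), rel=1e-12)

    def test_second_order_matches_monte_carlo_sd(self, rng):
        """In the regime where the delta expansion is valid (se_x << |beta_x|)
        the second-order SE agrees with the SD of the simulated ratio to 2%."""
        bx, by, sx, sy = 0.1, 0.02, 0.005, 0.01
        r = wald_ratio(hinst(bx=bx, by=by, sx=sx, sy=sy), order="second")
        n = 10**6
        draws = rng.normal(by, sy, n) / rng.normal(bx, sx, n)
        assert r.se == pytest.approx(float(np.std(draws)), rel=0.02)

    def test_zero_exposure_beta_names_rsid(self):
        with pytest.raises(EstimationError, match="rs1"):
            wald_ratio(hinst(rsid="rs1", bx=0.0))


class TestIVW:
    def test_single_ratio_degeneracy(self):
        r = RatioEstimate("rs1", 0.25, 0.07)
        res = ivw([r])
        assert res.estimate == pytest.approx(0.25)
        assert res.se == pytest.approx(0.07)
        assert res.q_stat is None and res.q_pval is None
        assert res.n_snps == 1

    def test_two_ratio_closed_form(self):
        res = ivw(ratios_from([0.1, 0.3], [0.1, 0.1]))
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1 / math.sqrt(2))
        assert res.q_stat == pytest.approx(2.0)

    def test_identical_ratios_zero_heterogeneity(self):
        res = ivw(ratios_from([0.15] * 4, [0.05] * 4))
        assert res.q_stat == pytest.approx(0.0, abs=1e-24)
        assert res.q_pval == pytest.approx(1.0)

    def test_matches_weighted_least_squares_oracle(self, rng):
        """Fixed-effects IVW equals a generic WLS fit of the ratios on a
        constant, weights 1/se^2 (statsmodels as independent oracle)."""
        est = rng.normal(0.1, 0.2, 12)
        ses = rng.uniform(0.02, 0.3, 12)
        res = ivw(ratios_from(est, ses))
        fit = sm.WLS(est, np.ones((12, 1)), weights=ses**-2).fit()
        assert res.estimate == pytest.approx(fit.params[0], rel=1e-10)
        # statsmodels scales by residual variance; undo to get fixed-effects SE
        fixed_se = fit.bse[0] / np.sqrt(fit.scale)
        assert res.se == pytest.approx(fixed_se, rel=1e-10)

    def test_random_multiplicative_inflates_only_when_q_large(self):
        heterogeneous = ratios_from([0.0, 0.5, -0.4, 0.6], [0.05] * 4)
        fixed = ivw(heterogeneous, model="fixed")
        random = ivw(heterogeneous, model="random_multiplicative")
        assert random.estimate == fixed.estimate
        assert random.se == pytest.approx(
            fixed.se * math.sqrt(fixed.q_stat / 3), rel=1e-12
        )
        homogeneous = ratios_from([0.1, 0.100001, 0.0999999], [0.1] * 3)
        assert ivw(homogeneous, "random_multiplicative").se == pytest.approx(
            ivw(homogeneous, "fixed").se
        )

    def test_empty_input_errors(self):
        with pytest.raises(EstimationError):
            ivw([])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        est=st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=10),
        seed=st.integers(0, 10**6),
    )
    def test_q_nonnegative_and_zero_iff_equal(self, est, seed):
        ses = np.random.default_rng(seed).uniform(0.01, 0.5, len(est))
        res = ivw(ratios_from(est, ses))
        assert res.q_stat >= 0
        if len(set(est)) == 1:
            assert res.q_stat == pytest.approx(0.0, abs=1e-18)
        elif max(est) - min(est) > 1e-6:
            assert res.q_stat > 0


class TestWeightedMedian:
    def test_equal_weight_triple_interpolates_to_middle(self):
        res = weighted_median(ratios_from([0.1, 0.2, 0.9], [0.1] * 3), seed=1)
        assert res.estimate == pytest.approx(0.2)

    def test_interpolation_formula_on_pair(self):
        # midpoints 0.25 and 0.75 -> 0.5 lands halfway between 0 and 1
        assert _weighted_median(np.array([0.0, 1.0]), np.ones(2)) == pytest.approx(0.5)

    def test_dominant_weight_wins(self):
        # one SNP carries ~0.999 of the total inverse-variance weight
        res = weighted_median(
            ratios_from([0.8, 0.1, 0.15], [0.001, 0.9, 0.9]), seed=1
        )
        assert res.estimate == pytest.approx(0.8, abs=1e-4)

    def test_equal_weights_odd_count_is_sample_median(self):
        vals = [0.3, -0.2, 0.05, 0.4, 0.1]
        res = weighted_median(ratios_from(vals, [0.1] * 5), seed=1)
        assert res.estimate == pytest.approx(float(np.median(vals)))

    def test_bootstrap_se_is_seeded_and_plausible(self):
        ratios = ratios_from([0.1, 0.15, 0.2, 0.25, 0.3], [0.05] * 5)
        a = weighted_median(ratios, n_boot=500, seed=3)
        b = weighted_median(ratios, n_boot=500, seed=3)
        assert a.se == b.se
        # bootstrap SE should be on the scale of the per-SNP SEs
        assert 0.01 < a.se < 0.2

    def test_requires_three_ratios_and_enough_boot(self):
        with pytest.raises(EstimationError, match="IVW"):
            weighted_median(ratios_from([0.1, 0.2], [0.1] * 2))
        with pytest.raises(EstimationError, match="n_boot"):
            weighted_median(ratios_from([0.1, 0.2, 0.3], [0.1] * 3), n_boot=50)


class TestMREgger:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        a, b = 0.03, 0.4
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        instruments = [
            hinst(rsid=f"rs{i}", bx=x, by=a + b * x, sy=0.01 + 0.001 * i)
            for i, x in enumerate(bx)
        ]
        res = mr_egger(instruments)
        assert res.estimate == pytest.approx(b, abs=1e-12)
        assert res.egger_intercept == pytest.approx(a, abs=1e-12)

    def test_zero_intercept_mode_equals_fixed_effects_ivw(self, rng):
        instruments = [
            hinst(rsid=f"rs{i}", bx=rng.uniform(0.1, 0.5),
                  by=rng.normal(0, 0.05), sy=rng.uniform(0.01, 0.03))
            for i in range(8)
        ]
        constrained = mr_egger(instruments, fit_intercept=False)
        pooled = ivw([wald_ratio(h, order="first") for h in instruments])
        assert constrained.estimate == pytest.approx(pooled.estimate, rel=1e-10)

    def test_orientation_invariance(self, rng):
        instruments = [
            hinst(rsid=f"rs{i}", bx=rng.uniform(0.1, 0.5),
                  by=rng.normal(0.02, 0.05), sy=rng.uniform(0.01, 0.03))
            for i in range(6)
        ]
        negated = [
            hinst(rsid=h.rsid, bx=-h.beta_exposure, by=-h.beta_outcome,
                  sx=h.se_exposure, sy=h.se_outcome)
            for h in instruments[:1]
        ] + instruments[1:]
        a, b = mr_egger(instruments), mr_egger(negated)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_matches_statsmodels_wls_oracle(self, rng):
        instruments = [
            hinst(rsid=f"rs{i}", bx=rng.uniform(0.1, 0.5),
                  by=rng.normal(0.05, 0.1), sy=rng.uniform(0.01, 0.03))
            for i in range(10)
        ]
        res = mr_egger(instruments)
        bx = np.array([h.beta_exposure for h in instruments])
        by = np.array([h.beta_outcome for h in instruments])
        w = np.array([h.se_outcome for h in instruments]) ** -2.0
        fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
        assert res.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert res.estimate == pytest.approx(fit.params[1], rel=1e-10)
        # statsmodels always scales by RSS/(L-2); we floor the factor at 1
        adj = max(1.0, fit.scale) / fit.scale
        assert res.se == pytest.approx(fit.bse[1] * math.sqrt(adj), rel=1e-10)
        assert res.egger_intercept_se == pytest.approx(
            fit.bse[0] * math.sqrt(adj), rel=1e-10
        )

    def test_too_few_or_collinear_instruments_error(self):
        with pytest.raises(EstimationError):
            mr_egger([hinst(rsid="rs1"), hinst(rsid="rs2")])
        same_x = [hinst(rsid=f"rs{i}", bx=0.2, by=0.01 * i) for i in range(4)]
        with pytest.raises(EstimationError, match="singular|collinear"):
            mr_egger(same_x)


class TestScalarConversions:
    @pytest.mark.parametrize(
        "estimate,se,expected",
        [(0.063, 0.024, 0.009), (0.063, 0.028, 0.024), (0.111, 0.053, 0.036)],
    )
    def test_p_values_reproduce_published_rows(self, estimate, se, expected):
        assert round(two_sided_p(estimate, se), 3) == expected

    def test_null_estimate_gives_p_one(self):
        assert two_sided_p(0.0, 0.1) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "estimate,expected",
        [(0.031, 1.03), (-0.065, 0.94), (-0.063, 0.94)],
    )
    def test_or_conversion_reproduces_published_rows(self, estimate, expected):
        or_, lo, hi = to_odds_ratio(estimate, 0.02)
        assert round(or_, 2) == expected
        assert lo < or_ < hi

    def test_null_or_ci_symmetric_in_log_space(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert math.log(hi) == pytest.approx(-math.log(lo), rel=1e-9)

    def test_se_must_be_positive(self):
        with pytest.raises(EstimationError):
            two_sided_p(0.1, 0.0)
        with pytest.raises(EstimationError):
            to_odds_ratio(0.1, -1.0)


@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scale_equivariance_of_all_estimators(c, rng):
    """Multiplying exposure betas and SEs by c divides every causal estimate by c."""
    base = [
        hinst(rsid=f"rs{i}", bx=rng.uniform(0.1, 0.5), sx=rng.uniform(0.01, 0.02),
              by=rng.normal(0.03, 0.04), sy=rng.uniform(0.01, 0.03))
        for i in range(7)
    ]
    scaled = [
        hinst(rsid=h.rsid, bx=c * h.beta_exposure, sx=c * h.se_exposure,
              by=h.beta_outcome, sy=h.se_outcome)
        for h in base
    ]

    def all_estimates(instruments):
        ratios = [wald_ratio(h, order="second") for h in instruments]
        return (
            ivw(ratios).estimate,
            weighted_median(ratios, seed=5).estimate,
            mr_egger(instruments).estimate,
        )

    for orig, scl in zip(all_estimates(base), all_estimates(scaled)):
        assert scl == pytest.approx(orig / c, rel=1e-9)
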