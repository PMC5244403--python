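"""Causal estimators: Wald, IVW (fixed/random/correlated), ML, MR-Egger.

Frozen expected values were computed by hand / with an independent oracle
from the four-SNP worked example (weighted-mean arithmetic over the printed
beta-SE pairs) and from closed-form matrix algebra on tiny instances.
"""

import numpy as np
import pytest

from mrkit.estimators import (
    EstimationError,
    ivw_correlated,
    ivw_fixed,
    ivw_random,
    ml_correlated,
    mr_egger,
    wald_ratio,
)
from mrkit.instruments import LDMatrix
from mrkit.summary_data import HarmonizedInstrument, HarmonizedSet

from conftest import random_harmonized


def inst(snp="rs1", bx=0.1, se_x=0.01, by=0.05, se_y=0.02):
    return HarmonizedInstrument(snp, "A", bx, se_x, by, se_y)


def hset(bx, by, se_y, se_x=None):
    bx = np.asarray(bx, dtype=float)
    se_x = np.full_like(bx, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    return HarmonizedSet.from_arrays(
        [f"rs{i}" for i in range(len(bx))], bx, se_x, by, se_y
    )


class TestWaldRatio:
    def test_strongest_snp_hand_computed(self):
        # by/bx = -0.052/-0.061; se = 0.013/0.061
        e = wald_ratio(inst(bx=-0.061, se_x=0.011, by=-0.052, se_y=0.013))
        assert e.beta == pytest.approx(0.8524590164, abs=1e-9)
        assert e.se == pytest.approx(0.2131147541, abs=1e-9)
        assert e.ci_low == pytest.approx(e.beta - 1.96 * e.se)

    def test_null_numerator_gives_null_estimate(self):
        e = wald_ratio(inst(by=0.0))
        assert e.beta == 0.0 and e.p_value == pytest.approx(1.0)

    def test_second_order_reduces_to_first_order_when_se_x_tiny(self):
        a = wald_ratio(inst(bx=1.0, se_x=1e-300, by=0.5, se_y=0.1), "second_order")
        b = wald_ratio(inst(bx=1.0, se_x=1e-300, by=0.5, se_y=0.1), "first_order")
        assert a.se == pytest.approx(b.se) == pytest.approx(0.1)

    def test_second_order_hand_formula(self):
        e = wald_ratio(inst(bx=-0.061, se_x=0.011, by=-0.052, se_y=0.013),
                       "second_order")
        expect = np.sqrt(0.013**2 / 0.061**2 + 0.052**2 * 0.011**2 / 0.061**4)
        assert e.se == pytest.approx(expect, rel=1e-12)

    def test_zero_denominator_raises(self):
        with pytest.raises(EstimationError, match="bx = 0"):
            wald_ratio(inst(bx=0.0))


class TestIvwFixed:
    def test_four_snp_worked_example(self, table1):
        e = ivw_fixed(table1)
        assert e.beta == pytest.approx(0.7727374804, abs=1e-9)
        assert e.se == pytest.approx(0.1124750973, abs=1e-9)
        assert round(e.odds_ratio, 2) == 2.17

    def test_single_instrument_equals_wald(self, table1):
        single = HarmonizedSet(table1.instruments[:1])
        e = ivw_fixed(single)
        w = wald_ratio(table1.instruments[0])
        assert e.beta == pytest.approx(w.beta) and e.se == pytest.approx(w.se)

    def test_duplicating_an_instrument_shrinks_se_by_sqrt2(self):
        one = hset([0.1], [0.05], [0.02])
        three = HarmonizedSet.from_arrays(
            ["rs0", "rs0b"], [0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02]
        )
        a, b = ivw_fixed(one), ivw_fixed(three)
        assert b.beta == pytest.approx(a.beta)
        assert b.se == pytest.approx(a.se / np.sqrt(2))

    def test_empty_set_rejected(self):
        with pytest.raises(EstimationError):
            ivw_fixed(HarmonizedSet([]))

    def test_matches_zero_intercept_weighted_regression_oracle(self, rng):
        """Analytic weighted mean vs statsmodels WLS through the origin."""
        import statsmodels.api as sm

        for _ in range(100):
            h = random_harmonized(rng, n=int(rng.integers(2, 15)))
            e = ivw_fixed(h)
            fit = sm.WLS(h.by, h.bx[:, None], weights=1.0 / h.se_y**2).fit()
            assert e.beta == pytest.approx(fit.params[0], rel=1e-10)


class TestIvwRandom:
    def test_homogeneous_ratios_give_tau2_zero(self):
        h = hset([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.02, 0.02, 0.02])
        a, b = ivw_random(h), ivw_fixed(h)
        assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)

    def test_worked_example_q_below_df_equals_fixed(self, table1):
        # Q ~ 0.266 < 3 df, so tau2 truncates to zero
        assert ivw_random(table1).beta == pytest.approx(ivw_fixed(table1).beta)

    def test_symmetric_two_ratio_case(self):
        h = hset([0.1, 0.1], [0.0, 0.1], [0.02, 0.02])
        assert ivw_random(h).beta == pytest.approx(0.5)

    def test_needs_two_instruments(self):
        with pytest.raises(EstimationError):
            ivw_random(hset([0.1], [0.05], [0.02]))

    def test_heterogeneity_widens_random_effects_se(self):
        h = hset([0.1, 0.1, 0.1, 0.1], [0.0, 0.02, 0.05, 0.09],
                 [0.005, 0.005, 0.005, 0.005])
        assert ivw_random(h).se > ivw_fixed(h).se


class TestIvwCorrelated:
    def test_identity_correlation_reproduces_fixed(self, table1):
        ld = LDMatrix.identity(table1.snp_ids)
        a, b = ivw_correlated(table1, ld), ivw_fixed(table1)
        assert a.beta == pytest.approx(b.beta, rel=1e-14)
        assert a.se == pytest.approx(b.se, rel=1e-14)

    def test_near_duplicate_instrument_adds_no_information(self):
        # two copies at r = 0.99: se within 0.5% of the single-SNP Wald se.
        # Oracle: closed-form 2x2 inverse of [[s2, r s2], [r s2, s2]].
        bx, by, se_y, r = 0.1, 0.05, 0.02, 0.99
        h = hset([bx, bx], [by, by], [se_y, se_y])
        ld = LDMatrix(["rs0", "rs1"], np.array([[1.0, r], [r, 1.0]]))
        e = ivw_correlated(h, ld)
        info_oracle = (2 * bx * bx / (1 + r)) / se_y**2  # bx' Omega^-1 bx by hand
        assert e.se == pytest.approx(1 / np.sqrt(info_oracle), rel=1e-12)
        single = wald_ratio(h.instruments[0])
        assert abs(e.se - single.se) / single.se < 0.005

    def test_negative_correlation_sharpens_the_estimate(self):
        h = hset([0.1, 0.12], [0.05, 0.06], [0.02, 0.02])
        ld_neg = LDMatrix(["rs0", "rs1"], np.array([[1.0, -0.5], [-0.5, 1.0]]))
        ld_id = LDMatrix.identity(["rs0", "rs1"])
        assert ivw_correlated(h, ld_neg).se < ivw_correlated(h, ld_id).se

    def test_near_singular_correlation_advises_pruning(self, table1):
        ld = LDMatrix.exchangeable(table1.snp_ids, 0.9995)
        with pytest.raises(EstimationError, match="prune"):
            ivw_correlated(table1, ld)


class TestMlCorrelated:
    def test_small_measurement_error_limit_matches_gls(self, table1):
        tiny = HarmonizedSet([
            HarmonizedInstrument(i.snp_id, i.effect_allele, i.bx, 1e-8, i.by, i.se_y)
            for i in table1.instruments
        ])
        ld = LDMatrix.identity(tiny.snp_ids)
        ml = ml_correlated(tiny, ld)
        gls = ivw_correlated(tiny, ld)
        assert ml.beta == pytest.approx(gls.beta, abs=1e-4)
        assert abs(ml.se - gls.se) / gls.se < 0.01

    def test_single_snp_saturated_model_is_exact_ratio(self):
        h = hset([0.1], [0.05], [0.02])
        assert ml_correlated(h).beta == pytest.approx(0.5, abs=1e-8)

    def test_recovers_truth_from_low_noise_simulation(self):
        from mrkit.synthetic import SimulationConfig, simulate_harmonized

        cfg = SimulationConfig(n_snps=10, true_beta=0.3, se_x=1e-4, se_y=1e-4, seed=7)
        h, truth = simulate_harmonized(cfg)
        e = ml_correlated(h)
        assert e.beta == pytest.approx(0.3, abs=3 * e.se)

    def test_accounts_for_exposure_noise_with_wider_se_than_gls(self, table1):
        ld = LDMatrix.identity(table1.snp_ids)
        assert ml_correlated(table1, ld).se > ivw_correlated(table1, ld).se


class TestMrEgger:
    def test_exact_proportionality_gives_zero_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        egger = mr_egger(hset(bx, 0.4 * bx, np.full(5, 0.02)))
        assert egger.slope.beta == pytest.approx(0.4, abs=1e-12)
        assert egger.intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_data_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        egger = mr_egger(hset(bx, 0.1 + 0.4 * bx, np.full(5, 0.02)))
        assert egger.slope.beta == pytest.approx(0.4, abs=1e-12)
        assert egger.intercept.beta == pytest.approx(0.1, abs=1e-12)

    def test_three_point_least_squares_by_hand(self):
        egger = mr_egger(hset([0.1, 0.2, 0.3], [0.25, 0.40, 0.55], [0.02] * 3))
        assert egger.slope.beta == pytest.approx(1.5, abs=1e-12)
        assert egger.intercept.beta == pytest.approx(0.1, abs=1e-12)

    def test_orientation_makes_preflips_irrelevant(self, rng):
        h = random_harmonized(rng, 8)
        flip = rng.random(8) < 0.5
        flipped = HarmonizedSet.from_arrays(
            h.snp_ids,
            np.where(flip, -h.bx, h.bx), h.se_x,
            np.where(flip, -h.by, h.by), h.se_y,
        )
        a, b = mr_egger(h), mr_egger(flipped)
        assert a.slope.beta == pytest.approx(b.slope.beta, rel=1e-12)
        assert a.intercept.beta == pytest.approx(b.intercept.beta, rel=1e-12)

    def test_matches_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            h = random_harmonized(rng, 10)
            h = HarmonizedSet.from_arrays(  # pre-orient so the oracle sees same data
                h.snp_ids, np.abs(h.bx), h.se_x,
                np.sign(h.bx) * h.by, h.se_y,
            )
            egger = mr_egger(h)
            x = sm.add_constant(h.bx)
            fit = sm.WLS(h.by, x, weights=1.0 / h.se_y**2).fit()
            assert egger.intercept.beta == pytest.approx(fit.params[0], rel=1e-10)
            assert egger.slope.beta == pytest.approx(fit.params[1], rel=1e-10)
            assert egger.slope.se == pytest.approx(fit.bse[1], rel=1e-8)

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError, match=">= 3"):
            mr_egger(hset([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))

    def test_collinear_exposure_coefficients_rejected(self):
        with pytest.raises(EstimationError, match="collinear"):
            mr_egger(hset([0.1, 0.1, -0.1], [0.05, 0.06, 0.04], [0.02] * 3))

    def test_t_reference_widens_small_sample_interval(self):
        h = hset([0.1, 0.2, 0.3, 0.4], [0.26, 0.41, 0.53, 0.72], [0.02] * 4)
        assert mr_egger(h, use_t=True).slope.p_value > mr_egger(h).slope.p_value


class TestEquivariance:
    """Scale and sign equivariance shared by every estimator."""

    @pytest.mark.parametrize("estimator", [ivw_fixed, ivw_random])
    def test_outcome_rescaling_rescales_estimate(self, estimator, rng):
        h = random_harmonized(rng, 8)
        c = 3.7
        scaled = HarmonizedSet.from_arrays(h.snp_ids, h.bx, h.se_x, c * h.by, c * h.se_y)
        a, b = estimator(h), estimator(scaled)
        assert b.beta == pytest.approx(c * a.beta, rel=1e-10)
        assert b.se == pytest.approx(c * a.se, rel=1e-10)

    @pytest.mark.parametrize("estimator", [ivw_fixed, ivw_random])
    def test_negating_exposure_negates_estimate(self, estimator, rng):
        h = random_harmonized(rng, 8)
        neg = HarmonizedSet.from_arrays(h.snp_ids, -h.bx, h.se_x, h.by, h.se_y)
        assert estimator(neg).beta == pytest.approx(-estimator(h).beta, rel=1e-10)

    def test_correlated_estimators_sign_equivariant(self, rng):
        h = random_harmonized(rng, 6)
        ld = LDMatrix.exchangeable(h.snp_ids, 0.3)
        neg = HarmonizedSet.from_arrays(h.snp_ids, -h.bx, h.se_x, h.by, h.se_y)
        assert ivw_correlated(neg, ld).beta == pytest.approx(
            -ivw_correlated(h, ld).beta, rel=1e-10
        )
        assert ml_correlated(neg, ld).beta == pytest.approx(
            -ml_correlated(h, ld).beta, rel=1e-6
        )
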