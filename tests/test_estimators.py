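"""Univariable MR estimators against hand values, an independent WLS
oracle (statsmodels), and their algebraic invariants."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrkit.estimators import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    WaldRatio,
    egger,
    ivw_mre,
    simple_median,
    wald_ratio,
    weighted_median,
)
from mrkit.harmonize import HarmonizedPair


def _pair(rsid="rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.05,
          se_out=0.02):
    return HarmonizedPair(
        rsid=rsid, beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out,
        se_out=se_out, eaf_exp=0.3, eaf_out=0.3, status="kept",
    )


def _ratios(values, ses):
    return [
        WaldRatio(rsid=f"rs{i}", ratio=v, se_ratio=s)
        for i, (v, s) in enumerate(zip(values, ses))
    ]


def _random_pairs(rng, k):
    return [
        _pair(
            rsid=f"rs{i}",
            beta_exp=rng.normal(0, 0.05) or 0.01,
            se_exp=rng.uniform(0.001, 0.01),
            beta_out=rng.normal(0, 0.02),
            se_out=rng.uniform(0.005, 0.05),
        )
        for i in range(k)
    ]


class TestWaldRatio:
    def test_hand_values(self):
        wr = wald_ratio(_pair(), se_mode="first_order")
        assert wr.ratio == pytest.approx(0.5)
        assert wr.se_ratio == pytest.approx(0.2)
        wr2 = wald_ratio(_pair(), se_mode="second_order")
        # sqrt(se_out²/βx² + βy²·se_exp²/βx⁴) = sqrt(0.04 + 0.0025)
        assert wr2.se_ratio == pytest.approx(np.sqrt(0.0425))

    def test_zero_outcome_beta(self):
        wr = wald_ratio(_pair(beta_out=0.0))
        assert wr.ratio == 0.0
        assert wr.se_ratio == pytest.approx(0.02 / 0.1)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(_pair(beta_exp=0.0))


class TestIvw:
    def test_identical_ratios_no_dispersion(self):
        est = ivw_mre(_ratios([0.4, 0.4, 0.4], [0.2, 0.1, 0.1]))
        assert est.beta == pytest.approx(0.4)
        # Q = 0 → SE equals fixed-effect SE
        w = 1 / 0.2**2 + 2 / 0.1**2
        assert est.se == pytest.approx(1 / np.sqrt(w))

    def test_hand_computed_weighted_mean(self):
        est = ivw_mre(_ratios([0.5, 0.3, 0.4], [0.2, 0.1, 0.1]))
        assert est.beta == pytest.approx(0.36666667, abs=1e-6)
        # Q = 1.0 < k−1 = 2 → multiplicative scale floored at 1
        assert est.se == pytest.approx(1 / np.sqrt(225), abs=1e-9)

    def test_order_invariance(self, rng):
        ratios = _ratios(rng.normal(0, 1, 10), rng.uniform(0.1, 1, 10))
        shuffled = list(ratios)
        rng.shuffle(shuffled)
        assert ivw_mre(ratios).beta == pytest.approx(
            ivw_mre(shuffled).beta, rel=1e-12
        )

    def test_equal_se_reduces_to_mean(self, rng):
        vals = rng.normal(0, 1, 7)
        est = ivw_mre(_ratios(vals, [0.3] * 7))
        assert est.beta == pytest.approx(np.mean(vals), rel=1e-12)

    def test_single_instrument_falls_back_to_wald(self):
        est = ivw_mre(_ratios([0.5], [0.2]))
        assert est.beta == 0.5
        assert "single_instrument_wald" in est.warnings

    def test_matches_wls_through_origin_oracle(self, rng):
        """IVW of first-order Wald ratios equals a no-intercept WLS of
        outcome betas on exposure betas with weights 1/se_out²
        (statsmodels as the independent implementation)."""
        for _ in range(20):
            pairs = _random_pairs(rng, int(rng.integers(3, 21)))
            ratios = [wald_ratio(p) for p in pairs]
            est = ivw_mre(ratios)
            bx = np.array([p.beta_exp for p in pairs])
            by = np.array([p.beta_out for p in pairs])
            w = 1 / np.array([p.se_out for p in pairs]) ** 2
            fit = sm.WLS(by, bx, weights=w).fit()
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)


class TestMedians:
    def test_simple_median_odd_count(self):
        est = simple_median(_ratios([0.2, 0.4, 0.6], [0.1, 0.1, 0.1]),
                            boot_reps=200, seed=1)
        assert est.beta == pytest.approx(0.4)

    def test_symmetric_ratios_give_zero(self):
        est = simple_median(
            _ratios([-0.3, -0.1, 0.0, 0.1, 0.3], [0.1] * 5),
            boot_reps=200, seed=1,
        )
        assert est.beta == 0.0

    def test_weighted_equals_simple_under_equal_weights(self, rng):
        vals = list(rng.normal(0, 1, 9))
        r = _ratios(vals, [0.25] * 9)
        assert weighted_median(r, 100, 3).beta == pytest.approx(
            simple_median(r, 100, 3).beta, rel=1e-12
        )

    def test_weighted_median_hand_interpolation(self):
        # normalized weights (0.25, 0.25, 0.50) → s = (0.125, 0.375, 0.75)
        # interpolate 0.5 between (0.375, 0.4) and (0.75, 0.6) → 0.4667
        ses = 1 / np.sqrt(np.array([0.25, 0.25, 0.50]))
        est = weighted_median(_ratios([0.2, 0.4, 0.6], ses),
                              boot_reps=100, seed=1)
        assert est.beta == pytest.approx(0.46666667, abs=1e-6)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            simple_median(_ratios([0.1, 0.2], [0.1, 0.1]))

    def test_bootstrap_se_converges(self):
        r = _ratios([0.1, 0.3, 0.2, 0.5, 0.4, 0.15], [0.1] * 6)
        se_small = simple_median(r, boot_reps=10_000, seed=7).se
        se_large = simple_median(r, boot_reps=100_000, seed=8).se
        assert abs(se_small - se_large) / se_large < 0.05

    def test_bootstrap_is_seeded(self):
        r = _ratios([0.1, 0.3, 0.2], [0.1] * 3)
        a = simple_median(r, 500, seed=11).se
        b = simple_median(r, 500, seed=11).se
        assert a == b


class TestEgger:
    def test_exact_proportional_fit(self):
        pairs = [
            _pair(rsid=f"rs{i}", beta_exp=bx, beta_out=0.5 * bx)
            for i, bx in enumerate([0.05, 0.1, 0.15, 0.2])
        ]
        slope, intercept = egger(pairs)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_affine_shift_moves_only_intercept(self):
        pairs = [
            _pair(rsid=f"rs{i}", beta_exp=bx, beta_out=0.5 * bx + 0.02)
            for i, bx in enumerate([0.05, 0.1, 0.15, 0.2])
        ]
        slope, intercept = egger(pairs)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.beta == pytest.approx(0.02, abs=1e-10)

    def test_matches_statsmodels_wls_oracle(self, rng):
        for _ in range(20):
            pairs = _random_pairs(rng, int(rng.integers(3, 21)))
            slope, intercept = egger(pairs)
            bx = np.array([p.beta_exp for p in pairs])
            by = np.array([p.beta_out for p in pairs])
            flip = bx < 0
            bx, by = np.abs(bx), np.where(flip, -by, by)
            w = 1 / np.array([p.se_out for p in pairs]) ** 2
            fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
            assert intercept.beta == pytest.approx(fit.params[0],
                                                   abs=1e-10)
            assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_negative_exposure_betas_are_reoriented(self, rng):
        pairs = _random_pairs(rng, 8)
        flipped = [
            dataclasses.replace(p, beta_exp=-p.beta_exp,
                                beta_out=-p.beta_out)
            for p in pairs
        ]
        s1, i1 = egger(pairs)
        s2, i2 = egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, rel=1e-12)
        assert i1.beta == pytest.approx(i2.beta, rel=1e-12)


@settings(max_examples=30, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=10_000),
    k=st.integers(min_value=3, max_value=15),
)
def test_sign_equivariance_all_estimators(seed, k):
    """Negating every outcome beta negates every estimator's beta."""
    rng = np.random.default_rng(seed)
    pairs = _random_pairs(rng, k)
    negated = [dataclasses.replace(p, beta_out=-p.beta_out) for p in pairs]
    r_pos = [wald_ratio(p) for p in pairs]
    r_neg = [wald_ratio(p) for p in negated]
    assert ivw_mre(r_neg).beta == pytest.approx(-ivw_mre(r_pos).beta,
                                                rel=1e-10)
    assert simple_median(r_neg, 100, 5).beta == pytest.approx(
        -simple_median(r_pos, 100, 5).beta, rel=1e-10
    )
    assert weighted_median(r_neg, 100, 5).beta == pytest.approx(
        -weighted_median(r_pos, 100, 5).beta, rel=1e-10
    )
    s_pos, _ = egger(pairs)
    s_neg, _ = egger(negated)
    assert s_neg.beta == pytest.approx(-s_pos.beta, rel=1e-10)


def test_ci_is_beta_plus_minus_1p96_se():
    est = ivw_mre(_ratios([0.5, 0.3, 0.4], [0.2, 0.1, 0.1]))
    assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se)
    assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se)
    or_, lo, hi = est.or_scale
    assert lo < or_ < hi and lo > 0
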