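"""Causal-effect estimators: Wald ratio, IVW, MR-Egger, median family.

Reference values for the six-SNP vitamin D / atrial fibrillation instrument
set were verified against the published analysis before being frozen here.
IVW is additionally checked against an independent weighted-regression
oracle, and the weighted median against a brute-force grid search over the
weighted CDF.
"""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlink.estimators import (
    egger,
    ivw,
    ivw_weights,
    median_estimator,
    wald_ratio,
    weighted_median_point,
)
from mrlink.harmonize import HarmonizedInstrument, HarmonizedSet


def _set_from_arrays(bx, by, sy, sx=None):
    sx = sx if sx is not None else np.full_like(np.asarray(bx, float), 0.002)
    return HarmonizedSet(
        [
            HarmonizedInstrument(
                rsid=f"rs{j}",
                effect_allele="A",
                other_allele="G",
                beta_exp=float(bx[j]),
                se_exp=float(sx[j]),
                beta_out=float(by[j]),
                se_out=float(sy[j]),
                eaf_exp=0.3,
                eaf_out=0.3,
            )
            for j in range(len(bx))
        ]
    )


def _random_set(rng, L):
    bx = rng.normal(0, 0.05, L)
    bx[np.abs(bx) < 5e-3] = 5e-3  # keep instruments relevant
    by = rng.normal(0, 0.01, L)
    sy = rng.uniform(0.004, 0.02, L)
    return _set_from_arrays(bx, by, sy)


class TestWaldRatio:
    def test_single_snp_estimate(self, harmonized):
        est = wald_ratio(next(i for i in harmonized if i.rsid == "rs3755967"))
        assert est.theta == pytest.approx(0.0056 / -0.089, rel=1e-12)
        assert est.se == pytest.approx(0.0074 / 0.089, rel=1e-12)

    def test_flipped_snp_ratio_positive(self, harmonized):
        est = wald_ratio(next(i for i in harmonized if i.rsid == "rs17216707"))
        assert est.theta == pytest.approx(0.0156 / 0.026, rel=1e-12)

    def test_null_outcome_effect(self):
        h = _set_from_arrays([0.05], [0.0], [0.01])
        est = wald_ratio(h.instruments[0])
        assert est.theta == 0.0
        assert est.p == pytest.approx(1.0)

    def test_second_order_se_is_larger(self, harmonized):
        inst = next(i for i in harmonized if i.rsid == "rs17216707")
        assert wald_ratio(inst, second_order=True).se > wald_ratio(inst).se


class TestIVW:
    def test_fixture_fixed_effect(self, harmonized):
        est = ivw(harmonized, "fixed")
        assert est.or_point == pytest.approx(1.003, abs=1e-3)
        assert est.or_low == pytest.approx(0.876, abs=1e-3)
        assert est.or_high == pytest.approx(1.148, abs=1e-3)
        assert est.p == pytest.approx(0.968, abs=1e-3)

    def test_fixture_random_effects(self, harmonized):
        est = ivw(harmonized, "random")
        assert est.or_point == pytest.approx(1.003, abs=1e-3)
        assert est.or_low == pytest.approx(0.841, abs=1e-3)
        assert est.or_high == pytest.approx(1.196, abs=1e-3)
        assert est.p == pytest.approx(0.976, abs=1e-3)

    def test_homogeneous_ratios_hit_the_scale_floor(self):
        # two SNPs with identical ratios: Q = 0, random-effects SE = fixed SE
        h = _set_from_arrays([0.05, 0.02], [0.005, 0.002], [0.01, 0.012])
        fe, re = ivw(h, "fixed"), ivw(h, "random")
        assert fe.theta == pytest.approx(0.1)
        assert re.se == fe.se

    def test_single_instrument_rejected(self):
        h = _set_from_arrays([0.05], [0.005], [0.01])
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(h, "fixed")

    @given(seed=st.integers(0, 10_000), L=st.integers(2, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_closed_form_matches_regression_through_origin(self, seed, L):
        # independent oracle: weighted least squares of beta_out on beta_exp
        # without intercept, weights 1/se_out^2
        h = _random_set(np.random.default_rng(seed), L)
        est = ivw(h, "fixed")
        bx = np.array([i.beta_exp for i in h])
        by = np.array([i.beta_out for i in h])
        sy = np.array([i.se_out for i in h])
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert est.theta == pytest.approx(float(fit.params[0]), abs=1e-10)
        se_fixed = float(fit.bse[0] / np.sqrt(fit.scale))  # un-scale to fixed-effect SE
        assert est.se == pytest.approx(se_fixed, abs=1e-10)

    def test_order_and_joint_sign_flip_invariance(self, harmonized):
        ref = ivw(harmonized, "random")
        shuffled = HarmonizedSet(list(reversed(harmonized.instruments)))
        flipped = HarmonizedSet(
            [
                dataclasses.replace(i, beta_exp=-i.beta_exp, beta_out=-i.beta_out)
                if j % 2
                else i
                for j, i in enumerate(harmonized.instruments)
            ]
        )
        for variant in (shuffled, flipped):
            est = ivw(variant, "random")
            assert est.theta == pytest.approx(ref.theta, rel=1e-12)
            assert est.se == pytest.approx(ref.se, rel=1e-12)


class TestEgger:
    def test_fixture_slope(self, harmonized):
        slope, _ = egger(harmonized)
        assert slope.or_point == pytest.approx(0.924, abs=1e-3)
        assert slope.or_low == pytest.approx(0.653, abs=1e-3)
        assert slope.or_high == pytest.approx(1.307, abs=1e-3)
        assert slope.p == pytest.approx(0.678, abs=1e-3)
        assert slope.df == 4

    def test_fixture_intercept(self, harmonized):
        _, intercept = egger(harmonized)
        assert intercept.theta == pytest.approx(0.004, abs=1e-3)
        assert intercept.se == pytest.approx(0.008, abs=1e-3)
        assert intercept.p == pytest.approx(0.610, abs=1e-3)

    def test_origin_constrained_slope_equals_ivw(self):
        # algebraic identity checked numerically on random data
        rng = np.random.default_rng(11)
        h = _random_set(rng, 12)
        bx = np.abs(np.array([i.beta_exp for i in h]))
        by = np.array([i.beta_out for i in h]) * np.sign([i.beta_exp for i in h])
        sy = np.array([i.se_out for i in h])
        origin_fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert float(origin_fit.params[0]) == pytest.approx(ivw(h, "fixed").theta, abs=1e-10)

    def test_too_few_instruments_rejected(self):
        h = _set_from_arrays([0.05, 0.02], [0.005, 0.002], [0.01, 0.012])
        with pytest.raises(ValueError, match="at least 3"):
            egger(h)

    def test_collinear_exposure_betas_rejected(self):
        h = _set_from_arrays([0.05, 0.05, -0.05], [0.005, 0.004, 0.006], [0.01] * 3)
        with pytest.raises(ValueError, match="collinear"):
            egger(h)

    def test_orientation_invariance(self, harmonized):
        # flipping any SNP's (beta_exp, beta_out) jointly cannot move Egger
        ref_slope, ref_int = egger(harmonized)
        flipped = HarmonizedSet(
            [
                dataclasses.replace(i, beta_exp=-i.beta_exp, beta_out=-i.beta_out)
                for i in harmonized.instruments
            ]
        )
        slope, intercept = egger(flipped)
        assert slope.theta == pytest.approx(ref_slope.theta, rel=1e-12)
        assert intercept.theta == pytest.approx(ref_int.theta, rel=1e-12)


def _grid_oracle_bounds(ratios, weights):
    """Brute-force weighted median: argmin over a dense grid of
    |step-CDF - 0.5|; returns (plateau, max adjacent gap)."""
    ratios, weights = np.asarray(ratios, float), np.asarray(weights, float)
    grid = np.linspace(ratios.min(), ratios.max(), 20_001)
    cdf = (weights[None, :] * (ratios[None, :] <= grid[:, None])).sum(axis=1) / weights.sum()
    err = np.abs(cdf - 0.5)
    plateau = grid[err <= err.min() + 1e-12]
    gap = np.max(np.diff(np.sort(ratios))) if len(ratios) > 1 else 0.0
    return plateau, gap


class TestMedianFamily:
    def test_fixture_points(self, harmonized):
        w = median_estimator(harmonized, "weighted", n_boot=10, seed=1)
        s = median_estimator(harmonized, "simple", n_boot=10, seed=1)
        p = median_estimator(harmonized, "penalized", n_boot=10, seed=1)
        assert w.or_point == pytest.approx(0.960, abs=1e-3)
        assert s.or_point == pytest.approx(0.984, abs=1e-3)
        assert p.or_point == pytest.approx(0.960, abs=1e-3)
        assert p.theta == w.theta  # no penalty engages on this data

    def test_bootstrap_se_reproduces_published_ci(self, fitted):
        # back-calculated from the printed weighted-median CI 0.826-1.117:
        # (ln 1.117 - ln 0.826) / (2 * 1.96) = 0.0769
        assert fitted["weighted_median"].se == pytest.approx(0.0769, abs=0.008)

    def test_seed_reproducibility_and_sensitivity(self, harmonized):
        a = median_estimator(harmonized, "weighted", n_boot=200, seed=5)
        b = median_estimator(harmonized, "weighted", n_boot=200, seed=5)
        c = median_estimator(harmonized, "weighted", n_boot=200, seed=6)
        assert a.se == b.se
        assert a.se != c.se

    def test_seed_mandatory_and_boot_floor(self, harmonized):
        with pytest.raises(ValueError, match="seed"):
            median_estimator(harmonized, "weighted", n_boot=100, seed=None)
        with pytest.raises(ValueError, match="n_boot"):
            median_estimator(harmonized, "weighted", n_boot=1, seed=1)

    def test_equal_weights_equal_simple_median(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(size=9)
        assert weighted_median_point(ratios, np.ones(9)) == pytest.approx(
            weighted_median_point(ratios, np.full(9, 0.2)), rel=1e-12
        )

    def test_even_count_equal_weights_is_midpoint_of_middle_pair(self):
        ratios = np.array([0.4, -1.2, 0.1, 2.0, -0.3, 0.9])
        expected = (0.1 + 0.4) / 2
        assert weighted_median_point(ratios, np.ones(6)) == pytest.approx(expected)

    def test_dominant_snp_breakdown(self):
        # a SNP carrying > 50% of total weight pins the weighted median to
        # its ratio, up to the interpolation step which vanishes as its
        # dominance grows
        ratios = np.array([-1.0, 0.42, 3.0, 5.0])
        moderate = weighted_median_point(ratios, np.array([0.1, 10.0, 0.1, 0.1]))
        extreme = weighted_median_point(ratios, np.array([0.1, 1000.0, 0.1, 0.1]))
        assert abs(extreme - 0.42) < abs(moderate - 0.42)
        assert extreme == pytest.approx(0.42, abs=1e-3)

    @given(seed=st.integers(0, 10_000), L=st.integers(3, 25))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_interpolation_agrees_with_grid_search_oracle(self, seed, L):
        rng = np.random.default_rng(seed)
        ratios = rng.normal(size=L)
        weights = rng.uniform(0.1, 5.0, size=L)
        med = weighted_median_point(ratios, weights)
        plateau, gap = _grid_oracle_bounds(ratios, weights)
        resolution = (ratios.max() - ratios.min()) / 20_000
        distance = np.min(np.abs(plateau - med))
        assert distance <= gap + resolution

    def test_order_invariance(self, harmonized):
        ref = median_estimator(harmonized, "weighted", n_boot=50, seed=2)
        shuffled = HarmonizedSet(list(reversed(harmonized.instruments)))
        est = median_estimator(shuffled, "weighted", n_boot=50, seed=2)
        assert est.theta == pytest.approx(ref.theta, rel=1e-12)

    def test_ivw_weights_formula(self, harmonized):
        bx = np.array([i.beta_exp for i in harmonized])
        sy = np.array([i.se_out for i in harmonized])
        assert ivw_weights(bx, sy) == pytest.approx(bx**2 / sy**2)
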