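"""Causal estimators against closed forms and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from tsmr.errors import (
    EmptyInstrumentError,
    InsufficientInstrumentsError,
    ScaleError,
    ValidationError,
)
from tsmr.estimators import (
    LOG_ODDS,
    HeterogeneityStats,
    egger_estimate,
    ivw_estimate,
    to_odds_ratio,
    wald_ci_p,
    wald_ratio,
    weighted_median_estimate,
    weighted_median_point,
)
from tsmr.harmonize import orient_for_egger

from conftest import make_instruments


def wls_oracle(g, G, sG, intercept):
    """Independent weighted-least-squares fit via statsmodels."""
    X = sm.add_constant(np.asarray(g)) if intercept else np.asarray(g)[:, None]
    fit = sm.WLS(np.asarray(G), X, weights=1.0 / np.asarray(sG) ** 2).fit()
    return fit.params


class TestWaldRatio:
    def test_arithmetic(self):
        (inst,) = make_instruments([0.1], [0.02], [0.01])
        est = wald_ratio(inst)
        assert est.estimate == pytest.approx(0.2, abs=1e-15)
        assert est.se == pytest.approx(0.1, abs=1e-15)

    def test_zero_outcome_effect(self):
        (inst,) = make_instruments([0.3], [0.0], [0.01])
        assert wald_ratio(inst).estimate == 0.0

    def test_sign_symmetry(self):
        (a,) = make_instruments([0.1], [0.02], [0.01])
        (b,) = make_instruments([-0.1], [-0.02], [0.01])
        assert wald_ratio(a).estimate == wald_ratio(b).estimate
        assert wald_ratio(a).se == wald_ratio(b).se

    def test_zero_gamma_rejected(self):
        (inst,) = make_instruments([0.0], [0.02], [0.01])
        with pytest.raises(ValidationError, match="rs1"):
            wald_ratio(inst)


class TestIVW:
    def test_exact_proportional_data(self):
        insts = make_instruments([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.01, 0.01, 0.02])
        est, het = ivw_estimate(insts)
        assert est.estimate == pytest.approx(0.2, abs=1e-12)
        assert est.se == pytest.approx(1 / 30, abs=1e-12)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0

    def test_heterogeneous_two_snp_example(self):
        insts = make_instruments([0.1, 0.2], [0.03, 0.02], [0.01, 0.01])
        est, het = ivw_estimate(insts)
        assert est.estimate == pytest.approx(0.14, abs=1e-12)
        assert het.Q == pytest.approx(3.2, abs=1e-12)
        assert het.df == 1
        assert het.i2 == pytest.approx(68.75, abs=1e-10)

    def test_single_instrument_reduces_to_wald(self):
        insts = make_instruments([0.13], [0.035], [0.012])
        est, het = ivw_estimate(insts)
        w = wald_ratio(insts[0])
        assert est.estimate == pytest.approx(w.estimate, abs=1e-15)
        assert est.se == pytest.approx(w.se, abs=1e-15)
        assert het.Q == 0.0 and het.df == 0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInstrumentError):
            ivw_estimate([])

    def test_equals_meta_analysis_of_wald_ratios(self, rng):
        """IVW is the inverse-variance meta-analysis of per-SNP ratios with weights γ²/σ_Γ²."""
        g = rng.normal(0.1, 0.05, 15)
        G = rng.normal(0.02, 0.03, 15)
        sG = rng.uniform(0.005, 0.05, 15)
        insts = make_instruments(g, G, sG)
        est, _ = ivw_estimate(insts)
        ratios = G / g
        w = g**2 / sG**2
        meta = np.sum(w * ratios) / np.sum(w)
        assert est.estimate == pytest.approx(meta, rel=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(w)), rel=1e-12)

    def test_random_effects_inflates_se_only_when_overdispersed(self):
        insts = make_instruments([0.1, 0.2], [0.03, 0.02], [0.01, 0.01])  # Q=3.2 > df=1
        fe, het = ivw_estimate(insts)
        re_, _ = ivw_estimate(insts, random_effects=True)
        assert re_.se == pytest.approx(fe.se * np.sqrt(het.Q / het.df), rel=1e-12)
        homog = make_instruments([0.1, 0.2], [0.02, 0.04], [0.01, 0.01])  # Q=0
        fe2, _ = ivw_estimate(homog)
        re2, _ = ivw_estimate(homog, random_effects=True)
        assert re2.se == fe2.se


class TestEgger:
    def test_exact_affine_data(self):
        insts = make_instruments([0.1, 0.2, 0.4], [0.03, 0.05, 0.09], [0.01, 0.01, 0.01])
        slope, intercept = egger_estimate(insts)
        assert slope.estimate == pytest.approx(0.2, abs=1e-12)
        assert intercept.estimate == pytest.approx(0.01, abs=1e-12)

    def test_exact_data_through_origin(self):
        insts = make_instruments([0.05, 0.2, 0.35], [0.015, 0.06, 0.105], [0.02, 0.01, 0.03])
        slope, intercept = egger_estimate(insts)
        assert intercept.estimate == pytest.approx(0.0, abs=1e-12)
        assert slope.estimate == pytest.approx(0.3, abs=1e-12)

    def test_matches_wls_oracle(self, rng):
        g = np.abs(rng.normal(0.1, 0.05, 6))
        G = rng.normal(0.02, 0.03, 6)
        sG = rng.uniform(0.005, 0.05, 6)
        slope, intercept = egger_estimate(make_instruments(g, G, sG))
        b = wls_oracle(g, G, sG, intercept=True)
        assert slope.estimate == pytest.approx(b[1], rel=1e-11)
        assert intercept.estimate == pytest.approx(b[0], rel=1e-11)

    def test_permutation_invariant(self, rng):
        g = np.abs(rng.normal(0.1, 0.05, 8))
        G = rng.normal(0.02, 0.03, 8)
        sG = rng.uniform(0.005, 0.05, 8)
        s1, i1 = egger_estimate(make_instruments(g, G, sG))
        perm = rng.permutation(8)
        s2, i2 = egger_estimate(make_instruments(g[perm], G[perm], sG[perm]))
        assert s1.estimate == pytest.approx(s2.estimate, rel=1e-12)
        assert i1.estimate == pytest.approx(i2.estimate, rel=1e-12)

    def test_too_few_instruments(self):
        insts = make_instruments([0.1, 0.2], [0.02, 0.04], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger_estimate(insts)

    def test_unoriented_input_rejected(self):
        insts = make_instruments([-0.1, 0.2, 0.3], [0.02, 0.04, 0.05], [0.01] * 3)
        with pytest.raises(ValidationError, match="orient"):
            egger_estimate(insts)


class TestWeightedMedian:
    def test_equal_weights_symmetric(self):
        insts = make_instruments([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.05] * 3)
        est = weighted_median_estimate(insts, n_boot=100, seed=1)
        assert est.estimate == pytest.approx(0.2, abs=1e-15)

    def test_unequal_weight_interpolation(self):
        # weights γ²/σ_Γ² = (1, 1, 2) for ratios (0.1, 0.2, 0.3)
        sG = [1.0, 1.0, 1 / np.sqrt(2)]
        insts = make_instruments([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], sG)
        est = weighted_median_estimate(insts, n_boot=100, seed=1)
        assert est.estimate == pytest.approx(0.7 / 3, abs=1e-12)

    def test_identical_ratios_degenerate(self):
        insts = make_instruments([0.1, 0.2, 0.3], [0.02, 0.04, 0.06], [1e-8] * 3,
                                 se_gamma=[1e-8] * 3)
        est = weighted_median_estimate(insts, n_boot=200, seed=2)
        assert est.estimate == pytest.approx(0.2, abs=1e-12)
        assert est.se < 1e-4  # bootstrap noise only through tiny SEs

    def test_equal_weights_equal_sample_median_odd_count(self, rng):
        ratios = rng.normal(0.2, 0.1, 9)
        w = np.ones(9)
        assert weighted_median_point(ratios, w) == pytest.approx(np.median(ratios), abs=1e-14)

    def test_bootstrap_seed_reproducible(self):
        insts = make_instruments([0.1, 0.2, 0.3], [0.03, 0.05, 0.04], [0.01] * 3)
        a = weighted_median_estimate(insts, n_boot=200, seed=42)
        b = weighted_median_estimate(insts, n_boot=200, seed=42)
        assert a == b
        c = weighted_median_estimate(insts, n_boot=200, seed=43)
        assert c.se != a.se

    def test_too_few_instruments(self):
        insts = make_instruments([0.1, 0.2], [0.02, 0.04], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median_estimate(insts, n_boot=100, seed=1)


class TestWaldCiP:
    def test_reference_values(self):
        lo, hi, p = wald_ci_p(0.2, 0.1)
        assert lo == pytest.approx(0.0040036, abs=1e-6)
        assert hi == pytest.approx(0.3959964, abs=1e-6)
        assert p == pytest.approx(0.0455003, abs=1e-6)

    def test_null_estimate(self):
        lo, hi, p = wald_ci_p(0.0, 0.5)
        assert p == 1.0
        assert lo == -hi

    def test_se_must_be_positive(self):
        with pytest.raises(ValidationError):
            wald_ci_p(0.1, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(z1=st.floats(0, 10), z2=st.floats(0, 10))
    def test_p_monotone_in_z(self, z1, z2):
        _, _, p1 = wald_ci_p(z1, 1.0)
        _, _, p2 = wald_ci_p(z2, 1.0)
        if z1 < z2:
            assert p1 >= p2


class TestOddsRatioScale:
    def test_null_log_odds_maps_to_unit_or(self):
        insts = make_instruments([0.1, 0.2, 0.3], [0.0, 0.0, 0.0], [0.01] * 3)
        est, _ = ivw_estimate(insts, scale=LOG_ODDS)
        orr = to_odds_ratio(est)
        assert orr.estimate == 1.0
        assert orr.ci_low < 1.0 < orr.ci_high

    def test_exponentiation(self):
        insts = make_instruments([1.0], [0.207], [0.05])
        est, _ = ivw_estimate(insts, scale=LOG_ODDS)
        orr = to_odds_ratio(est)
        assert orr.estimate == pytest.approx(np.exp(0.207), rel=1e-12)
        assert orr.estimate == pytest.approx(1.23, abs=0.003)
        assert orr.pval == est.pval and orr.se == est.se

    def test_continuous_scale_rejected(self):
        insts = make_instruments([1.0], [0.2], [0.05])
        est, _ = ivw_estimate(insts)  # linear scale
        with pytest.raises(ScaleError):
            to_odds_ratio(est)

    def test_order_preserved(self):
        insts = make_instruments([0.5, 0.6, 0.7], [0.1, 0.15, 0.12], [0.02] * 3)
        est, _ = ivw_estimate(insts, scale=LOG_ODDS)
        orr = to_odds_ratio(est)
        assert orr.ci_low < orr.estimate < orr.ci_high


class TestHeterogeneityStats:
    def test_i2_zero_when_q_below_df(self):
        het = HeterogeneityStats.from_q(1.5, 5)
        assert het.i2 == 0.0

    def test_i2_formula(self):
        het = HeterogeneityStats.from_q(10.0, 4)
        assert het.i2 == pytest.approx(60.0, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(q=st.floats(0, 1e6), df=st.integers(0, 50))
    def test_i2_bounded(self, q, df):
        het = HeterogeneityStats.from_q(q, df)
        assert 0 <= het.i2 <= 100


class TestCIContract:
    def test_ci_width_matches_normal_quantile(self, rng):
        g = rng.normal(0.1, 0.03, 10)
        G = rng.normal(0.02, 0.02, 10)
        sG = rng.uniform(0.01, 0.03, 10)
        est, _ = ivw_estimate(make_instruments(g, G, sG))
        z = stats.norm.ppf(0.975)
        assert est.ci_high - est.ci_low == pytest.approx(2 * z * est.se, rel=1e-12)
        assert est.ci_low <= est.estimate <= est.ci_high
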