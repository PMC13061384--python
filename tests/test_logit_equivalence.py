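"""Logit-equivalence additivity test: lines, dose conversion, slope test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mixtox.doseresponse import log_logistic_activity
from mixtox.logit_equivalence import (
    LogitEquivalenceModel,
    equivalent_concentration,
    expected_inhibition,
    fit_logit_line,
    line_from_log_logistic,
    logit_inhibition,
    slope_test,
)
from mixtox.pipeline import demo_ache_agents, demo_ache_concentrations
from mixtox.simulate import simulate_ache_assay

# spans ~2% to ~99% inhibition for the curves used below, so no point clips
GRID = np.geomspace(0.05, 15.0, 9)


class TestFitLogitLine:
    def test_noiseless_log_logistic_gives_analytic_line(self):
        ic50, hill = 0.7, 1.6
        line = fit_logit_line(GRID, log_logistic_activity(GRID, ic50, hill))
        exact = line_from_log_logistic(ic50, hill)
        assert line.slope == pytest.approx(exact.slope, rel=1e-6)
        assert line.intercept == pytest.approx(exact.intercept, rel=1e-6)

    def test_duplicated_dataset_identical_line(self):
        c = np.array([0.1, 1.0, 10.0])
        a = np.array([90.0, 50.0, 10.0])
        l1 = fit_logit_line(c, a)
        l2 = fit_logit_line(np.tile(c, 2), np.tile(a, 2))
        assert l1.slope == pytest.approx(l2.slope, rel=1e-12)
        assert l1.intercept == pytest.approx(l2.intercept, rel=1e-12)

    def test_clip_events_counted(self):
        c = np.array([0.01, 0.1, 1.0, 10.0])
        a = np.array([100.0, 99.9, 50.0, 0.0])  # inhibition 0, 0.1, 50, 100
        line = fit_logit_line(c, a)
        assert line.n_clipped_low == 2 and line.n_clipped_high == 1

    def test_all_clipped_same_side_rejected(self):
        c = np.array([0.1, 1.0, 10.0])
        with pytest.raises(ValueError, match="clipped"):
            fit_logit_line(c, np.array([100.0, 100.0, 100.0]))

    def test_requires_three_distinct_concentrations(self):
        with pytest.raises(ValueError):
            fit_logit_line([1.0, 1.0, 2.0], [60.0, 55.0, 40.0])


class TestEquivalentConcentration:
    def test_identity_for_same_line(self):
        line = line_from_log_logistic(1.0, 2.0)
        for c in (0.1, 1.0, 7.3):
            assert equivalent_concentration(c, line, line) == pytest.approx(c, rel=1e-12)

    def test_parallel_offset_closed_form(self):
        b = 2.0
        la = line_from_log_logistic(1.0, b / math.log(10))
        delta = 0.8
        lb = type(la)(agent="B", intercept=la.intercept - delta, slope=la.slope,
                      n=0, residual_se=0.0)
        out = equivalent_concentration(2.0, la, lb)
        assert out == pytest.approx(2.0 * 10 ** (delta / la.slope), rel=1e-12)

    def test_oxon_potency_gap(self):
        # equal Hill slopes, IC50s 1 and 13.6: 1 uM of A matches 13.6 uM of B
        la = line_from_log_logistic(1.0, 1.5)
        lb = line_from_log_logistic(13.6, 1.5)
        assert equivalent_concentration(1.0, la, lb) == pytest.approx(13.6, rel=1e-9)

    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3))
    def test_monotone_increasing(self, c1, c2):
        la = line_from_log_logistic(0.5, 2.0)
        lb = line_from_log_logistic(5.0, 1.0)
        lo, hi = sorted([c1, c2])
        if lo < hi:
            assert equivalent_concentration(lo, la, lb) < equivalent_concentration(
                hi, la, lb
            )

    def test_zero_slope_rejected(self):
        la = line_from_log_logistic(1.0, 1.0)
        lb = type(la)(agent="B", intercept=0.0, slope=0.0, n=0, residual_se=0.0)
        with pytest.raises(ValueError):
            equivalent_concentration(1.0, la, lb)


class TestExpectedInhibition:
    def test_degenerate_mixture_reduces_to_single_agent(self):
        la = line_from_log_logistic(1.0, 2.0)
        lb = line_from_log_logistic(3.0, 1.5)
        c = np.array([0.2, 1.0, 5.0])
        np.testing.assert_allclose(
            expected_inhibition(np.zeros(3), c, la, lb), lb.predict(c), rtol=1e-12
        )

    @given(
        split=st.floats(0.05, 0.95),
        c=st.floats(1e-2, 1e2),
        ic50=st.floats(1e-2, 1e2),
        hill=st.floats(0.3, 4.0),
    )
    def test_sham_identity_any_split(self, split, c, ic50, hill):
        line = line_from_log_logistic(ic50, hill)
        got = expected_inhibition(split * c, (1 - split) * c, line, line)
        assert got == pytest.approx(float(line.predict(c)), rel=1e-9, abs=1e-9)

    def test_ca_generated_mixture_matches_expectation(self):
        a, b = demo_ache_agents()
        conc = demo_ache_concentrations()
        df = simulate_ache_assay([a, b], conc, fractions=(0.5, 0.5),
                                 replicates=1, noise_sd=0.0)
        la = line_from_log_logistic(a.ache_ic50, a.ache_hill)
        lb = line_from_log_logistic(b.ache_ic50, b.ache_hill)
        ct = df["concentration_uM"].to_numpy()
        expected = expected_inhibition(0.5 * ct, 0.5 * ct, la, lb)
        observed, _, _ = logit_inhibition(100 - df["percent_activity"].to_numpy())
        # equal Hill slopes: the equivalence construction is exact
        np.testing.assert_allclose(observed, expected, atol=1e-6)


class TestSlopeTest:
    def test_perfect_fit_degenerate(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        res = slope_test(x, x, use_medians=False)
        assert res.slope == pytest.approx(1.0)
        assert res.degenerate and res.p_value == 1.0 and not res.reject_at_alpha

    def test_constructed_double_slope(self):
        x = np.linspace(-2, 2, 6)
        res = slope_test(2 * x, x, use_medians=False)
        assert res.slope == pytest.approx(2.0)
        assert res.degenerate

    def test_zero_variance_expected_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            slope_test(np.array([1.0, 2.0, 3.0]), np.zeros(3), use_medians=False)

    def test_medians_reduce_replicates(self):
        conc = np.repeat([1.0, 2.0, 4.0, 8.0], 3)
        exp_ = np.log10(conc)
        rng = np.random.default_rng(0)
        obs = exp_ + rng.normal(0, 0.05, conc.size)
        res = slope_test(obs, exp_, concentrations=conc, use_medians=True)
        assert res.n_points == 4

    def test_matches_statsmodels_inference(self):
        import statsmodels.api as sm
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        x = np.linspace(-3, 3, 12)
        y = 1.3 * x + rng.normal(0, 0.3, x.size)
        res = slope_test(y, x, use_medians=False)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(ols.params[1], rel=1e-10)
        assert res.slope_se == pytest.approx(ols.bse[1], rel=1e-10)
        t = (ols.params[1] - 1.0) / ols.bse[1]
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), ols.df_resid),
                                            rel=1e-10)


class TestPower:
    def test_tenfold_synergy_detected(self):
        # potency-shifted mixtures saturate the inhibition scale at the
        # top of the tested range; the flattened observed logits reject
        # the unit-slope null in the vast majority of assays
        a1, b1 = demo_ache_agents()
        a10, b10 = demo_ache_agents(shift_factor=10.0)
        conc = demo_ache_concentrations()
        la = line_from_log_logistic(a1.ache_ic50, a1.ache_hill)
        lb = line_from_log_logistic(b1.ache_ic50, b1.ache_hill)
        rng = np.random.default_rng(77)
        rejections = 0
        n_seeds = 500
        for _ in range(n_seeds):
            df = simulate_ache_assay(
                [a10, b10], conc, fractions=(0.5, 0.5), replicates=3,
                noise_sd=0.1, seed=int(rng.integers(0, 2**31 - 1)),
                noise_scale="logit",
            )
            ct = df["concentration_uM"].to_numpy()
            expected = expected_inhibition(0.5 * ct, 0.5 * ct, la, lb)
            observed, _, _ = logit_inhibition(
                100 - df["percent_activity"].to_numpy()
            )
            res = slope_test(observed, expected, concentrations=ct)
            rejections += res.reject_at_alpha
        assert rejections / n_seeds >= 0.8


class TestModel:
    def make_frames(self, noise=0.0, seed=0):
        a, b = demo_ache_agents()
        conc = demo_ache_concentrations()
        single_a = simulate_ache_assay([a], np.geomspace(a.ache_ic50 / 8,
                                                         a.ache_ic50 * 8, 8),
                                       replicates=3, noise_sd=noise, seed=seed)
        single_b = simulate_ache_assay([b], np.geomspace(b.ache_ic50 / 8,
                                                         b.ache_ic50 * 8, 8),
                                       replicates=3, noise_sd=noise, seed=seed + 1)
        mixture = simulate_ache_assay([a, b], conc, fractions=(0.5, 0.5),
                                      replicates=3, noise_sd=noise, seed=seed + 2)
        return single_a, single_b, mixture

    def test_additive_mixture_not_rejected(self):
        sa, sb, mix = self.make_frames(noise=2.0, seed=4)
        res = LogitEquivalenceModel(sa, sb, mix, agents=("OxA", "OxB")).fit()
        assert abs(res.slope_test.slope - 1.0) < 0.15
        assert not res.slope_test.reject_at_alpha
        assert "slope" in res.summary()
        report = res.to_report()
        assert report["logit_base"] == "natural"
        assert 0 <= report["p_value"] <= 1

    def test_fraction_validation(self):
        sa, sb, mix = self.make_frames()
        with pytest.raises(ValueError):
            LogitEquivalenceModel(sa, sb, mix, fractions=(0.7, 0.7))
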