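"""Benchmark-concentration estimation: normalisation, crossing, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mixtox.bmc import (
    BMRSpec,
    BenchmarkConcentrationModel,
    bmr_crossing,
    estimate_bmc,
    mask_dead_animals,
    normalize_responses,
    pav_increasing,
)
from mixtox.simulate import ScreenDesign, simulate_single_agent

CONC = [0.1, 0.316, 1.0, 3.16, 10.0]


def records_from_values(readout, is_incidence, per_conc, controls=None,
                        condition="X", worm="adult", day=12):
    """Animal-level record table from per-concentration value lists."""
    rows = []
    groups = dict(per_conc)
    if controls is not None:
        groups[0.0] = controls
    for conc, values in groups.items():
        for i, v in enumerate(values):
            rows.append({
                "condition": condition, "concentration_uM": conc,
                "worm_type": worm, "day": day,
                "plate_id": f"P{i % 3 + 1}", "well_id": f"W{i}",
                "readout": readout, "direction": "+", "value": float(v),
                "is_incidence": is_incidence,
            })
    return pd.DataFrame(rows)


class TestNormalize:
    def test_incidence_counting(self):
        rec = records_from_values("stickiness", True,
                                  {1.0: [1] * 12 + [0] * 12},
                                  controls=[0] * 24)
        out = normalize_responses(rec)
        assert out.loc[0, "response"] == pytest.approx(50.0)
        assert out.loc[0, "n"] == 24

    def test_continuous_signed_percent_change(self):
        rec = records_from_values("speed_dark", False, {1.0: [0.4] * 24},
                                  controls=[1.0] * 24)
        out = normalize_responses(rec)
        minus = out[out["direction"] == "-"]["response"].iloc[0]
        plus = out[out["direction"] == "+"]["response"].iloc[0]
        assert minus == pytest.approx(60.0)
        assert plus == pytest.approx(-60.0)

    def test_missing_controls_rejected(self):
        rec = records_from_values("speed_dark", False, {1.0: [0.4] * 8})
        with pytest.raises(ValueError, match="control"):
            normalize_responses(rec)

    def test_zero_control_mean_flagged_unusable(self):
        rec = records_from_values("speed_dark", False, {1.0: [0.4] * 8},
                                  controls=[0.0] * 8)
        out = normalize_responses(rec)
        assert out.empty
        assert ("X", "adult", 12, "speed_dark") in out.attrs["unusable"]

    def test_summaries_track_generating_curve(self, demo_truth):
        design = ScreenDesign(worm_types=("adult",), days=(12,),
                              noise_sd_continuous=0.0, seed=0)
        df = simulate_single_agent(demo_truth, design, seed=0)
        out = normalize_responses(df, mask_dead=False)
        from mixtox.simulate import expected_single_response

        sub = out[(out["readout"] == "speed_dark") & (out["direction"] == "-")]
        for _, row in sub.iterrows():
            truth_resp = expected_single_response(
                demo_truth, "speed_dark", row["concentration_uM"]
            )
            assert row["response"] == pytest.approx(truth_resp, abs=1e-9)


class TestDeadAnimalMask:
    def test_dead_wells_excluded_from_behavior(self):
        behavior = records_from_values("speed_dark", False, {1.0: [9.9, 1.0]},
                                       controls=[1.0] * 4)
        lethality = records_from_values("lethality", True, {1.0: [1, 0]},
                                        controls=[0] * 4)
        # same well ids in both readouts: animal W0 died at 1.0 uM
        rec = pd.concat([behavior, lethality], ignore_index=True)
        masked = mask_dead_animals(rec)
        kept = masked[(masked["readout"] == "speed_dark")
                      & (masked["concentration_uM"] == 1.0)]["value"]
        assert list(kept) == [1.0]
        # lethality rows are untouched
        assert (masked["readout"] == "lethality").sum() == 6


class TestCrossing:
    def test_log_linear_interpolation(self):
        bmc = bmr_crossing(CONC, [0, 10, 30, 70, 90], 50.0)
        # midway between 1 and 3.16 in log10 space
        assert bmc == pytest.approx(10 ** (0.5 * np.log10(3.16)), rel=1e-9)

    def test_exact_hit_returns_tested_concentration(self):
        assert bmr_crossing(CONC, [0, 10, 50, 70, 90], 50.0) == pytest.approx(1.0)

    def test_no_crossing_is_nan(self):
        assert np.isnan(bmr_crossing(CONC, [0, 5, 10, 15, 20], 50.0))

    def test_first_crossing_wins(self):
        # non-monotone series crossing twice: scanned low to high
        bmc = bmr_crossing(CONC, [0, 60, 10, 80, 90], 50.0)
        assert 0.1 < bmc < 0.316

    def test_floor_convention(self):
        assert bmr_crossing(CONC, [70, 80, 90, 95, 99], 50.0) == pytest.approx(0.1)


class TestPav:
    @given(
        hnp.arrays(np.float64, st.integers(2, 8),
                   elements=st.floats(-100, 100, allow_nan=False))
    )
    def test_matches_sklearn_isotonic(self, row):
        from sklearn.isotonic import IsotonicRegression

        ours = pav_increasing(row[None, :])[0]
        ref = IsotonicRegression(increasing=True).fit_transform(
            np.arange(row.size), row
        )
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_already_monotone_untouched(self):
        row = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(pav_increasing(row), row)


class TestEstimate:
    def spec(self, readout="stickiness", bmr=50.0, incidence=True, direction="+"):
        return BMRSpec(readout=readout, worm_type="adult", day=12,
                       direction=direction, bmr=bmr, is_incidence=incidence)

    def test_subthreshold_response_inactive(self):
        rec = records_from_values(
            "stickiness", True,
            {c: [1] * 5 + [0] * 19 for c in CONC},  # ~20% max, BMR 50
            controls=[0] * 24,
        )
        est = estimate_bmc(rec, self.spec(), n_boot=200, seed=1)
        assert not est.active
        assert est.hit_confidence == 0.0
        assert np.isnan(est.bmc_median)

    def test_seeded_determinism(self, demo_screen, bmr_table):
        spec = self.spec("lethality", bmr=20.0)
        a = estimate_bmc(demo_screen, spec, n_boot=300, seed=42)
        b = estimate_bmc(demo_screen, spec, n_boot=300, seed=42)
        assert a == b

    def test_quantile_ordering_and_range(self, demo_screen, bmr_table):
        model = BenchmarkConcentrationModel(demo_screen, bmr_table)
        res = model.fit(n_boot=300, seed=9)
        for est in res.estimates:
            if est.active:
                assert est.bmc_lb <= est.bmc_median <= est.bmc_ub
                assert est.bmc_median <= 10.0

    def test_noiseless_bmc_matches_grid_crossing(self, demo_truth):
        from mixtox.bmc import bmr_crossing as crossing
        from mixtox.simulate import expected_single_response

        design = ScreenDesign(worm_types=("adult",), days=(12,),
                              noise_sd_continuous=0.0, seed=0)
        df = simulate_single_agent(demo_truth, design, seed=0)
        spec = self.spec("speed_dark", bmr=50.0, incidence=False, direction="-")
        est = estimate_bmc(df, spec, n_boot=200, seed=0)
        truth_resp = [expected_single_response(demo_truth, "speed_dark", c)
                      for c in CONC]
        expected = crossing(CONC, truth_resp, 50.0)
        assert est.active
        assert est.bmc_median == pytest.approx(expected, rel=1e-6)
        assert est.bmc_ub / est.bmc_lb == pytest.approx(1.0, rel=1e-6)

    def test_monotone_potency_shift(self):
        # shifting the generating EC50 tenfold shifts the BMC tenfold
        from mixtox.simulate import AgentTruth

        bmcs = []
        for ec50 in (0.3, 3.0):
            truth = AgentTruth(
                name="T", ec50={"speed_dark": ec50}, hill={"speed_dark": 2.0},
                max_effect={"speed_dark": 80.0}, direction={"speed_dark": "-"},
                is_incidence={"speed_dark": False},
            )
            design = ScreenDesign(worm_types=("adult",), days=(12,),
                                  noise_sd_continuous=0.0, seed=0)
            df = simulate_single_agent(truth, design, seed=0)
            est = estimate_bmc(
                df, self.spec("speed_dark", 50.0, False, "-"), n_boot=100, seed=0
            )
            bmcs.append(est.bmc_median)
        ratio = bmcs[1] / bmcs[0]
        assert 10.0 * 0.75 <= ratio <= 10.0 * 1.25

    def test_low_n_boot_flagged(self, demo_screen):
        est = estimate_bmc(demo_screen, self.spec("lethality", 20.0),
                           n_boot=50, seed=0)
        assert "low_n_boot" in est.flags

    def test_too_few_concentrations_rejected(self):
        rec = records_from_values("stickiness", True,
                                  {0.1: [1] * 8, 1.0: [1] * 8, 10.0: [1] * 8},
                                  controls=[0] * 8)
        with pytest.raises(ValueError, match="4"):
            estimate_bmc(rec, self.spec(), n_boot=100, seed=0)


def test_model_pairs_series_with_bmr_table(demo_screen, bmr_table, demo_truth):
    res = BenchmarkConcentrationModel(demo_screen, bmr_table).fit(n_boot=200, seed=3)
    frame = res.frame
    # one series per incidence readout, two per continuous readout
    expected_series = sum(
        1 if demo_truth.is_incidence[r] else 2 for r in demo_truth.readouts
    )
    assert len(frame) == expected_series
    assert set(frame["condition"]) == {demo_truth.name}
    assert "Benchmark concentrations" in res.summary()
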