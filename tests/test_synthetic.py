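"""Design generation, trait models and the trace/raster simulators."""

import numpy as np
import pandas as pd
import pytest

from ectoscope.errors import (
    DegenerateTraceError,
    DegenerateTrialError,
    InvalidSpecificationError,
)
from ectoscope.factors import BETWEEN_FACTORS, LEVELS
from ectoscope.synthetic import (
    DesignSpec,
    EffectModel,
    generate_design,
    simulate_climate_rasters,
    simulate_mito_trace,
    simulate_respirometry_trace,
    simulate_swim_trial,
    simulate_traits,
)
from ectoscope.synthetic.design import coded_interaction


class TestDesign:
    @pytest.mark.parametrize(
        "n, rows, fish", [(1, 16, 8), (2, 32, 16), (16, 256, 128)]
    )
    def test_row_and_fish_counts(self, n, rows, fish):
        d = generate_design(DesignSpec(n_per_group=n))
        assert len(d) == rows
        assert d["fish_id"].nunique() == fish

    def test_every_fish_measured_at_both_test_temperatures(self):
        d = generate_design(DesignSpec(n_per_group=3))
        per_fish = d.groupby("fish_id")["test_temp"].agg(["count", "nunique"])
        assert (per_fish["count"] == 2).all()
        assert (per_fish["nunique"] == 2).all()

    def test_balanced_between_cells(self):
        d = generate_design(DesignSpec(n_per_group=4))
        cells = d.drop_duplicates("fish_id").groupby(list(BETWEEN_FACTORS)).size()
        assert len(cells) == 8
        assert (cells == 4).all()

    def test_deterministic(self):
        a = generate_design(DesignSpec(n_per_group=5, seed=3))
        b = generate_design(DesignSpec(n_per_group=5, seed=3))
        assert a.to_csv() == b.to_csv()

    def test_invalid_group_size(self):
        with pytest.raises(InvalidSpecificationError):
            DesignSpec(n_per_group=0)


class TestEffectModel:
    def test_exact_when_noiseless(self):
        d = generate_design(DesignSpec(n_per_group=1))
        model = EffectModel(
            baseline=2.0,
            main_effects={"day_length": {"short": 0.5}},
            interactions={(("thyroid", "hypo"), ("test_temp", 28)): -0.25},
        )
        y = simulate_traits(d, model, seed=0)
        expected = (
            2.0
            + 0.5 * (d["day_length"] == "short")
            - 0.25 * ((d["thyroid"] == "hypo") & (d["test_temp"] == 28))
        )
        np.testing.assert_allclose(y, expected)

    def test_fish_intercept_shared_within_fish(self):
        d = generate_design(DesignSpec(n_per_group=4))
        model = EffectModel(baseline=0.0, within_fish_sd=1.0, noise_sd=0.0)
        y = simulate_traits(d, model, seed=1)
        d = d.assign(y=y)
        spread = d.groupby("fish_id")["y"].agg(lambda v: v.max() - v.min())
        assert (spread == 0).all()
        assert d["y"].std() > 0

    def test_deterministic_given_seed(self):
        d = generate_design(DesignSpec(n_per_group=2))
        model = EffectModel(baseline=0.0, noise_sd=1.0, within_fish_sd=0.3)
        np.testing.assert_array_equal(
            simulate_traits(d, model, seed=7), simulate_traits(d, model, seed=7)
        )

    def test_coded_interaction_is_balanced(self):
        table = coded_interaction(("day_length", "thyroid"), 0.5)
        assert len(table) == 4
        assert sum(table.values()) == pytest.approx(0.0)
        assert sorted(table.values()) == [-0.5, -0.5, 0.5, 0.5]


class TestRespirometrySim:
    def test_zero_mo2_gives_flat_trace(self):
        tr = simulate_respirometry_trace(0.0, mass_g=1.0, noise_sd=0.0)
        assert np.ptp(tr.o2_umol_per_l) == 0.0

    def test_slope_matches_chamber_arithmetic(self):
        # 1 μmol/g/min x 1 g in the 27 ml chamber: -37.037 μmol/L/min
        tr = simulate_respirometry_trace(
            1.0, mass_g=1.0, volume_l=0.027, duration_min=5.0, noise_sd=0.0
        )
        slopes = np.diff(tr.o2_umol_per_l) / np.diff(tr.time_min)
        np.testing.assert_allclose(slopes, -1.0 / 0.027, rtol=1e-9)

    def test_seed_determinism(self):
        a = simulate_respirometry_trace(0.5, mass_g=0.5, noise_sd=2.0, seed=11)
        b = simulate_respirometry_trace(0.5, mass_g=0.5, noise_sd=2.0, seed=11)
        np.testing.assert_array_equal(a.o2_umol_per_l, b.o2_umol_per_l)

    def test_truncates_before_anoxia(self):
        tr = simulate_respirometry_trace(
            5.0, mass_g=1.0, volume_l=0.027, duration_min=30.0, noise_sd=0.0
        )
        assert tr.time_min[-1] < 30.0
        assert (tr.o2_umol_per_l >= 0).all()

    def test_immediate_anoxia_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            simulate_respirometry_trace(
                500.0, mass_g=10.0, volume_l=0.027, noise_sd=0.0
            )


class TestSwimSim:
    def test_inverts_brett_formula(self):
        rec = simulate_swim_trial(0.11)
        assert rec.last_completed_speed_ms == pytest.approx(0.10)
        assert rec.time_at_final_speed_min == pytest.approx(2.5)  # 150 s

    def test_ucrit_on_step_boundary_gives_zero_time(self):
        rec = simulate_swim_trial(0.10)
        assert rec.last_completed_speed_ms == pytest.approx(0.10)
        assert rec.time_at_final_speed_min == pytest.approx(0.0, abs=1e-9)

    def test_below_initial_speed_rejected(self):
        with pytest.raises(DegenerateTrialError):
            simulate_swim_trial(0.03)

    def test_initial_failure_mode(self):
        rec = simulate_swim_trial(0.03, allow_initial_failure=True)
        assert rec.last_completed_speed_ms == 0.0
        assert rec.time_at_final_speed_min == pytest.approx(10.0)  # 0.03/0.06 x 20


class TestMitoSim:
    def test_state3_oxygen_budget_matches_stoichiometry(self):
        # 0.5 mM ADP in 0.1 ml = 50 nmol; at P:O 1.0 State 3 must consume
        # 25 nmol O2 (2 atoms per molecule)
        tr = simulate_mito_trace(volume_ml=0.1, target_po=1.0, noise_sd=0.0)
        gt = tr.ground_truth
        slope = gt["segment_slopes"]["state3"]
        dur = gt["state4_onset_min"] - tr.events["adp_added"]
        consumed_nmol = -slope * dur * tr.chamber_volume_ml
        assert consumed_nmol == pytest.approx(25.0, rel=0.02)
        assert gt["realized_po"] == pytest.approx(1.0, rel=0.02)

    def test_uncoupled_input_contract(self):
        with pytest.raises(InvalidSpecificationError):
            simulate_mito_trace(
                state_rates={"state2": 10, "state3": 20, "state4": 25, "fccp": 60}
            )

    def test_seed_determinism(self):
        a = simulate_mito_trace(target_po=1.5, noise_sd=1.0, seed=5)
        b = simulate_mito_trace(target_po=1.5, noise_sd=1.0, seed=5)
        np.testing.assert_array_equal(a.o2_nmol_per_ml, b.o2_nmol_per_ml)

    def test_oxygen_exhaustion_rejected(self):
        with pytest.raises(DegenerateTraceError):
            simulate_mito_trace(target_po=1.5, start_o2_nmol_ml=50.0)


class TestClimateSim:
    def test_constant_climate_has_zero_seasonality(self):
        from ectoscope.climate import seasonality

        stack = simulate_climate_rasters(
            shape=(6, 8), amplitude_max_c=0.0, diurnal_range_c=0.0, noise_sd=0.0
        )
        np.testing.assert_allclose(seasonality(stack, "annual_range"), 0.0, atol=1e-12)
        np.testing.assert_allclose(seasonality(stack, "july_january"), 0.0, atol=1e-12)

    def test_tmax_at_least_tmin_everywhere(self):
        stack = simulate_climate_rasters(shape=(10, 10), noise_sd=1.0, seed=2)
        assert np.all(stack.tmax_monthly >= stack.tmin_monthly)

    def test_seasonality_monotone_in_latitude(self):
        from ectoscope.climate import seasonality

        stack = simulate_climate_rasters(shape=(19, 4), noise_sd=0.0)
        s = seasonality(stack, "july_january")[:, 0]
        north = s[:10]  # +90 .. 0
        assert np.all(np.diff(north) <= 1e-9)  # decreasing toward equator

    def test_seed_determinism(self):
        a = simulate_climate_rasters(shape=(5, 5), noise_sd=0.5, seed=9)
        b = simulate_climate_rasters(shape=(5, 5), noise_sd=0.5, seed=9)
        np.testing.assert_array_equal(a.tmin_monthly, b.tmin_monthly)
        np.testing.assert_array_equal(a.warming, b.warming)

    def test_invalid_shape(self):
        with pytest.raises(InvalidSpecificationError):
            simulate_climate_rasters(shape=(0, 5))
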