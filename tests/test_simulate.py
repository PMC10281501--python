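"""Synthetic-data generators: determinism, calibration against their own
truth, and schema compatibility with the analysis stages."""

import numpy as np
import pandas as pd
import pytest

from salmoscope import pipeline, simulate
from salmoscope.simulate import (CohortConfig, CTMAX_RAMP_C_PER_MIN,
                                 default_truth, generate_cohort,
                                 generate_ctmax_trials, generate_env_table,
                                 generate_growth_data, generate_o2_trace,
                                 generate_trait_table, inject_env_effect)


class TestDeterminism:
    def test_tables_bit_reproducible_under_fixed_seed(self, small_cohort, small_truth):
        for trait in ("growth", "ctmax", "rmr", "as"):
            a = generate_trait_table(trait, small_truth, small_cohort, seed=5)
            b = generate_trait_table(trait, small_truth, small_cohort, seed=5)
            pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(generate_env_table("paper", seed=3),
                                      generate_env_table("paper", seed=3))

    def test_trace_reproducible_and_seed_sensitive(self, small_truth):
        fish = {"fish_id": "F", "population": "Coleman", "acclim_temp_C": 16.0,
                "mass_g": 24.0}
        a = generate_o2_trace(small_truth, fish, 16.0, seed=1)
        b = generate_o2_trace(small_truth, fish, 16.0, seed=1)
        c = generate_o2_trace(small_truth, fish, 16.0, seed=2)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)


class TestCohort:
    def test_default_design_has_18_treatment_groups(self):
        cfg = CohortConfig()
        fish, treat = generate_cohort(cfg, seed=0)
        assert len(treat) == 18
        assert fish.groupby(["population", "acclim_temp_C"]).ngroups == 18
        assert treat.n_ctmax.between(18, 25).all()
        assert treat.n_resp.between(32, 46).all()

    def test_invalid_test_temps_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(test_temps=(9.0,))


class TestGrowth:
    def test_zero_noise_gives_exact_treatment_lines(self, small_cohort):
        truth = default_truth(small_cohort, seed=0)
        truth.growth_noise_sd = 1e-12
        df = generate_growth_data(truth, small_cohort, seed=1)
        for (p, a), sub in df.groupby(["population", "acclim_temp_C"]):
            slope, icpt = np.polyfit(sub.days, sub.mass_g, 1)
            assert slope == pytest.approx(truth.growth_slope[(p, a)], abs=5e-3)

    def test_row_count_is_treatments_by_dates_by_n(self, small_cohort, small_truth):
        df = generate_growth_data(small_truth, small_cohort, seed=2)
        n_dates = small_cohort.growth_horizon_days // 14 + 1
        assert len(df) == (len(small_cohort.treatments) * n_dates
                           * small_cohort.growth_n_per_date)

    def test_ols_slope_within_three_se_of_truth(self, small_cohort, small_truth):
        df = generate_growth_data(small_truth, small_cohort, seed=3)
        sub = df[(df.population == "Coleman") & (df.acclim_temp_C == 16.0)]
        x = sub.days.to_numpy(float)
        y = sub.mass_g.to_numpy(float)
        slope = np.polyfit(x, y, 1)[0]
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        se = resid.std(ddof=2) / np.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(slope - small_truth.growth_slope[("Coleman", 16.0)]) < 3 * se


class TestCTmax:
    def test_ramp_phase_heats_at_printed_rate(self, small_truth, small_cohort):
        """The emitted bath series must ramp at 0.33 deg C/min after the
        30-min hold (least-squares slope of the ramp phase)."""
        _, series = generate_ctmax_trials(small_truth, small_cohort, seed=4)
        one = series[series.fish_id == series.fish_id.iloc[0]]
        ramp = one[one.phase == "ramp"]
        slope = np.polyfit(ramp.time_min, ramp.temp_C, 1)[0]
        assert slope == pytest.approx(CTMAX_RAMP_C_PER_MIN, abs=1e-9)
        hold = one[one.phase == "hold"]
        assert hold.temp_C.nunique() == 1

    def test_zero_sd_puts_all_loe_at_truth_mean(self, small_cohort):
        truth = default_truth(small_cohort, seed=0)
        for cell in truth.ctmax_sd:
            truth.ctmax_sd[cell] = 1e-9
        trials, _ = generate_ctmax_trials(truth, small_cohort, seed=5)
        for (p, a), sub in trials.groupby(["population", "acclim_temp_C"]):
            assert np.allclose(sub.ctmax_C, truth.ctmax_mean[(p, a)], atol=0.01)

    def test_large_sample_mean_within_three_se(self):
        cfg = CohortConfig(populations=("Coleman",), ctmax_n_range=(200, 200))
        truth = default_truth(cfg, seed=0)
        trials, _ = generate_ctmax_trials(truth, cfg, seed=6)
        sub = trials[trials.acclim_temp_C == 16.0]
        se = truth.ctmax_sd[("Coleman", 16.0)] / np.sqrt(len(sub))
        assert abs(sub.ctmax_C.mean() - truth.ctmax_mean[("Coleman", 16.0)]) < 3 * se

    def test_nonrecovery_rate_near_six_percent(self):
        cfg = CohortConfig(populations=("Coleman",), ctmax_n_range=(400, 400))
        truth = default_truth(cfg, seed=0)
        trials, _ = generate_ctmax_trials(truth, cfg, seed=7)
        rate = 1.0 - trials.recovered.mean()
        assert 0.03 < rate < 0.09


class TestTraces:
    def test_saturation_respects_floor(self, small_truth):
        fish = {"fish_id": "F", "population": "Coleman", "acclim_temp_C": 20.0,
                "mass_g": 60.0}   # heavy fish forces period shortening
        tr = generate_o2_trace(small_truth, fish, 26.0, seed=8, noise_sd_pct=0.0)
        assert tr.samples[:, 1].min() >= 79.0

    def test_noisy_round_trip_within_five_percent(self, small_truth):
        from salmoscope.respirometry import process_trace
        cell = ("Coleman", 16.0)
        want = small_truth.rmr_at(cell, 16.0)
        errs = []
        for rep in range(10):
            fish = {"fish_id": f"F{rep}", "population": "Coleman",
                    "acclim_temp_C": 16.0, "mass_g": 24.0}
            tr = generate_o2_trace(small_truth, fish, 16.0, seed=100 + rep,
                                   noise_sd_pct=0.3, routine_period_s=1800.0,
                                   n_routine_periods=6)
            res = process_trace(tr, mmr_step_s=120.0)
            errs.append(abs(res.rmr - want) / want)
        assert np.mean(errs) < 0.05

    def test_injected_swim_step_carries_mmr(self, small_truth):
        from salmoscope.respirometry import extract_mmr
        fish = {"fish_id": "F", "population": "Coleman", "acclim_temp_C": 16.0,
                "mass_g": 24.0}
        tr = generate_o2_trace(small_truth, fish, 16.0, seed=9, noise_sd_pct=0.0)
        mmr, est = extract_mmr(tr, step_s=60.0)
        cell = ("Coleman", 16.0)
        want = small_truth.rmr_at(cell, 16.0) + small_truth.as_at(cell, 16.0)
        assert mmr == pytest.approx(want, rel=1e-6)
        assert est.period.context == "swim"


class TestEnvTable:
    def test_printed_migration_distances(self):
        env = generate_env_table("paper", seed=0).set_index("population")
        assert env.loc["Coleman", "Mig.D"] == 441.0
        assert env.loc["Trask River", "Mig.D"] == 28.0
        assert env.loc["Elk River", "Mig.D"] == 22.0
        assert env.loc["Priest Rapids", "Mig.D"] == 631.0

    def test_paper_mode_internal_consistency(self):
        env = generate_env_table("paper", seed=0)
        assert np.allclose(env.CARange, env.CAMax - env.CAMin, atol=0.05)
        # current habitats warmer than the historical reaches they truncate
        assert (env.CRAve > env.HRAve).all()
        assert abs(env.CRAve.mean() - 9.2) < 1.0
        assert abs(env.HRAve.mean() - 7.5) < 1.0

    def test_random_mode_hits_target_correlation(self):
        rs = []
        for s in range(20):
            env = generate_env_table("random", seed=s, n_populations=6,
                                     target_corr=0.9)
            rs.append(env[["CAMax", "CRMax"]].corr().iloc[0, 1])
        assert abs(np.mean(rs) - 0.9) < 0.15


class TestInjectEffect:
    def test_zero_coefficients_are_identity(self, small_truth):
        env = generate_env_table("paper", seed=0)
        new = inject_env_effect(small_truth, env, {("ctmax", "CRCMax"): 0.0})
        assert new.ctmax_mean == small_truth.ctmax_mean

    def test_positive_coefficient_orders_cells_by_predictor(self, small_truth):
        env = generate_env_table("paper", seed=0)
        new = inject_env_effect(small_truth, env, {("ctmax", "CRCMax"): 1.0})
        shift = {p: new.ctmax_mean[(p, 16.0)] - small_truth.ctmax_mean[(p, 16.0)]
                 for p, _ in small_truth.ctmax_mean if _ == 16.0}
        x = env.set_index("population").CRCMax
        pops = sorted(shift)
        assert np.corrcoef([x[p] for p in pops], [shift[p] for p in pops])[0, 1] > 0.999

    def test_unknown_predictor_rejected(self, small_truth):
        with pytest.raises(ValueError):
            inject_env_effect(small_truth, generate_env_table("paper", seed=0),
                              {("ctmax", "NotAColumn"): 1.0})


def test_emitted_tables_satisfy_pipeline_schemas(small_cohort, small_truth):
    tables = {t: generate_trait_table(t, small_truth, small_cohort, seed=11)
              for t in ("growth", "ctmax", "rmr", "mmr", "as")}
    tables["env"] = generate_env_table("paper", seed=11)
    assert pipeline.validate_inputs(tables) == []
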