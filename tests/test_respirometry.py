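"""Oxygen-trace processing: conversion equations, slope fits, RMR/MMR/AS
extraction and trial-level quality control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salmoscope.respirometry import (InsufficientDataError, InvalidPhysicsError,
                                     MeasurePeriod, MetabolicResult, O2Trace,
                                     aerobic_scope, extract_mmr, extract_rmr,
                                     fit_period_slope, fulton_k, mo2_from_slope,
                                     o2_concentration, process_trace, qc_filter)
from conftest import make_trace


class TestO2Concentration:
    @pytest.mark.parametrize("sat, alpha, bp, expected", [
        (0.0, 0.05, 700.0, 0.0),
        (100.0, 0.0563, 760.0, 0.0563 * 760.0),
        (87.5, 0.0563, 760.0, 0.875 * 0.0563 * 760.0),   # = 37.4395
    ])
    def test_known_values(self, sat, alpha, bp, expected):
        assert o2_concentration(sat, alpha, bp) == pytest.approx(expected, abs=1e-12)

    @given(sat=st.floats(0, 110), alpha=st.floats(0.01, 0.1), bp=st.floats(500, 800),
           k=st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_each_argument(self, sat, alpha, bp, k):
        base = o2_concentration(sat, alpha, bp)
        assert o2_concentration(sat, alpha * k, bp) == pytest.approx(k * base, rel=1e-9)
        assert o2_concentration(sat, alpha, bp * k) == pytest.approx(k * base, rel=1e-9)
        if sat * k <= 110:
            assert o2_concentration(sat * k, alpha, bp) == pytest.approx(k * base, rel=1e-9)

    @pytest.mark.parametrize("alpha, bp", [(0.0, 760.0), (-0.05, 760.0), (0.05, 0.0)])
    def test_invalid_physics(self, alpha, bp):
        with pytest.raises(InvalidPhysicsError):
            o2_concentration(50.0, alpha, bp)


class TestPeriodSlope:
    def test_noiseless_line_recovers_slope_exactly(self):
        tr = make_trace(mo2=3.0)
        est = fit_period_slope(tr, tr.phases[0])
        expected = -3.0 * tr.fish_mass_kg / (tr.tunnel_volume_L * 60.0)
        assert est.slope_mgO2_L_s == pytest.approx(expected, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_trace_reports_zero_slope_and_zero_r2(self):
        tr = make_trace(mo2=0.0)
        est = fit_period_slope(tr, tr.phases[0])
        assert est.slope_mgO2_L_s == 0.0
        assert est.r_squared == 0.0

    def test_matches_normal_equations_oracle_under_noise(self):
        rng = np.random.default_rng(42)
        tr = make_trace(mo2=3.0, noise_sd=0.2, seed=7)
        period = tr.phases[0]
        est = fit_period_slope(tr, period)
        t = tr.samples[:, 0]
        m = (t >= period.start_s) & (t <= period.end_s)
        x, y = t[m], o2_concentration(tr.samples[m, 1], tr.alpha_O2,
                                      tr.barometric_pressure_mmHg)
        # independent closed-form least squares
        n = x.size
        slope = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x * x).sum() - x.sum() ** 2)
        assert est.slope_mgO2_L_s == pytest.approx(slope, abs=1e-10)

    def test_too_few_samples_raises(self):
        tr = make_trace(mo2=3.0)
        with pytest.raises(InsufficientDataError):
            fit_period_slope(tr, MeasurePeriod(0, 10, "sealed", "routine"))


class TestMO2:
    @pytest.mark.parametrize("r, v, m, expected", [
        (0.0, 5.0, 0.025, 0.0),
        (-0.002, 5.0, 0.025, 24.0),
    ])
    def test_known_values(self, r, v, m, expected):
        mo2, flag = mo2_from_slope(r, v, m)
        assert mo2 == pytest.approx(expected)
        assert not flag

    def test_linear_in_volume(self):
        a, _ = mo2_from_slope(-0.001, 5.0, 0.02)
        b, _ = mo2_from_slope(-0.001, 10.0, 0.02)
        assert b == pytest.approx(2 * a)

    def test_oxygen_gain_flagged_but_converted(self):
        mo2, flag = mo2_from_slope(0.002, 5.0, 0.025)
        assert flag and mo2 == pytest.approx(24.0)


class TestRMR:
    def test_mean_of_three_lowest(self):
        rmr, n = extract_rmr([5, 4, 3, 2, 1])
        assert rmr == pytest.approx(2.0) and n == 3

    def test_all_equal(self):
        rmr, _ = extract_rmr([3.3] * 5)
        assert rmr == pytest.approx(3.3)

    def test_matches_bruteforce_after_flag_removal(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 10, 10)
        flags = [False] * 10
        flags[2] = flags[7] = True
        rmr, _ = extract_rmr(vals, flags)
        retained = sorted(v for v, f in zip(vals, flags) if not f)
        assert rmr == pytest.approx(np.mean(retained[:3]))

    def test_insufficient_periods_raises(self):
        with pytest.raises(InsufficientDataError):
            extract_rmr([1, 2, 3], [True, False, False])


class TestMMR:
    def test_constant_depletion_returns_period_mo2(self):
        tr = make_trace(mo2=8.0, period_s=960, n_periods=1, context="swim")
        mmr, est = extract_mmr(tr)
        assert mmr == pytest.approx(8.0, rel=1e-9)

    def test_steeper_second_period_wins(self):
        tr = make_trace(mo2=[6.0, 9.0], period_s=600, n_periods=2, context="swim")
        mmr, _ = extract_mmr(tr)
        assert mmr == pytest.approx(9.0, rel=1e-9)

    def test_matches_exhaustive_window_oracle(self):
        """Piecewise trace with the steepest 300-s stretch mid-period: the
        scan must equal a brute-force fit over every 1-s-offset window."""
        from salmoscope.respirometry import MeasurePeriod, O2Trace

        rng = np.random.default_rng(5)
        n = 1200
        t = np.arange(n, dtype=float)
        slope = np.full(n, -0.004)
        slope[450:800] = -0.012          # steep mid-period stretch
        sat = 100 + np.concatenate([[0], np.cumsum(slope[:-1])])
        sat += rng.normal(0, 0.02, n)
        tr = O2Trace(fish_id="X", test_temp_C=16, acclim_temp_C=16, tunnel_id="S",
                     tunnel_volume_L=5.0, fish_mass_kg=0.024,
                     barometric_pressure_mmHg=760, alpha_O2=0.0563,
                     samples=np.column_stack([t, np.clip(sat, 0, 110)]),
                     phases=[MeasurePeriod(0, n - 1, "sealed", "swim", 30.0)])
        mmr, _ = extract_mmr(tr, r2_threshold=0.0)

        conc = o2_concentration(tr.samples[:, 1], tr.alpha_O2, tr.barometric_pressure_mmHg)
        best = 0.0
        for s in range(0, n - 300):
            xs, ys = t[s:s + 301], conc[s:s + 301]
            b = np.polyfit(xs, ys, 1)[0]
            best = max(best, abs(b) * 5.0 / 0.024 * 60.0)
        assert mmr == pytest.approx(best, rel=1e-9)

    def test_no_qualifying_window_raises(self):
        tr = make_trace(mo2=5.0, period_s=200, n_periods=1, context="swim")
        with pytest.raises(InsufficientDataError):
            extract_mmr(tr)


class TestAerobicScope:
    def test_difference_and_identity(self):
        as_, neg = aerobic_scope(2.0, 10.0)
        assert as_ == 8.0 and not neg
        assert aerobic_scope(3.7, 3.7)[0] == 0.0
        rmr, as_val = 2.4, 8.9           # magnitudes near a thermal optimum
        assert rmr + as_val == pytest.approx(rmr + aerobic_scope(rmr, rmr + as_val)[0])

    def test_negative_scope_flagged_not_clipped(self):
        as_, neg = aerobic_scope(10.0, 8.0)
        assert as_ == -2.0 and neg


class TestFultonK:
    @pytest.mark.parametrize("m, l, k", [(10.0, 10.0, 1.0),
                                         (23.03, 12.4, 100 * 23.03 / 12.4 ** 3)])
    def test_known_values(self, m, l, k):
        assert fulton_k(m, l) == pytest.approx(k)

    def test_cubic_scale_invariance(self):
        assert fulton_k(8 * 23.0, 2 * 12.4) == pytest.approx(fulton_k(23.0, 12.4))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fulton_k(-1.0, 10.0)


class TestQCFilter:
    @staticmethod
    def _result(fid, flags=()):
        return MetabolicResult(fish_id=fid, test_temp_C=16, rmr=2.0, mmr=9.0,
                               aerobic_scope=7.0, qc_flags=set(flags))

    def test_clean_set_is_identity(self):
        rs = [self._result(f"f{i}") for i in range(4)]
        retained, log = qc_filter(rs)
        assert len(retained) == 4 and log.empty

    def test_rule_violations_counted(self):
        rs = ([self._result(f"ok{i}") for i in range(7)]
              + [self._result("m", {"mortality"}),
                 self._result("a", {"activity_excluded"}),
                 self._result("s", {"saturation_floor"})])
        retained, log = qc_filter(rs)
        assert len(retained) == 7 and len(log) == 3
        assert set(log.reason) == {"mortality", "activity_excluded", "saturation_floor"}

    def test_saturation_floor_boundary(self):
        tr = make_trace(mo2=3.0, start_sat=80.3)   # dips below 80% within period
        res = process_trace(tr)
        assert "saturation_floor" in res.qc_flags
        retained, _ = qc_filter([res])
        assert retained == []


class TestRoundTrip:
    def test_zero_noise_recovers_generating_rates(self, small_truth):
        """Inverse-model traces run back through the extraction chain must
        reproduce the generating RMR and MMR to < 1e-6 relative error."""
        from salmoscope.simulate import generate_o2_trace

        fish = {"fish_id": "RT", "population": "Coleman", "acclim_temp_C": 16.0,
                "mass_g": 24.0}
        tr = generate_o2_trace(small_truth, fish, 16.0, seed=1, noise_sd_pct=0.0)
        res = process_trace(tr, mmr_step_s=60.0)
        cell = ("Coleman", 16.0)
        want_rmr = small_truth.rmr_at(cell, 16.0)
        want_mmr = want_rmr + small_truth.as_at(cell, 16.0)
        assert res.rmr == pytest.approx(want_rmr, rel=1e-6)
        assert res.mmr == pytest.approx(want_mmr, rel=1e-6)
        assert res.aerobic_scope + res.rmr == res.mmr    # exact identity

    def test_r2_tends_to_one_as_noise_vanishes(self):
        r2 = []
        for sd in (0.5, 0.05, 0.0):
            tr = make_trace(mo2=4.0, noise_sd=sd, seed=11)
            r2.append(fit_period_slope(tr, tr.phases[0]).r_squared)
        assert r2[0] < r2[1] <= r2[2] == pytest.approx(1.0, abs=1e-9)
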