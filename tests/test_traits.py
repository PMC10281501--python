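"""Trait-model layer: standardization, WAIC, significance rule, contrasts,
marginal means and stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from salmoscope import reference, simulate, traits
from salmoscope.bayes import SamplerConfig
from salmoscope.traits import (MarginalMean, acclimation_capacity,
                               classify_significance, compute_waic, default_spec,
                               fit_trait_model, growth_rates, pairwise_contrasts,
                               prepare_trait_frame, standardize, stepwise_select,
                               treatment_means)


class TestStandardize:
    def test_symmetric_triple(self):
        sf = standardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), z_cols={"x": "x_z"})
        assert np.allclose(sf.data["x_z"], [-1.0, 0.0, 1.0])

    def test_constant_column_errors_with_name(self):
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame({"flat": [2.0, 2.0]}), z_cols={"flat": "z"})

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3, 7, 50)
        sf = standardize(pd.DataFrame({"x": x, "t": rng.uniform(0, 90, 50)}),
                         z_cols={"x": "x_z"}, unit_cols={"t": "t01"})
        assert np.allclose(sf.inverse("x_z", sf.data["x_z"]), x, atol=1e-10)
        assert np.allclose(sf.inverse("t01", sf.data["t01"]),
                           sf.data["t"], atol=1e-10)
        assert sf.data["t01"].between(0, 1).all()
        assert abs(sf.data["x_z"].mean()) < 1e-8


class TestWAIC:
    def test_identical_draws_have_zero_penalty(self):
        ll = np.tile([-1.3, -0.4], (5, 1))
        waic, lppd, p = compute_waic(ll)
        assert p == pytest.approx(0.0, abs=1e-12)
        assert waic == pytest.approx(-2 * (-1.3 - 0.4), abs=1e-10)

    def test_matches_direct_formula_on_toy_matrix(self):
        ll = np.array([[-1.0, -2.0], [-1.5, -0.5], [-0.7, -1.1]])
        waic, lppd, p = compute_waic(ll)
        lppd_direct = sum(logsumexp(ll[:, i]) - np.log(3) for i in range(2))
        p_direct = sum(ll[:, i].var(ddof=1) for i in range(2))
        assert lppd == pytest.approx(lppd_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, abs=1e-12)
        assert waic == pytest.approx(-2 * (lppd_direct - p_direct), abs=1e-12)

    def test_additive_in_observations(self):
        ll = np.array([[-1.0, -2.0], [-1.5, -0.5]])
        w2 = compute_waic(ll)[1]
        w3 = compute_waic(np.hstack([ll, ll[:, :1]]))[1]
        assert w3 == pytest.approx(w2 + compute_waic(ll[:, :1])[1], abs=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            compute_waic(np.array([[0.0, -np.inf]]))


class TestSignificanceRule:
    def test_unanimous_is_strong(self):
        cls, d = classify_significance(np.abs(np.random.default_rng(0).normal(size=500)) + .01)
        assert (cls, d) == ("strong", "positive")

    def test_exact_90_percent_is_weak(self):
        draws = np.concatenate([np.ones(900), -np.ones(100)])
        assert classify_significance(draws) == ("weak", "positive")

    @pytest.mark.parametrize("n_pos, expected", [
        (945, "strong"),   # exactly at the 94.5% threshold (inclusive)
        (944, "weak"),
        (850, "weak"),     # exactly at 85%
        (849, "none"),
        (500, "none"),
    ])
    def test_threshold_boundaries_inclusive(self, n_pos, expected):
        draws = np.concatenate([np.ones(n_pos), -np.ones(1000 - n_pos)])
        cls, _ = classify_significance(draws)
        assert cls == expected

    def test_monotone_in_majority_mass(self):
        order = {"none": 0, "weak": 1, "strong": 2}
        prev = -1
        for n_pos in range(500, 1001, 25):
            draws = np.concatenate([np.ones(n_pos), -np.ones(1000 - n_pos)])
            level = order[classify_significance(draws)[0]]
            assert level >= prev
            prev = level

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            classify_significance(np.ones(50))


def _mm(pop, acc, draws, trait="ctmax"):
    return MarginalMean(population=pop, acclim_temp_C=acc, trait=trait,
                        draws=np.asarray(draws, float))


class TestContrasts:
    def test_identical_cells_yield_null_contrast(self):
        d = np.random.default_rng(0).normal(size=400)
        c = pairwise_contrasts([_mm("A", 11, d), _mm("B", 11, d)])[0]
        assert c.mean == 0.0 and c.significance == "none"

    def test_eighteen_cells_give_153_contrasts(self):
        rng = np.random.default_rng(1)
        cells = [_mm(f"P{i}", a, rng.normal(size=200))
                 for i in range(6) for a in (11, 16, 20)]
        assert len(pairwise_contrasts(cells)) == 18 * 17 // 2 == 153

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = _mm("A", 11, rng.normal(size=300)), _mm("B", 11, rng.normal(1, 1, 300))
        cab = pairwise_contrasts([a, b])[0]
        cba = pairwise_contrasts([b, a])[0]
        assert np.allclose(cab.draws, -cba.draws)

    def test_mismatched_draw_counts_rejected(self):
        with pytest.raises(ValueError):
            pairwise_contrasts([_mm("A", 11, np.ones(200)), _mm("B", 11, np.ones(300))])


class TestAcclimationCapacity:
    def test_printed_treatment_means_reproduce_printed_capacity(self):
        """Degenerate (point-mass) posteriors at the published cell means
        must reproduce the published 20C-11C capacity exactly."""
        pop = "Coleman"
        m20 = _mm(pop, 20, np.full(200, reference.CTMAX_MODELED_C[(pop, 20)]))
        m11 = _mm(pop, 11, np.full(200, reference.CTMAX_MODELED_C[(pop, 11)]))
        cap = acclimation_capacity(m20, m11)
        assert cap.mean == pytest.approx(reference.CTMAX_CAPACITY[pop], abs=1e-9)

    def test_identical_inputs_give_zero(self):
        d = np.random.default_rng(3).normal(size=200)
        assert acclimation_capacity(_mm("A", 20, d), _mm("A", 11, d)).mean == 0.0

    def test_population_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            acclimation_capacity(_mm("A", 20, np.ones(200)), _mm("B", 11, np.ones(200)))


class TestModelFits:
    def test_treatment_means_recover_cell_truth(self, small_cohort, small_truth,
                                                fast_sampler):
        df = simulate.generate_trait_table("ctmax", small_truth, small_cohort, seed=10)
        tp = fit_trait_model(default_spec("ctmax"), prepare_trait_frame("ctmax", df),
                             config=fast_sampler, seed=11)
        for m in treatment_means(tp):
            truth_mean = small_truth.ctmax_mean[(m.population, m.acclim_temp_C)]
            assert abs(m.mean - truth_mean) < 4 * m.sd + 0.05

    def test_growth_rates_reported_at_treatment_level(self, small_cohort,
                                                      small_truth, fast_sampler):
        df = simulate.generate_trait_table("growth", small_truth, small_cohort, seed=12)
        tp = fit_trait_model(default_spec("growth"), prepare_trait_frame("growth", df),
                             config=fast_sampler, seed=13)
        rates = growth_rates(tp)
        # one rate per treatment cell, not per fish
        assert len(rates) == len(small_cohort.treatments)
        for m in rates:
            ols = np.polyfit(df[(df.population == m.population)
                                & (df.acclim_temp_C == m.acclim_temp_C)].days,
                             df[(df.population == m.population)
                                & (df.acclim_temp_C == m.acclim_temp_C)].mass_g, 1)[0]
            assert m.mean == pytest.approx(ols, abs=4 * m.sd + 0.01)

    def test_natural_scale_reporting_matches_shifted_fit(self, fast_sampler):
        """Fitting on the z-scale and back-transforming equals fitting the
        location-scale-shifted data directly (linear Gaussian toy)."""
        rng = np.random.default_rng(4)
        base = pd.DataFrame({
            "population": np.repeat(["A", "B"], 40),
            "acclim_temp_C": np.tile([11.0, 16.0], 40),
            "ctmax_C": rng.normal(28, 1, 80),
            "mass_g": rng.normal(20, 3, 80),
            "age_days": rng.integers(100, 200, 80),
        })
        shifted = base.assign(ctmax_C=2.0 * base.ctmax_C + 5.0)
        m1 = treatment_means(fit_trait_model(
            default_spec("ctmax"), prepare_trait_frame("ctmax", base),
            config=fast_sampler, seed=5))
        m2 = treatment_means(fit_trait_model(
            default_spec("ctmax"), prepare_trait_frame("ctmax", shifted),
            config=fast_sampler, seed=5))
        for a, b in zip(m1, m2):
            assert b.mean == pytest.approx(2 * a.mean + 5, abs=6 * 2 * a.sd)


class TestStepwise:
    @staticmethod
    def _data(effect, seed, n=120):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "population": np.repeat(["A", "B"], n // 2),
            "acclim_temp_C": np.tile([11.0, 16.0, 20.0], n // 3),
            "mass_g": rng.normal(20, 3, n),
            "age_days": rng.integers(100, 200, n),
        })
        age01 = (df.age_days - df.age_days.min()) / np.ptp(df.age_days)
        df["ctmax_C"] = (28 + 0.5 * (df.acclim_temp_C - 16) / 4
                         + effect * age01 + rng.normal(0, 0.4, n))
        return df

    def test_empty_candidates_return_base(self, fast_sampler):
        from dataclasses import replace
        base = replace(default_spec("ctmax"), fixed_formula="0 + C(treatment) + mass_z")
        sf = prepare_trait_frame("ctmax", self._data(0.0, 0))
        best, _, ledger = stepwise_select(base, [], sf, config=fast_sampler, seed=1)
        assert best == base and len(ledger) == 1

    def test_strong_predictor_included(self, fast_sampler):
        from dataclasses import replace
        base = replace(default_spec("ctmax"), fixed_formula="0 + C(treatment) + mass_z")
        sf = prepare_trait_frame("ctmax", self._data(3.0, 1))
        best, _, ledger = stepwise_select(base, ["age01"], sf,
                                          config=fast_sampler, seed=2)
        assert "age01" in best.fixed_formula
        assert ledger.accepted.sum() >= 2

    def test_noise_predictor_usually_excluded(self, fast_sampler):
        """A pure-noise candidate should be rejected by WAIC in most
        replicates (the penalty outweighs the fit gain)."""
        from dataclasses import replace
        base = replace(default_spec("ctmax"), fixed_formula="0 + C(treatment) + mass_z")
        excluded = 0
        n_rep = 20
        for r in range(n_rep):
            sf = prepare_trait_frame("ctmax", self._data(0.0, 500 + r, n=360))
            best, _, _ = stepwise_select(base, ["age01"], sf,
                                         config=SamplerConfig(draws=1000, warmup=300),
                                         seed=700 + r)
            if "age01" not in best.fixed_formula:
                excluded += 1
        assert excluded >= 0.8 * n_rep
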