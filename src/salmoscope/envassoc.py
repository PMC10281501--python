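"""Environment-phenotype association screening.

Fifteen population-level environmental predictors (latitude, migration
distance and slope, and twelve stream-temperature metrics for current and
historical rearing habitat) are screened one at a time against the five
physiological traits: 75 models in all.  Each model carries the trait's
covariates, a predictor x acclimation interaction, a random intercept for
source population, and — for the metabolic traits — a predictor x
test-temperature interaction plus the acclimation fixed effect, so the
predictor's effect can be read off at acute test temperatures 11, 16 and
20 deg C within each acclimation group.

The reported estimand per cell is the posterior of the marginal slope
d(response)/d(predictor) on the standardized scale, classified by the
two-threshold posterior-mass rule.  Growth associations are additionally
required to be robust to excluding the slowest-growing outlier population
(the "Trinity" rule): a growth cell keeps its class only when direction and
class agree between the screens with and without that population.

With six populations a population-level predictor competes with the
population random intercept; fits that fail convergence are reported as
unavailable rather than classified.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bayes import ConvergenceError, Priors, SamplerConfig
from .simulate import ENV_PREDICTORS
from .traits import (TraitModelSpec, TraitPosterior, classify_significance,
                     fit_trait_model, prepare_trait_frame, standardize)

__all__ = ["AssociationResult", "validate_env_table", "build_env_spec",
           "association_cells", "screen", "screen_trait", "trinity_robustness",
           "correlation_matrix", "REPORT_TEST_TEMPS", "METABOLIC_TRAITS"]

REPORT_TEST_TEMPS = (11.0, 16.0, 20.0)
METABOLIC_TRAITS = ("rmr", "mmr", "as")
ALL_TRAITS = ("growth", "ctmax") + METABOLIC_TRAITS


@dataclass
class AssociationResult:
    """Direction and significance of one predictor x trait x acclimation
    (x test-temperature) cell."""

    trait: str
    predictor: str
    acclim_temp_C: float
    test_temp_C: float | None
    direction: str
    significance: str
    mean: float
    sd: float
    available: bool = True
    robust_to_trinity: bool | None = None   # growth only

    def __post_init__(self):
        if self.trait in ("growth", "ctmax") and self.test_temp_C is not None:
            raise ValueError("test_temp_C applies to metabolic traits only")


def validate_env_table(table: pd.DataFrame, tol: float = 0.05) -> pd.DataFrame:
    """Check the predictor table: one row per population, the 15 predictor
    columns present, and range columns consistent with max - min."""
    missing = set(ENV_PREDICTORS) - set(table.columns)
    if missing:
        raise ValueError(f"missing predictor columns: {sorted(missing)}")
    if "population" not in table.columns:
        raise ValueError("population column required")
    if table["population"].duplicated().any():
        raise ValueError("duplicate population rows")
    for rng_col, hi, lo in (("CARange", "CAMax", "CAMin"), ("HARange", "HAMax", "HAMin")):
        if {rng_col, hi, lo} <= set(table.columns):
            diff = (table[hi] - table[lo] - table[rng_col]).abs()
            if (diff > tol).any():
                raise ValueError(f"{rng_col} inconsistent with {hi} - {lo}")
    return table


_ENV_FORMULAS = {
    "growth": "0 + pred_z * C(acclim_temp_C) * time01 + start_mass_z",
    "ctmax": "0 + pred_z * C(acclim_temp_C) + mass_z + age01",
    "rmr": "0 + pred_z * C(acclim_temp_C) + temp_z + pred_z:temp_z + age01",
    "mmr": "0 + pred_z * C(acclim_temp_C) + log2temp_z + pred_z:log2temp_z + K_z + age01",
    "as": "0 + pred_z * C(acclim_temp_C) + temp_z + temp_z2 + pred_z:temp_z + K_z",
}

_ENV_RANDOM = {
    "growth": ("population",),
    "ctmax": ("population", "chamber"),
    "rmr": ("population", "tunnel_id"),
    "mmr": ("population", "tunnel_id"),
    "as": ("population", "tunnel_id"),
}

_RESPONSE = {"growth": "mass_z", "ctmax": "ctmax_z", "rmr": "log_rmr_z",
             "mmr": "mmr_z", "as": "as_z"}


def build_env_spec(trait: str, predictor: str) -> TraitModelSpec:
    """The single-predictor environmental model for one trait.

    The trait's base (latitude) model with the predictor swapped in: the
    predictor enters z-scored (column ``pred_z``), interacting with
    acclimation temperature and — for metabolic traits — with the acute
    test temperature; source population is a random intercept.
    """
    if trait not in ALL_TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    if predictor not in ENV_PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    transform = {"growth": "none", "ctmax": "none", "rmr": "exp-log-response",
                 "mmr": "log2", "as": "quadratic"}[trait]
    return TraitModelSpec(
        trait=trait, response_col=_RESPONSE[trait],
        fixed_formula=_ENV_FORMULAS[trait],
        response_transform="log" if trait == "rmr" else "identity",
        temp_transform=transform,
        random_terms=_ENV_RANDOM[trait],
        nuisance_factors=(),
    )


def association_cells(trait: str) -> list[tuple[float, float | None]]:
    """(acclim_temp_C, test_temp_C-or-None) cells reported for one trait:
    3 for growth/ctmax, 9 for each metabolic trait."""
    if trait in ("growth", "ctmax"):
        return [(a, None) for a in (11.0, 16.0, 20.0)]
    return [(a, t) for a in (11.0, 16.0, 20.0) for t in REPORT_TEST_TEMPS]


def _prepare_env_frame(trait: str, data: pd.DataFrame, env_table: pd.DataFrame,
                       predictor: str):
    merged = data.merge(env_table[["population", predictor]], on="population",
                        how="left")
    if merged[predictor].isna().any():
        missing = sorted(set(data.population) - set(env_table.population))
        raise ValueError(f"populations absent from predictor table: {missing}")
    sf = prepare_trait_frame(trait, merged)
    x = sf.data[predictor].to_numpy(float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    sf.data["pred_z"] = (x - x.mean()) / sd
    sf.params["pred_z"] = ("z", float(x.mean()), float(sd))
    return sf


def _effect_grid(trait: str, sf, acclim: float, test_temp: float | None,
                 pred_z: float) -> pd.DataFrame:
    data = sf.data
    row = {"acclim_temp_C": acclim, "pred_z": pred_z}
    for col, (kind, *_ ) in sf.params.items():
        if col in ("pred_z",) or col == _RESPONSE[trait]:
            continue
        if kind == "z":
            row[col] = 0.0
        else:
            row[col] = float(data[col].mean())
    if test_temp is not None:
        if "temp_z" in data.columns:
            row["temp_z"] = float(sf.forward("temp_z", test_temp))
        if "temp_z2" in data.columns:
            row["temp_z2"] = row["temp_z"] ** 2
        if "log2temp_z" in data.columns:
            row["log2temp_z"] = float(sf.forward("log2temp_z", np.log2(test_temp)))
    return pd.DataFrame([row])


def _effect_draws(trait: str, tp: TraitPosterior, sf, acclim: float,
                  test_temp: float | None) -> np.ndarray:
    """Posterior of the marginal slope wrt the standardized predictor.

    Exact for these linear models via a unit finite difference in pred_z.
    For growth the slope is taken on the growth rate, i.e. the difference
    of the predictor effect between the ends of the scaled time range.
    """
    if trait == "growth":
        g = [_effect_grid(trait, sf, acclim, None, pz) for pz in (1.0, 0.0)]
        g1t1, g0t1 = [f.assign(time01=1.0) for f in g]
        g1t0, g0t0 = [f.assign(time01=0.0) for f in g]
        return ((tp.predict(g1t1) - tp.predict(g0t1))
                - (tp.predict(g1t0) - tp.predict(g0t0))).ravel()
    g1 = _effect_grid(trait, sf, acclim, test_temp, 1.0)
    g0 = _effect_grid(trait, sf, acclim, test_temp, 0.0)
    return (tp.predict(g1) - tp.predict(g0)).ravel()


def screen_trait(trait: str, data: pd.DataFrame, env_table: pd.DataFrame,
                 predictors=ENV_PREDICTORS,
                 priors: Priors = Priors(), config: SamplerConfig = SamplerConfig(),
                 seed: int = 0) -> list[AssociationResult]:
    """Screen one trait against a set of predictors; one model per predictor."""
    out: list[AssociationResult] = []
    for k, predictor in enumerate(predictors):
        spec = build_env_spec(trait, predictor)
        try:
            sf = _prepare_env_frame(trait, data, env_table, predictor)
            tp = fit_trait_model(spec, sf, priors, config, seed=seed + 1000 * k)
        except ConvergenceError:
            for acclim, tt in association_cells(trait):
                out.append(AssociationResult(trait, predictor, acclim, tt,
                                             direction="", significance="unavailable",
                                             mean=np.nan, sd=np.nan, available=False))
            continue
        for acclim, tt in association_cells(trait):
            draws = _effect_draws(trait, tp, sf, acclim, tt)
            cls, direction = classify_significance(draws)
            out.append(AssociationResult(trait, predictor, acclim, tt,
                                         direction=direction, significance=cls,
                                         mean=float(draws.mean()),
                                         sd=float(draws.std(ddof=1))))
    return out


def screen(trait_data: dict[str, pd.DataFrame], env_table: pd.DataFrame,
           predictors=ENV_PREDICTORS, priors: Priors = Priors(),
           config: SamplerConfig = SamplerConfig(), seed: int = 0,
           trinity_population: str | None = None) -> list[AssociationResult]:
    """Run the full screen over every supplied trait.

    When ``trinity_population`` is given, the growth screen runs twice —
    with and without that population — and growth cells are merged through
    :func:`trinity_robustness`.
    """
    validate_env_table(env_table)
    results: list[AssociationResult] = []
    for i, (trait, data) in enumerate(sorted(trait_data.items())):
        r = screen_trait(trait, data, env_table, predictors, priors, config,
                         seed=seed + 10_000 * i)
        if trait == "growth" and trinity_population is not None:
            sub = data[data.population != trinity_population]
            r_wo = screen_trait(trait, sub, env_table, predictors, priors, config,
                                seed=seed + 10_000 * i + 5000)
            r = trinity_robustness(r, r_wo)
        results.extend(r)
    return results


def trinity_robustness(results_with: list[AssociationResult],
                       results_without: list[AssociationResult]) -> list[AssociationResult]:
    """Keep a growth association's class only if direction and class agree
    between the screens including and excluding the outlier population."""
    def key(r):
        return (r.trait, r.predictor, r.acclim_temp_C, r.test_temp_C)

    without = {key(r): r for r in results_without}
    if {key(r) for r in results_with} != set(without):
        raise ValueError("mismatched cell sets between the two growth screens")
    merged = []
    for r in results_with:
        o = without[key(r)]
        robust = (r.available and o.available and r.direction == o.direction
                  and r.significance == o.significance)
        merged.append(replace(r, robust_to_trinity=robust,
                              significance=r.significance if robust else "none"))
    return merged


def correlation_matrix(table: pd.DataFrame, predictors=ENV_PREDICTORS) -> pd.DataFrame:
    """Pairwise Pearson correlations among the predictors (documents the
    collinearity that motivates single-predictor models).  Constant columns
    yield NaN entries."""
    if len(table) < 3:
        raise ValueError("need at least 3 populations")
    return table[list(predictors)].corr(method="pearson")


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trait": r.trait, "predictor": r.predictor,
        "acclim_temp_C": r.acclim_temp_C, "test_temp_C": r.test_temp_C,
        "direction": r.direction, "significance": r.significance,
        "mean": r.mean, "sd": r.sd, "available": r.available,
        "robust_to_trinity": r.robust_to_trinity,
    } for r in results])
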