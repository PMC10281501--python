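"""Bayesian trait models for the five physiological traits.

Five Gaussian-response models, one per trait, all with population x
acclimation-temperature interacting categorical fixed effects:

* growth    — mass as a linear function of scaled time, slope and intercept
              per treatment group plus a starting-mass covariate; the
              scientific quantity is the treatment-level growth rate (g/day),
              the posterior of the per-treatment time slope.
* ctmax     — critical thermal maximum with mass and age covariates.
* rmr       — exponential rise with acute test temperature, fit linearly on
              log-transformed response (plus swim-tunnel and age terms).
* mmr       — linear in log2(test temperature) (plus tunnel, condition
              factor, age).
* as        — second-order polynomial in test temperature per treatment
              group (plus condition factor); its vertex is the thermal
              optimum handled in :mod:`salmoscope.topt`.

Responses and continuous covariates are z-scored; time and age are scaled
to [0, 1].  Model comparison uses WAIC from stored pointwise
log-likelihoods; treatment means, pairwise contrasts and acclimation
capacities are posterior summaries classified by the two-threshold
posterior-mass rule (strong if >= 94.5% of mass is one-signed, weak if
>= 85%).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy.special import logsumexp

from .bayes import ConvergenceError, LMMPosterior, Priors, SamplerConfig, fit_lmm

__all__ = [
    "StandardizedFrame", "standardize", "TraitModelSpec", "default_spec",
    "TraitPosterior", "fit_trait_model", "compute_waic", "stepwise_select",
    "MarginalMean", "Contrast", "treatment_means", "growth_rates",
    "classify_significance", "pairwise_contrasts", "acclimation_capacity",
    "STRONG_THRESHOLD", "WEAK_THRESHOLD",
]

STRONG_THRESHOLD = 0.945
WEAK_THRESHOLD = 0.85

TRAITS = ("growth", "ctmax", "rmr", "mmr", "as")


# ---------------------------------------------------------------------------
# standardization

@dataclass
class StandardizedFrame:
    """A data frame with z-scored and unit-scaled derived columns.

    ``params`` maps derived column name -> ("z", mean, sd) or
    ("01", min, max); :meth:`inverse` undoes either transform exactly.
    """

    data: pd.DataFrame
    params: dict[str, tuple]

    def inverse(self, column: str, values):
        kind, a, b = self.params[column]
        values = np.asarray(values, float)
        if kind == "z":
            return values * b + a
        return values * (b - a) + a

    def forward(self, column: str, values):
        kind, a, b = self.params[column]
        values = np.asarray(values, float)
        if kind == "z":
            return (values - a) / b
        return (values - a) / (b - a)


def standardize(frame: pd.DataFrame, z_cols: dict[str, str] | None = None,
                unit_cols: dict[str, str] | None = None) -> StandardizedFrame:
    """Attach z-scored (``z_cols``) and 0-1 scaled (``unit_cols``) columns.

    Both arguments map source column -> new column name.  A zero-variance
    (or zero-range) source column raises ``ValueError`` naming the column.
    """
    data = frame.copy()
    params: dict[str, tuple] = {}
    for src, dst in (z_cols or {}).items():
        x = data[src].to_numpy(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))  # sample SD: [1,2,3] -> [-1,0,1]
        if sd <= 1e-12 * max(1.0, abs(mu)):             # exact or round-off constant
            raise ValueError(f"column {src!r} has zero variance; cannot z-score")
        data[dst] = (x - mu) / sd
        params[dst] = ("z", mu, sd)
    for src, dst in (unit_cols or {}).items():
        x = data[src].to_numpy(float)
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise ValueError(f"column {src!r} has zero range; cannot scale to [0,1]")
        data[dst] = (x - lo) / (hi - lo)
        params[dst] = ("01", lo, hi)
    return StandardizedFrame(data=data, params=params)


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class TraitModelSpec:
    """Declarative description of one trait model.

    ``fixed_formula`` is a patsy right-hand side; ``random_terms`` name
    categorical columns that receive exchangeable random intercepts;
    ``candidate_terms`` are entries the stepwise search may add, each either
    a formula fragment or ``("random", column)``.  ``response_transform``
    ("identity" | "log") is applied before z-scoring.
    """

    trait: str
    response_col: str
    fixed_formula: str
    response_transform: str = "identity"
    temp_transform: str = "none"    # none | exp-log-response | log2 | quadratic
    random_terms: tuple[str, ...] = ()
    candidate_terms: tuple = ()
    nuisance_factors: tuple[str, ...] = ()   # fixed factors averaged over for means

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        structural = ("treatment" in self.fixed_formula
                      or "population" in self.fixed_formula
                      or "population" in self.random_terms)
        if not structural:
            raise ValueError("population x acclimation structure must appear in every spec")


_DEFAULT_SPECS = {
    "growth": TraitModelSpec(
        trait="growth", response_col="mass_z",
        fixed_formula="0 + C(treatment) + C(treatment):time01 + start_mass_z",
        temp_transform="none",
        candidate_terms=(("random", "tank"),),
    ),
    "ctmax": TraitModelSpec(
        trait="ctmax", response_col="ctmax_z",
        fixed_formula="0 + C(treatment) + mass_z + age01",
        temp_transform="none",
        candidate_terms=(("random", "chamber"),),
    ),
    "rmr": TraitModelSpec(
        trait="rmr", response_col="log_rmr_z",
        fixed_formula="0 + C(treatment) + temp_z + C(tunnel_id) + age01",
        response_transform="log", temp_transform="exp-log-response",
        nuisance_factors=("tunnel_id",),
    ),
    "mmr": TraitModelSpec(
        trait="mmr", response_col="mmr_z",
        fixed_formula="0 + C(treatment) + log2temp_z + C(tunnel_id) + K_z + age01",
        temp_transform="log2",
        nuisance_factors=("tunnel_id",),
    ),
    "as": TraitModelSpec(
        trait="as", response_col="as_z",
        fixed_formula="0 + C(treatment) + C(treatment):temp_z + C(treatment):temp_z2 + K_z",
        temp_transform="quadratic",
    ),
}


def default_spec(trait: str) -> TraitModelSpec:
    """The default model family for one trait (see module docstring)."""
    return _DEFAULT_SPECS[trait]


# ---------------------------------------------------------------------------
# fitting

@dataclass
class TraitPosterior:
    """Posterior draws from one fitted trait model plus design metadata."""

    spec: TraitModelSpec
    posterior: LMMPosterior
    design_info: object
    sframe: StandardizedFrame
    seed: int

    @property
    def n_draws(self) -> int:
        return self.posterior.n_draws

    @property
    def pointwise_loglik(self) -> np.ndarray:
        return self.posterior.pointwise_loglik

    @property
    def diagnostics(self) -> dict[str, float]:
        return self.posterior.rhat

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        """Population-level linear predictor (random effects at 0) for each
        draw; shape (n_draws, len(newdata)), on the standardized scale."""
        (Xnew,) = build_design_matrices([self.design_info], newdata)
        return self.posterior.coef_draws @ np.asarray(Xnew).T

    def to_natural(self, z_values: np.ndarray) -> np.ndarray:
        """Back-transform standardized response draws to natural units."""
        nat = self.sframe.inverse(self.spec.response_col, z_values)
        if self.spec.response_transform == "log":
            nat = np.exp(nat)
        return nat


def prepare_trait_frame(trait: str, frame: pd.DataFrame) -> StandardizedFrame:
    """Standardize a raw trait table into the columns the default specs use.

    Expects ``population`` and ``acclim_temp_C`` (combined into
    ``treatment``), the trait response column, and whichever covariates the
    trait's family needs (mass_g, age_days, days, test_temp_C, fulton_k...).
    """
    df = frame.copy()
    df["treatment"] = df["population"].astype(str) + "@" + df["acclim_temp_C"].astype(int).astype(str)
    z_cols: dict[str, str] = {}
    unit_cols: dict[str, str] = {}
    if trait == "growth":
        z_cols["mass_g"] = "mass_z"
        z_cols["start_mass_g"] = "start_mass_z"
        unit_cols["days"] = "time01"
    elif trait == "ctmax":
        z_cols["ctmax_C"] = "ctmax_z"
        z_cols["mass_g"] = "mass_z"
        unit_cols["age_days"] = "age01"
    elif trait == "rmr":
        df["log_rmr"] = np.log(df["rmr"])
        z_cols["log_rmr"] = "log_rmr_z"
        z_cols["test_temp_C"] = "temp_z"
        unit_cols["age_days"] = "age01"
    elif trait == "mmr":
        df["log2_temp"] = np.log2(df["test_temp_C"])
        z_cols["mmr"] = "mmr_z"
        z_cols["log2_temp"] = "log2temp_z"
        z_cols["fulton_k"] = "K_z"
        unit_cols["age_days"] = "age01"
    elif trait == "as":
        z_cols["aerobic_scope"] = "as_z"
        z_cols["test_temp_C"] = "temp_z"
        z_cols["fulton_k"] = "K_z"
    else:
        raise ValueError(f"unknown trait {trait!r}")
    sf = standardize(df, z_cols, unit_cols)
    if trait == "as":
        sf.data["temp_z2"] = sf.data["temp_z"] ** 2
    return sf


def fit_trait_model(spec: TraitModelSpec, sframe: StandardizedFrame,
                    priors: Priors = Priors(),
                    config: SamplerConfig = SamplerConfig(),
                    seed: int | None = None) -> TraitPosterior:
    """Fit one trait model by Gibbs sampling; raises on non-convergence."""
    if seed is None:
        raise ValueError("seed is required")
    data = sframe.data
    Xd = dmatrix(spec.fixed_formula, data, return_type="matrix")
    design_info = Xd.design_info
    X = np.asarray(Xd)
    Z: dict[str, np.ndarray] = {}
    ranef_names: dict[str, list[str]] = {}
    for col in spec.random_terms:
        dummies = pd.get_dummies(data[col].astype(str))
        Z[col] = dummies.to_numpy(float)
        ranef_names[col] = list(dummies.columns)
    post = fit_lmm(X, data[spec.response_col].to_numpy(float), Z=Z, priors=priors,
                   config=config, seed=seed,
                   coef_names=list(design_info.column_names), ranef_names=ranef_names)
    return TraitPosterior(spec=spec, posterior=post, design_info=design_info,
                          sframe=sframe, seed=seed)


# ---------------------------------------------------------------------------
# WAIC and stepwise selection

def compute_waic(pointwise_loglik: np.ndarray) -> tuple[float, float, float]:
    """WAIC from an (n_draws, n_obs) pointwise log-likelihood matrix.

    lppd_i = log mean_d exp(ll_id) (log-sum-exp stabilized);
    p_waic_i = var_d(ll_id); waic = -2 * (lppd - p_waic).
    """
    ll = np.asarray(pointwise_loglik, float)
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    d = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(d)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1))) if d > 1 else 0.0
    waic = -2.0 * (lppd - p_waic)
    return waic, lppd, p_waic


def _with_term(spec: TraitModelSpec, term) -> TraitModelSpec:
    if isinstance(term, tuple) and term[0] == "random":
        return replace(spec, random_terms=spec.random_terms + (term[1],))
    return replace(spec, fixed_formula=f"{spec.fixed_formula} + {term}")


def _without_term(spec: TraitModelSpec, term) -> TraitModelSpec:
    if isinstance(term, tuple) and term[0] == "random":
        return replace(spec, random_terms=tuple(t for t in spec.random_terms if t != term[1]))
    return replace(spec, fixed_formula=spec.fixed_formula.replace(f" + {term}", ""))


def stepwise_select(base_spec: TraitModelSpec, candidate_terms, sframe: StandardizedFrame,
                    priors: Priors = Priors(), config: SamplerConfig = SamplerConfig(),
                    seed: int = 0) -> tuple[TraitModelSpec, TraitPosterior, pd.DataFrame]:
    """Greedy WAIC search: forward additions, then one backward pass.

    Returns the winning spec, its fitted posterior, and a ledger of every
    model tried (step, action, term, waic, accepted).
    """
    rows = []

    def fit_and_waic(spec, s):
        """A candidate whose fit fails convergence is ineligible (WAIC inf)
        rather than fatal; the base model itself must converge."""
        try:
            tp = fit_trait_model(spec, sframe, priors, config, seed=s)
        except ConvergenceError:
            return None, float("inf")
        return tp, compute_waic(tp.pointwise_loglik)[0]

    current = base_spec
    tp_current, waic_current = fit_and_waic(current, seed)
    if tp_current is None:
        tp_current = fit_trait_model(current, sframe, priors, config, seed=seed)
    rows.append({"step": 0, "action": "base", "term": "", "waic": waic_current,
                 "accepted": True})
    remaining = list(candidate_terms)
    added: list = []
    step = 1
    improved = True
    while improved and remaining:
        improved = False
        trials = []
        for term in remaining:
            cand = _with_term(current, term)
            tp, w = fit_and_waic(cand, seed + step)
            trials.append((w, term, cand, tp))
            rows.append({"step": step, "action": "add", "term": str(term), "waic": w,
                         "accepted": False})
        trials.sort(key=lambda t: t[0])
        if trials and trials[0][0] < waic_current:
            waic_current, term, current, tp_current = (trials[0][0], trials[0][1],
                                                       trials[0][2], trials[0][3])
            remaining.remove(term)
            added.append(term)
            for r in rows:
                if r["step"] == step and r["term"] == str(term):
                    r["accepted"] = True
            improved = True
        step += 1
    # single backward pass over the terms added
    for term in list(added):
        cand = _without_term(current, term)
        tp, w = fit_and_waic(cand, seed + step)
        accept = w < waic_current
        rows.append({"step": step, "action": "drop", "term": str(term), "waic": w,
                     "accepted": accept})
        if accept:
            current, tp_current, waic_current = cand, tp, w
            added.remove(term)
        step += 1
    return current, tp_current, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior summaries

@dataclass
class MarginalMean:
    """Posterior of one treatment-cell mean on the natural response scale."""

    population: str
    acclim_temp_C: float
    trait: str
    draws: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1))


@dataclass
class Contrast:
    """Paired-draw difference between two cells with its significance class."""

    pair: tuple
    draws: np.ndarray
    direction: str = ""
    significance: str = ""

    def __post_init__(self):
        if not self.direction:
            self.significance, self.direction = classify_significance(self.draws)

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=1))


def classify_significance(draws) -> tuple[str, str]:
    """Two-threshold posterior-mass rule.

    p = max(Pr(q>0), Pr(q<0)); class is "strong" if p >= 0.945, "weak" if
    p >= 0.85, else "none"; direction follows the majority mass (ties break
    to the sign of the mean).
    """
    draws = np.asarray(draws, float)
    if draws.size < 100:
        raise ValueError("need at least 100 draws to classify significance")
    p_pos = float(np.mean(draws > 0))
    p_neg = float(np.mean(draws < 0))
    if p_pos > p_neg:
        direction = "positive"
    elif p_neg > p_pos:
        direction = "negative"
    else:
        direction = "positive" if draws.mean() >= 0 else "negative"
    p = max(p_pos, p_neg)
    if p >= STRONG_THRESHOLD:
        cls = "strong"
    elif p >= WEAK_THRESHOLD:
        cls = "weak"
    else:
        cls = "none"
    return cls, direction


def _cell_grid(tp: TraitPosterior) -> pd.DataFrame:
    """One prediction row per treatment cell, expanded over nuisance-factor
    levels: covariate z-columns at 0 (the grand mean), time/age at the
    cell-specific mean."""
    data = tp.sframe.data
    cells = data[["population", "acclim_temp_C", "treatment"]].drop_duplicates()
    rows = []
    zero_cols = [c for c, (k, *_) in tp.sframe.params.items()
                 if k == "z" and c != tp.spec.response_col]
    nuisance_levels = {f: sorted(data[f].astype(str).unique())
                       for f in tp.spec.nuisance_factors}
    for _, cell in cells.iterrows():
        sub = data[data.treatment == cell.treatment]
        base = {"population": cell.population, "acclim_temp_C": cell.acclim_temp_C,
                "treatment": cell.treatment}
        for c in zero_cols:
            base[c] = 0.0
        for c in ("time01", "age01"):
            if c in data.columns:
                base[c] = float(sub[c].mean())
        if "temp_z" in data.columns:
            base["temp_z"] = 0.0
            base["temp_z2"] = 0.0
        combos = [dict()] if not nuisance_levels else [
            dict(zip(nuisance_levels, vals))
            for vals in itertools.product(*nuisance_levels.values())]
        for combo in combos:
            rows.append({**base, **combo})
    return pd.DataFrame(rows)


def treatment_means(tp: TraitPosterior) -> list[MarginalMean]:
    """Posterior treatment-cell means on the natural response scale.

    The linear predictor is evaluated per draw at reference covariates
    (z-covariates at the grand mean, time/age at the cell mean), averaged
    with equal weight over nuisance-factor levels, and back-transformed.
    For the growth trait use :func:`growth_rates` instead; the scientific
    quantity there is a rate, not a mean mass.
    """
    grid = _cell_grid(tp)
    preds = tp.predict(grid)                       # (n_draws, n_rows)
    out = []
    for (pop, acc), idx in grid.groupby(["population", "acclim_temp_C"]).groups.items():
        cell_draws = preds[:, list(idx)].mean(axis=1)
        out.append(MarginalMean(population=str(pop), acclim_temp_C=float(acc),
                                trait=tp.spec.trait, draws=tp.to_natural(cell_draws)))
    out.sort(key=lambda m: (m.population, m.acclim_temp_C))
    return out


def growth_rates(tp: TraitPosterior) -> list[MarginalMean]:
    """Treatment-level growth rate (g/day): the posterior mass change across
    the scaled time range divided by its span in days."""
    if tp.spec.trait != "growth":
        raise ValueError("growth_rates applies to the growth model only")
    lo, hi = tp.sframe.params["time01"][1], tp.sframe.params["time01"][2]
    span_days = hi - lo
    grid0 = _cell_grid(tp)
    grid0["time01"] = 0.0
    grid1 = grid0.copy()
    grid1["time01"] = 1.0
    p0, p1 = tp.predict(grid0), tp.predict(grid1)
    _, mu, sd = tp.sframe.params[tp.spec.response_col]
    out = []
    for (pop, acc), idx in grid0.groupby(["population", "acclim_temp_C"]).groups.items():
        cols = list(idx)
        diff_z = (p1[:, cols] - p0[:, cols]).mean(axis=1)
        rate = diff_z * sd / span_days           # z-scale slope -> g/day
        out.append(MarginalMean(population=str(pop), acclim_temp_C=float(acc),
                                trait="growth", draws=rate))
    out.sort(key=lambda m: (m.population, m.acclim_temp_C))
    return out


def pairwise_contrasts(means: list[MarginalMean]) -> list[Contrast]:
    """All unordered pairwise differences, paired by draw index."""
    if len(means) < 2:
        raise ValueError("need at least two cells")
    n = {m.draws.shape[0] for m in means}
    if len(n) != 1:
        raise ValueError("mismatched draw counts across cells")
    out = []
    for a, b in itertools.combinations(means, 2):
        key_a = (a.population, a.acclim_temp_C)
        key_b = (b.population, b.acclim_temp_C)
        out.append(Contrast(pair=(key_a, key_b), draws=a.draws - b.draws))
    return out


def acclimation_capacity(mean20: MarginalMean, mean11: MarginalMean) -> Contrast:
    """Warm-acclimation response: per-draw difference (20C - 11C) of a
    population's trait mean."""
    if mean20.population != mean11.population:
        raise ValueError(
            f"population mismatch: {mean20.population!r} vs {mean11.population!r}")
    if mean20.trait != mean11.trait:
        raise ValueError("trait mismatch")
    return Contrast(pair=((mean20.population, mean20.acclim_temp_C),
                          (mean11.population, mean11.acclim_temp_C)),
                    draws=mean20.draws - mean11.draws)
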