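"""Configuration, validation, orchestration and reporting.

Ties the stages together: synthetic-data generation (or CSV inputs) ->
respirometry extraction -> trait models -> thermal optima -> environmental
screen -> summary tables, under one seeded configuration.  Every run emits
a manifest (config hash, input hashes, stage timings, exclusion counts) so
results are attributable and reruns reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envassoc, respirometry, simulate, topt, traits
from .bayes import Priors, SamplerConfig

__all__ = ["PipelineConfig", "RunManifest", "validate_inputs", "run_pipeline",
           "render_report", "demo_config"]


@dataclass
class PipelineConfig:
    """All fixed constants of the analysis in one place.

    Defaults are the study's stated values: significance thresholds
    0.945/0.85, 500 posterior draws for T_opt, an 80% saturation floor, the
    r^2 linearity threshold 0.90, and the 11/16/20 deg C reporting grid.
    """

    seed: int
    out_dir: str = "results"
    draws: int = 1000
    warmup: int = 500
    chains: int = 2
    rhat_max: float = 1.01
    r2_threshold: float = respirometry.R2_THRESHOLD
    saturation_floor_pct: float = respirometry.SATURATION_FLOOR_PCT
    strong_threshold: float = traits.STRONG_THRESHOLD
    weak_threshold: float = traits.WEAK_THRESHOLD
    topt_n_draws: int = 500
    report_test_temps: tuple = envassoc.REPORT_TEST_TEMPS
    traits: tuple = ("growth", "ctmax", "rmr", "mmr", "as")
    env_predictors: tuple = simulate.ENV_PREDICTORS
    trinity_population: str | None = "Trinity River"
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    run_respirometry_demo: bool = True
    run_env_screen: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("strong_threshold", "weak_threshold", "r2_threshold"):
            v = getattr(self, name)
            if not 0.5 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0.5, 1)")

    @property
    def sampler(self) -> SamplerConfig:
        return SamplerConfig(draws=self.draws, warmup=self.warmup,
                             chains=self.chains, rhat_max=self.rhat_max)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        cfg = cls(**raw)
        if cohort:
            for k in ("populations", "acclim_temps", "test_temps",
                      "ctmax_n_range", "resp_n_range"):
                if k in cohort:
                    cohort[k] = tuple(cohort[k])
            cfg.cohort = simulate.CohortConfig(**cohort)
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)


def demo_config(seed: int = 1, out_dir: str = "results") -> PipelineConfig:
    """A desk-scale configuration: three populations, reduced sample sizes
    and draw counts, three predictors — minutes, not hours, on one CPU."""
    cohort = simulate.CohortConfig(
        populations=("Coleman", "Priest Rapids", "Trask River"),
        ctmax_n_range=(12, 14), resp_n_range=(18, 22),
        growth_n_per_date=15,
        test_temps=(8.0, 12.0, 16.0, 20.0, 24.0, 26.0),
    )
    return PipelineConfig(seed=seed, out_dir=out_dir, draws=800, warmup=400,
                          cohort=cohort,
                          env_predictors=("Latitude", "Mig.D", "CRCMax"),
                          trinity_population=None)


@dataclass
class RunManifest:
    config_hash: str
    input_hashes: dict
    stage_seconds: dict
    exclusion_counts: dict
    timestamp: str
    n_inputs: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


_SCHEMAS = {
    "growth": {"population", "acclim_temp_C", "days", "mass_g", "start_mass_g"},
    "ctmax": {"population", "acclim_temp_C", "ctmax_C", "mass_g", "age_days"},
    "rmr": {"population", "acclim_temp_C", "test_temp_C", "rmr"},
    "mmr": {"population", "acclim_temp_C", "test_temp_C", "mmr", "fulton_k"},
    "as": {"population", "acclim_temp_C", "test_temp_C", "aerobic_scope", "fulton_k"},
    "env": {"population"} | set(simulate.ENV_PREDICTORS),
}

_RANGES = {
    "acclim_temp_C": (5.0, 25.0), "test_temp_C": (5.0, 30.0),
    "ctmax_C": (15.0, 40.0), "mass_g": (0.1, 500.0),
    "saturation_pct": (0.0, 110.0),
}


def validate_inputs(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Schema and range checks keyed by table kind; returns the list of
    violations (empty = valid) and raises if any are fatal."""
    violations = []
    for kind, df in tables.items():
        want = _SCHEMAS.get(kind)
        if want is None:
            violations.append(f"{kind}: unknown table kind")
            continue
        missing = want - set(df.columns)
        if missing:
            violations.append(f"{kind}: missing columns {sorted(missing)}")
            continue
        for col, (lo, hi) in _RANGES.items():
            if col in df.columns:
                bad = df[(df[col] < lo) | (df[col] > hi)]
                for i in bad.index[:5]:
                    violations.append(f"{kind}[{i}].{col}={df.loc[i, col]} outside [{lo}, {hi}]")
    if violations:
        raise ValueError("input validation failed:\n" + "\n".join(violations))
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order; returns the results bundle and writes
    CSV summaries plus a manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_seconds: dict[str, float] = {}
    exclusions: dict[str, int] = {}
    bundle: dict = {"config": config}

    def tick(name):
        stage_seconds[name] = round(time.time() - t0 - sum(stage_seconds.values()), 2)

    # -- simulate ----------------------------------------------------------
    truth = simulate.default_truth(config.cohort, seed=config.seed)
    tables = {t: simulate.generate_trait_table(t, truth, config.cohort,
                                               seed=config.seed)
              for t in config.traits}
    env_table = simulate.generate_env_table(
        "paper", seed=config.seed) if set(config.cohort.populations) <= set(
            simulate.PAPER_POPULATIONS) else simulate.generate_env_table(
            "random", seed=config.seed, n_populations=len(config.cohort.populations))
    if set(env_table.population) != set(config.cohort.populations):
        env_table = env_table[env_table.population.isin(config.cohort.populations)]
    validate_inputs({k: v for k, v in tables.items() if k in _SCHEMAS})
    bundle["truth"], bundle["tables"], bundle["env_table"] = truth, tables, env_table
    tick("simulate")

    # -- respirometry demo (trace-level round trip on a subset) ------------
    if config.run_respirometry_demo:
        fish, _ = simulate.generate_cohort(config.cohort, truth, seed=config.seed)
        sub = fish[fish.assay == "respirometry"].groupby(
            ["population", "acclim_temp_C"], as_index=False).head(2)
        results = []
        for i, (_, f) in enumerate(sub.iterrows()):
            temp = config.cohort.test_temps[i % len(config.cohort.test_temps)]
            trace = simulate.generate_o2_trace(truth, f.to_dict(), temp,
                                               seed=config.seed + i)
            results.append(respirometry.process_trace(
                trace, r2_threshold=config.r2_threshold,
                saturation_floor_pct=config.saturation_floor_pct, mmr_step_s=30.0))
        retained, log = respirometry.qc_filter(results)
        exclusions["respirometry"] = len(log)
        bundle["respirometry"] = respirometry.results_to_frame(retained)
        bundle["respirometry_exclusions"] = log
        tick("respirometry")

    # -- trait models ------------------------------------------------------
    fits: dict[str, traits.TraitPosterior] = {}
    means: dict[str, list] = {}
    for i, trait in enumerate(config.traits):
        sf = traits.prepare_trait_frame(trait, tables[trait])
        tp = traits.fit_trait_model(traits.default_spec(trait), sf,
                                    config=config.sampler,
                                    seed=config.seed + 100 + i)
        fits[trait] = tp
        means[trait] = (traits.growth_rates(tp) if trait == "growth"
                        else traits.treatment_means(tp))
    bundle["fits"], bundle["means"] = fits, means
    caps = {}
    for trait in ("growth", "ctmax"):
        if trait in means:
            by_cell = {(m.population, m.acclim_temp_C): m for m in means[trait]}
            for pop in {m.population for m in means[trait]}:
                if (pop, 20.0) in by_cell and (pop, 11.0) in by_cell:
                    caps[(trait, pop)] = traits.acclimation_capacity(
                        by_cell[(pop, 20.0)], by_cell[(pop, 11.0)])
    bundle["acclimation_capacity"] = caps
    tick("trait_models")

    # -- thermal optima ----------------------------------------------------
    topts = {}
    if "as" in fits:
        tp = fits["as"]
        for pop in config.cohort.populations:
            for acc in config.cohort.acclim_temps:
                est = topt.estimate_topt(tp, pop, acc, n_draws=config.topt_n_draws,
                                         seed=config.seed + 7)
                topts[(pop, acc)] = est
        deltas = {}
        for pop in config.cohort.populations:
            e20, e11 = topts.get((pop, 20.0)), topts.get((pop, 11.0))
            if e20 is not None and e11 is not None and e20.concave and e11.concave:
                deltas[pop] = topt.delta_topt(e20, e11)
        bundle["topt"], bundle["delta_topt"] = topts, deltas
    tick("thermal_optimum")

    # -- environmental screen ---------------------------------------------
    if config.run_env_screen:
        assoc = envassoc.screen(
            {t: tables[t] for t in config.traits}, env_table,
            predictors=config.env_predictors,
            config=config.sampler, seed=config.seed + 300,
            trinity_population=config.trinity_population)
        bundle["associations"] = assoc
        tick("env_screen")

    # -- report ------------------------------------------------------------
    render_report(bundle, out)
    tick("report")

    manifest = RunManifest(
        config_hash=hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16],
        input_hashes={k: _hash_frame(v) for k, v in tables.items()},
        stage_seconds=stage_seconds, exclusion_counts=exclusions,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        n_inputs={k: len(v) for k, v in tables.items()},
    )
    manifest.write(out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def render_report(bundle: dict, out_dir, plots: bool = False) -> None:
    """Write the summary tables: treatment means/rates, contrasts,
    acclimation capacities, T_opt, and the association grid; with
    ``plots=True`` also a treatment-mean figure and an association-grid
    heatmap (PNG)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for trait, ms in bundle.get("means", {}).items():
        for m in ms:
            rows.append({"trait": trait, "population": m.population,
                         "acclim_temp_C": m.acclim_temp_C,
                         "mean": m.mean, "sd": m.sd})
    pd.DataFrame(rows).to_csv(out / "treatment_means.csv", index=False)

    cap_rows = []
    for (trait, pop), c in bundle.get("acclimation_capacity", {}).items():
        cap_rows.append({"trait": trait, "population": pop, "mean": c.mean,
                         "sd": c.sd, "direction": c.direction,
                         "significance": c.significance})
    pd.DataFrame(cap_rows).to_csv(out / "acclimation_capacity.csv", index=False)

    contrast_rows = []
    for trait, ms in bundle.get("means", {}).items():
        if len(ms) >= 2:
            for c in traits.pairwise_contrasts(ms):
                contrast_rows.append({"trait": trait, "a": str(c.pair[0]),
                                      "b": str(c.pair[1]), "mean": c.mean,
                                      "sd": c.sd, "significance": c.significance,
                                      "direction": c.direction})
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)

    topt_rows = []
    for (pop, acc), est in bundle.get("topt", {}).items():
        topt_rows.append({"population": pop, "acclim_temp_C": acc,
                          "topt_C": est.topt_C if est.concave else np.nan,
                          "sd_C": est.sd_C, "extrapolated": est.extrapolated,
                          "concave_fraction": est.concave_fraction})
    pd.DataFrame(topt_rows).to_csv(out / "topt.csv", index=False)

    if "associations" in bundle:
        envassoc.results_to_frame(bundle["associations"]).to_csv(
            out / "associations.csv", index=False)
    if "env_table" in bundle:
        bundle["env_table"].to_csv(out / "env_predictors.csv", index=False)
        try:
            envassoc.correlation_matrix(bundle["env_table"]).to_csv(
                out / "env_correlation.csv")
        except ValueError:
            pass
    if "respirometry" in bundle:
        bundle["respirometry"].to_csv(out / "metabolic_results.csv", index=False)
        bundle["respirometry_exclusions"].to_csv(out / "exclusion_log.csv", index=False)

    if plots:
        _render_plots(bundle, out)


def _render_plots(bundle: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = bundle.get("means", {})
    if means:
        fig, axes = plt.subplots(1, len(means), figsize=(4 * len(means), 3.2),
                                 squeeze=False)
        for ax, (trait, ms) in zip(axes[0], sorted(means.items())):
            pops = sorted({m.population for m in ms})
            for pop in pops:
                cells = sorted((m.acclim_temp_C, m.mean, m.sd)
                               for m in ms if m.population == pop)
                x, y, e = zip(*cells)
                ax.errorbar(x, y, yerr=e, marker="o", capsize=3, label=pop)
            ax.set_xlabel("acclimation temp (C)")
            ax.set_title(trait)
        axes[0][0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "treatment_means.png", dpi=120)
        plt.close(fig)

    if "associations" in bundle:
        from . import envassoc as _ea
        df = _ea.results_to_frame(bundle["associations"])
        if not df.empty:
            order = {"none": 0, "weak": 1, "strong": 2, "unavailable": np.nan}
            df["score"] = df.significance.map(order) * np.where(
                df.direction == "negative", -1, 1)
            grid = df.pivot_table(index="predictor", columns=["trait", "acclim_temp_C"],
                                  values="score", aggfunc="mean")
            fig, ax = plt.subplots(figsize=(1 + 0.5 * grid.shape[1],
                                            1 + 0.3 * grid.shape[0]))
            im = ax.imshow(grid.to_numpy(float), cmap="RdBu_r", vmin=-2, vmax=2,
                           aspect="auto")
            ax.set_yticks(range(len(grid.index)), grid.index, fontsize=7)
            ax.set_xticks(range(grid.shape[1]),
                          [f"{t}@{a:g}" for t, a in grid.columns],
                          rotation=90, fontsize=7)
            fig.colorbar(im, label="signed significance")
            fig.tight_layout()
            fig.savefig(out / "association_grid.png", dpi=120)
            plt.close(fig)
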