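"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the structure of a six-population, three-acclimation
(11/16/20 deg C) common-garden rearing study of juvenile fall-run Chinook
Salmon: biweekly growth sampling (30 fish per treatment per date), critical
thermal maximum trials at a 0.33 deg C/min ramp (18-25 fish per treatment,
~6% non-recovery), and swim-tunnel intermittent-flow respirometry
(32-46 fish per treatment spread over acute test temperatures 8-26 deg C).
Default trait magnitudes are seeded from the treatment-level summaries the
study published (growth 0.06-0.27 g/day, CT_max 27.8-30.1 deg C, RMR around
2.2-2.7 mg O2 kg^-1 min^-1 with exponential temperature dependence, aerobic
scope domes peaking 7-12 mg O2 kg^-1 min^-1 at 17.5-23.5 deg C); they are an
emulation of those magnitudes, not data.

Every generator is deterministic given its seed, and emitted tables satisfy
the input schemas of the downstream modules unchanged.  ``SyntheticTruth``
records the generating parameters so recovery tests can compare estimates
against truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .respirometry import MeasurePeriod, O2Trace, fulton_k

__all__ = [
    "CohortConfig", "SyntheticTruth", "default_truth", "generate_cohort",
    "generate_growth_data", "generate_ctmax_trials", "generate_o2_trace",
    "generate_trait_table", "generate_env_table", "inject_env_effect",
    "PAPER_POPULATIONS", "ENV_PREDICTORS", "CTMAX_RAMP_C_PER_MIN",
]

#: Printed population metadata (hatchery latitude, elevation m, migration
#: distance km) for the six study populations; migration slope is
#: elevation / distance (m/km).
PAPER_POPULATIONS = {
    "Coleman": {"latitude": 40.398, "elevation_m": 123.0, "mig_d_km": 441.0},
    "Elk River": {"latitude": 42.740, "elevation_m": 35.0, "mig_d_km": 22.0},
    "Feather River": {"latitude": 39.519, "elevation_m": 41.0, "mig_d_km": 233.0},
    "Priest Rapids": {"latitude": 46.630, "elevation_m": 125.0, "mig_d_km": 631.0},
    "Trask River": {"latitude": 45.433, "elevation_m": 17.0, "mig_d_km": 28.0},
    "Trinity River": {"latitude": 40.727, "elevation_m": 562.0, "mig_d_km": 250.0},
}

ENV_PREDICTORS = ("Latitude", "Mig.D", "Mig.S",
                  "CAMax", "CAMin", "CARange", "CRMax", "CRCMax", "CRAve",
                  "HAMax", "HAMin", "HARange", "HRMax", "HRCMax", "HRAve")

CTMAX_RAMP_C_PER_MIN = 0.33
CTMAX_HOLD_MIN = 30.0
CTMAX_SAMPLE_EVERY_MIN = 5.0

ACCLIM_TEMPS = (11.0, 16.0, 20.0)
TEST_TEMP_MENU = (8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 22.0, 24.0, 25.0, 26.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs; defaults are the emulated study's sizes."""

    populations: tuple[str, ...] = tuple(PAPER_POPULATIONS)
    acclim_temps: tuple[float, ...] = ACCLIM_TEMPS
    tanks_per_treatment: int = 2
    growth_n_per_date: int = 30          # fish measured per treatment per date
    growth_horizon_days: int = 42        # biweekly dates: 0, 14, 28, 42
    ctmax_n_range: tuple[int, int] = (18, 25)
    resp_n_range: tuple[int, int] = (32, 46)
    test_temps: tuple[float, ...] = TEST_TEMP_MENU
    start_mass_g: float = 7.9            # cohort at first growth measurement
    start_mass_sd_g: float = 2.0
    trial_mass_g: float = 23.5           # fish size at CT_max/respirometry
    trial_mass_sd_g: float = 4.0
    condition_factor: float = 1.15
    condition_factor_sd: float = 0.07
    nonrecovery_rate: float = 0.06

    def __post_init__(self):
        if not set(self.test_temps) <= {8., 10., 12., 14., 16., 18., 20., 22., 24., 25., 26.}:
            raise ValueError("test_temps outside the supported menu")
        if self.growth_n_per_date <= 0 or self.tanks_per_treatment <= 0:
            raise ValueError("counts must be positive")

    @property
    def treatments(self) -> list[tuple[str, float]]:
        return [(p, a) for p in self.populations for a in self.acclim_temps]


@dataclass
class SyntheticTruth:
    """Generating parameters per treatment cell, with observation noise.

    Keys of the per-cell dicts are (population, acclim_temp_C) tuples.
    RMR follows log RMR = log(rmr_ref) + rmr_b * (T - 16); MMR follows
    mmr_0 + mmr_b * log2(T); AS follows as_max + as_curv * (T - topt)^2
    with as_curv < 0 unless a monotone cell is explicitly requested.
    """

    growth_slope: dict = field(default_factory=dict)      # g/day
    growth_intercept: dict = field(default_factory=dict)  # g at day 0
    growth_noise_sd: float = 2.5                          # g
    ctmax_mean: dict = field(default_factory=dict)        # deg C
    ctmax_sd: dict = field(default_factory=dict)          # deg C
    rmr_ref: dict = field(default_factory=dict)           # mg O2/kg/min at 16 C
    rmr_b: float = 0.055                                  # per deg C (Q10 ~ 1.7)
    rmr_noise_sd: float = 0.08                            # on log scale
    mmr_0: dict = field(default_factory=dict)
    mmr_b: float = 3.2                                    # per doubling of T
    mmr_noise_sd: float = 0.6                             # mg O2/kg/min
    as_max: dict = field(default_factory=dict)            # mg O2/kg/min
    as_topt: dict = field(default_factory=dict)           # deg C
    as_curv: dict = field(default_factory=dict)           # < 0
    as_noise_sd: float = 0.55                             # mg O2/kg/min
    sat_noise_sd_pct: float = 0.1                         # respirometry sensor
    seed: int = 0

    def __post_init__(self):
        for cell, a in self.as_curv.items():
            if a >= 0:
                raise ValueError(f"AS curvature must be negative for {cell} "
                                 "(request monotone cells explicitly)")
        for name in ("growth_noise_sd", "rmr_noise_sd", "mmr_noise_sd",
                     "as_noise_sd", "sat_noise_sd_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rmr_at(self, cell: tuple[str, float], temp_C: float) -> float:
        return float(self.rmr_ref[cell] * np.exp(self.rmr_b * (temp_C - 16.0)))

    def mmr_at(self, cell: tuple[str, float], temp_C: float) -> float:
        return float(self.mmr_0[cell] + self.mmr_b * np.log2(temp_C))

    def as_at(self, cell: tuple[str, float], temp_C: float) -> float:
        return float(self.as_max[cell]
                     + self.as_curv[cell] * (temp_C - self.as_topt[cell]) ** 2)


# per-acclimation baselines emulating the published treatment summaries
_GROWTH_BASE = {11.0: 0.15, 16.0: 0.20, 20.0: 0.21}
_CTMAX_BASE = {11.0: 28.0, 16.0: 28.9, 20.0: 29.6}
_CTMAX_SD = {11.0: 0.40, 16.0: 0.65, 20.0: 0.80}
_RMR_REF_BASE = {11.0: 2.65, 16.0: 2.45, 20.0: 2.35}
_AS_TOPT_BASE = {11.0: 18.6, 16.0: 19.6, 20.0: 21.8}
_AS_MAX_BASE = {11.0: 9.0, 16.0: 9.0, 20.0: 8.1}


def default_truth(config: CohortConfig = CohortConfig(), seed: int = 0) -> SyntheticTruth:
    """Truth emulating the published magnitudes, with small reproducible
    population offsets so cells differ."""
    rng = np.random.default_rng(seed)
    pops = config.populations
    pop_off = {p: o for p, o in zip(pops, rng.normal(0.0, 1.0, len(pops)))}
    truth = SyntheticTruth(seed=seed)
    for p, a in config.treatments:
        o = pop_off[p]
        cell = (p, a)
        truth.growth_slope[cell] = round(max(0.04, _GROWTH_BASE[a] + 0.03 * o), 3)
        # treatments began at slightly different cohort masses (6-9 g range)
        truth.growth_intercept[cell] = round(
            config.start_mass_g + 0.4 * o + 0.05 * (a - 16.0), 2)
        truth.ctmax_mean[cell] = round(_CTMAX_BASE[a] + 0.25 * o, 2)
        truth.ctmax_sd[cell] = _CTMAX_SD[a]
        truth.rmr_ref[cell] = round(max(1.8, _RMR_REF_BASE[a] + 0.12 * o), 3)
        truth.as_topt[cell] = round(_AS_TOPT_BASE[a] + 0.6 * o, 2)
        truth.as_max[cell] = round(max(6.0, _AS_MAX_BASE[a] + 0.8 * o), 2)
        truth.as_curv[cell] = -0.045
        # MMR anchored so MMR ~ RMR + AS near the cell's optimum
        topt = truth.as_topt[cell]
        mmr_at_topt = truth.rmr_at(cell, topt) + truth.as_max[cell]
        truth.mmr_0[cell] = round(mmr_at_topt - truth.mmr_b * np.log2(topt), 3)
    return truth


def _length_from_mass(mass_g: float, config: CohortConfig,
                      rng: np.random.Generator) -> float:
    """Fork length implied by a per-fish condition factor drawn around the
    cohort mean (K is never exactly constant across real fish)."""
    k = max(0.8, rng.normal(config.condition_factor, config.condition_factor_sd))
    return (100.0 * mass_g / k) ** (1.0 / 3.0)


def _spawn(seed: int, *keys) -> np.random.Generator:
    """Independent stream per (seed, keys) so generators are reproducible
    and order-independent."""
    h = zlib.crc32(repr(keys).encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


# ---------------------------------------------------------------------------
# cohort and growth

def generate_cohort(config: CohortConfig = CohortConfig(),
                    truth: SyntheticTruth | None = None,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fish registry (trial-sized fish) and per-treatment table."""
    truth = truth or default_truth(config, seed)
    fish_rows, treat_rows = [], []
    for p, a in config.treatments:
        rng = _spawn(seed, "cohort", p, a)
        n_ct = int(rng.integers(*config.ctmax_n_range, endpoint=True))
        n_resp = int(rng.integers(*config.resp_n_range, endpoint=True))
        treat_rows.append({"population": p, "acclim_temp_C": a,
                           "n_ctmax": n_ct, "n_resp": n_resp,
                           "tanks": config.tanks_per_treatment})
        for i in range(n_ct + n_resp):
            mass = max(5.0, rng.normal(config.trial_mass_g, config.trial_mass_sd_g))
            length = _length_from_mass(mass, config, rng)
            fish_rows.append({
                "fish_id": f"{p[:2].upper()}{int(a)}-{i:03d}",
                "population": p, "acclim_temp_C": a,
                "tank": f"{p[:2].upper()}{int(a)}-T{i % config.tanks_per_treatment + 1}",
                "assay": "ctmax" if i < n_ct else "respirometry",
                "mass_g": round(mass, 2), "fork_length_cm": round(length, 2),
                "fulton_k": round(fulton_k(mass, length), 4),
                "age_days": int(rng.integers(150, 260)),
            })
    return pd.DataFrame(fish_rows), pd.DataFrame(treat_rows)


def generate_growth_data(truth: SyntheticTruth, config: CohortConfig = CohortConfig(),
                         seed: int = 0) -> pd.DataFrame:
    """Biweekly repeated cross-sectional growth table.

    Fish are not individually marked, so each date draws a fresh arbitrary
    sample of ``growth_n_per_date`` fish per treatment; mass follows the
    treatment-level line intercept + slope*days plus Gaussian noise.
    """
    dates = list(range(0, config.growth_horizon_days + 1, 14))
    if len(dates) < 2:
        raise ValueError("growth horizon must cover at least two biweekly dates")
    rows = []
    for p, a in config.treatments:
        cell = (p, a)
        rng = _spawn(seed, "growth", p, a)
        b0 = truth.growth_intercept[cell]
        b1 = truth.growth_slope[cell]
        for d in dates:
            mu = b0 + b1 * d
            masses = mu + rng.normal(0.0, truth.growth_noise_sd, config.growth_n_per_date)
            masses = np.maximum(masses, 0.5)
            for j, m in enumerate(masses):
                rows.append({"population": p, "acclim_temp_C": a,
                             "tank": f"{p[:2].upper()}{int(a)}-T{j % config.tanks_per_treatment + 1}",
                             "days": d, "mass_g": round(float(m), 2),
                             "fork_length_cm": round(float((100 * max(m, 0.5) /
                                                            config.condition_factor) ** (1 / 3)), 2),
                             "start_mass_g": b0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CT_max

def generate_ctmax_trials(truth: SyntheticTruth, config: CohortConfig = CohortConfig(),
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CT_max trial table plus the per-trial ramp temperature series.

    Each trial holds the bath at the fish's acclimation temperature for 30
    minutes, then ramps at 0.33 deg C/min with the bath temperature logged
    every 5 minutes; the endpoint is loss of equilibrium (LOE) at a
    temperature drawn from the cell's Normal truth.  About 6% of fish fail
    to recover within 24 h and carry ``recovered=False`` (excluded from
    analysis downstream).
    """
    trial_rows, series_rows = [], []
    for p, a in config.treatments:
        cell = (p, a)
        rng = _spawn(seed, "ctmax", p, a)
        n = int(rng.integers(*config.ctmax_n_range, endpoint=True))
        for i in range(n):
            fid = f"CT-{p[:2].upper()}{int(a)}-{i:03d}"
            loe = float(rng.normal(truth.ctmax_mean[cell], truth.ctmax_sd[cell]))
            mass = max(5.0, rng.normal(config.trial_mass_g, config.trial_mass_sd_g))
            length = _length_from_mass(mass, config, rng)
            recovered = bool(rng.uniform() > config.nonrecovery_rate)
            ramp_minutes = max(0.0, (loe - a) / CTMAX_RAMP_C_PER_MIN)
            t = 0.0
            while t <= CTMAX_HOLD_MIN + ramp_minutes:
                in_ramp = t > CTMAX_HOLD_MIN
                temp = a + (CTMAX_RAMP_C_PER_MIN * (t - CTMAX_HOLD_MIN) if in_ramp else 0.0)
                series_rows.append({"fish_id": fid, "time_min": t,
                                    "temp_C": round(temp, 3),
                                    "phase": "ramp" if in_ramp else "hold"})
                t += CTMAX_SAMPLE_EVERY_MIN
            trial_rows.append({"fish_id": fid, "population": p, "acclim_temp_C": a,
                               "chamber": f"B{i % 6 + 1}", "mass_g": round(mass, 2),
                               "fork_length_cm": round(length, 2),
                               "age_days": int(rng.integers(150, 260)),
                               "ctmax_C": round(loe, 2), "recovered": recovered})
    return pd.DataFrame(trial_rows), pd.DataFrame(series_rows)


# ---------------------------------------------------------------------------
# respirometry traces

def generate_o2_trace(truth: SyntheticTruth, fish: dict, test_temp_C: float,
                      seed: int = 0, n_routine_periods: int = 5,
                      routine_period_s: float = 900.0, flush_s: float = 240.0,
                      swim_period_s: float = 960.0, n_swim_steps: int = 3,
                      saturation_floor_pct: float = 80.0,
                      noise_sd_pct: float | None = None,
                      activity_flag_period: int | None = None,
                      tunnel_volume_L: float = 5.0,
                      alpha_O2: float = 0.0118,
                      barometric_pressure_mmHg: float = 760.0) -> O2Trace:
    """Inverse-model a saturation trace encoding the cell's RMR and MMR.

    Sealed routine periods deplete saturation at the rate implied by the
    target RMR through the concentration and rate equations run backwards;
    flush periods restore full saturation; swim steps at increasing tunnel
    velocity deplete at rates ramping up to the target MMR, so the
    steepest >= 5 min window encodes MMR.  If a requested rate would breach
    the saturation floor the sealed period is shortened to stop just above
    it.  Sensor noise is Gaussian on saturation; ``noise_sd_pct=0`` gives
    the exact inverse model (round-trip recovery to numerical precision).

    ``alpha_O2`` defaults to 0.0118 mg O2 L^-1 mmHg^-1 of total barometric
    pressure, i.e. ~9 mg O2 L^-1 at full saturation and one atmosphere — a
    temperature-typical freshwater value; with the default 0.1% sensor
    noise this yields per-period regression r^2 near 0.98, matching the
    linearity the emulated study reports.
    """
    cell = (fish["population"], fish["acclim_temp_C"])
    rng = _spawn(seed, "trace", fish["fish_id"], test_temp_C)
    if noise_sd_pct is None:
        noise_sd_pct = truth.sat_noise_sd_pct
    mass_kg = fish["mass_g"] / 1000.0
    rmr = truth.rmr_at(cell, test_temp_C)
    mmr = rmr + max(0.5, truth.as_at(cell, test_temp_C))

    def sat_slope(mo2: float) -> float:
        # %/s implied by MO2 (mg/kg/min) through the two rate equations
        conc_slope = mo2 * mass_kg / (tunnel_volume_L * 60.0)  # mg/L/s
        return -conc_slope / (alpha_O2 * barometric_pressure_mmHg / 100.0)

    times, sats, phases, flags = [], [], [], []
    t = 0.0

    def emit_sealed(duration: float, mo2: float, context: str, velocity: float,
                    flagged: bool) -> None:
        nonlocal t
        slope = sat_slope(mo2)
        max_drop = 100.0 - saturation_floor_pct - 1.0   # keep 1% headroom
        if abs(slope) * duration > max_drop:
            duration = max(60.0, max_drop / abs(slope))
        n = int(duration)
        tt = t + np.arange(n)
        sat = 100.0 + slope * (tt - t)
        times.append(tt)
        sats.append(sat)
        phases.append(MeasurePeriod(float(tt[0]), float(tt[-1]), "sealed", context, velocity))
        flags.append(flagged)
        t = float(tt[-1]) + 1.0

    def emit_flush(duration: float) -> None:
        nonlocal t
        n = int(duration)
        tt = t + np.arange(n)
        times.append(tt)
        sats.append(np.full(n, 100.0))
        phases.append(MeasurePeriod(float(tt[0]), float(tt[-1]), "flush", "routine", 0.0))
        flags.append(False)
        t = float(tt[-1]) + 1.0

    # routine overnight cycle: mild MO2 variation around RMR; three lowest
    # periods average back to RMR exactly
    bumps = [0.0, 0.0, 0.0] + [0.35 * rmr * (k + 1) / max(1, n_routine_periods - 3)
                               for k in range(n_routine_periods - 3)]
    rng.shuffle(bumps)
    for k in range(n_routine_periods):
        flagged = activity_flag_period is not None and k == activity_flag_period
        emit_sealed(routine_period_s, rmr + bumps[k], "routine", 0.0, flagged)
        emit_flush(flush_s)

    # incremental swim steps ending at MMR
    velocities = [30.0 * 1.1 ** k for k in range(n_swim_steps)]
    for k, v in enumerate(velocities):
        frac = 0.75 + 0.25 * (k + 1) / n_swim_steps
        emit_sealed(swim_period_s, frac * mmr if k < n_swim_steps - 1 else mmr,
                    "swim", v, False)
        emit_flush(flush_s)

    tt = np.concatenate(times)
    ss = np.concatenate(sats)
    if noise_sd_pct > 0:
        ss = ss + rng.normal(0.0, noise_sd_pct, ss.size)
    ss = np.clip(ss, 0.0, 110.0)
    return O2Trace(
        fish_id=str(fish["fish_id"]), test_temp_C=float(test_temp_C),
        acclim_temp_C=float(fish["acclim_temp_C"]), tunnel_id=fish.get("tunnel_id", "S1"),
        tunnel_volume_L=tunnel_volume_L, fish_mass_kg=mass_kg,
        barometric_pressure_mmHg=barometric_pressure_mmHg, alpha_O2=alpha_O2,
        samples=np.column_stack([tt, ss]), phases=phases, activity_flags=flags,
        survived=bool(fish.get("survived", True)),
    )


def generate_trait_table(trait: str, truth: SyntheticTruth,
                         config: CohortConfig = CohortConfig(),
                         seed: int = 0) -> pd.DataFrame:
    """Per-observation table for one trait drawn from its generating family.

    This is the fast path feeding the trait models directly (each metabolic
    row is the summary a respirometry trial would yield); the slow path
    generates full oxygen traces with :func:`generate_o2_trace` and runs
    them through the respirometry module.
    """
    if trait == "growth":
        return generate_growth_data(truth, config, seed)
    if trait == "ctmax":
        trials, _ = generate_ctmax_trials(truth, config, seed)
        return trials[trials.recovered].drop(columns=["recovered"])
    if trait not in ("rmr", "mmr", "as"):
        raise ValueError(f"unknown trait {trait!r}")
    rows = []
    for p, a in config.treatments:
        cell = (p, a)
        rng = _spawn(seed, trait, p, a)
        n = int(rng.integers(*config.resp_n_range, endpoint=True))
        temps = np.asarray(config.test_temps)
        assigned = temps[np.arange(n) % temps.size]
        rng.shuffle(assigned)
        for i, T in enumerate(assigned):
            mass = max(5.0, rng.normal(config.trial_mass_g, config.trial_mass_sd_g))
            length = _length_from_mass(mass, config, rng)
            row = {"fish_id": f"R-{p[:2].upper()}{int(a)}-{i:03d}", "population": p,
                   "acclim_temp_C": a, "test_temp_C": float(T),
                   "tunnel_id": f"S{i % 4 + 1}", "mass_g": round(mass, 2),
                   "fork_length_cm": round(length, 2),
                   "fulton_k": round(fulton_k(mass, length), 4),
                   "age_days": int(rng.integers(150, 260))}
            if trait == "rmr":
                row["rmr"] = float(np.exp(np.log(truth.rmr_at(cell, T))
                                          + rng.normal(0, truth.rmr_noise_sd)))
            elif trait == "mmr":
                row["mmr"] = float(truth.mmr_at(cell, T)
                                   + rng.normal(0, truth.mmr_noise_sd))
            else:
                row["aerobic_scope"] = float(truth.as_at(cell, T)
                                             + rng.normal(0, truth.as_noise_sd))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# environmental predictors

def generate_env_table(mode: str = "paper", seed: int = 0, n_populations: int = 6,
                       target_corr: float = 0.8) -> pd.DataFrame:
    """The 15-column environmental predictor table, one row per population.

    mode="paper": latitude, migration distance and slope are the published
    values for the six study populations; the twelve stream-temperature
    metrics are synthetic stand-ins (the study's values live in an
    unpublished supplement) constructed deterministically so that current
    metrics exceed historical ones, rearing-season averages sit near the
    published aggregate anchors (CRAve ~9.2, HRAve ~7.5 deg C across
    populations) and same-kind current/historical metrics are strongly
    correlated.

    mode="random": every column is drawn from a correlated Gaussian with
    pairwise correlation ``target_corr``, for screen-calibration work.
    """
    if mode == "paper":
        rng = np.random.default_rng(seed)
        rows = []
        for p, meta in PAPER_POPULATIONS.items():
            # latitude explains part of a population's thermal regime; local
            # hydrology (the per-metric jitters) decorrelates the rest, so
            # same-kind metrics stay strongly but not perfectly correlated
            warmth = (46.63 - meta["latitude"]) / 7.1 + rng.normal(0, 0.25)
            camax = 16.5 + 5.5 * warmth + rng.normal(0, 0.8)
            camin = 3.5 + 3.0 * warmth + rng.normal(0, 0.5)
            crave = 7.9 + 2.6 * warmth + rng.normal(0, 0.5)
            crmax = crave + 3.0 + warmth + rng.normal(0, 0.4)
            crcmax = crave + 1.6 + 0.8 * warmth + rng.normal(0, 0.4)
            hshift = 1.3 + 0.5 * warmth + rng.normal(0, 0.2)  # historical cooler
            rows.append({
                "population": p, "Latitude": meta["latitude"],
                "Mig.D": meta["mig_d_km"],
                "Mig.S": round(meta["elevation_m"] / meta["mig_d_km"], 3),
                "CAMax": round(camax, 2), "CAMin": round(camin, 2),
                "CARange": round(camax - camin, 2),
                "CRMax": round(crmax, 2), "CRCMax": round(crcmax, 2),
                "CRAve": round(crave, 2),
                "HAMax": round(camax - hshift, 2), "HAMin": round(camin - hshift / 2, 2),
                "HARange": round(camax - camin - hshift / 2, 2),
                "HRMax": round(crmax - hshift, 2), "HRCMax": round(crcmax - hshift, 2),
                "HRAve": round(crave - hshift, 2),
            })
        return pd.DataFrame(rows)
    if mode == "random":
        rng = np.random.default_rng(seed)
        k = len(ENV_PREDICTORS)
        cov = np.full((k, k), target_corr)
        np.fill_diagonal(cov, 1.0)
        vals = rng.multivariate_normal(np.zeros(k), cov, size=n_populations,
                                       method="cholesky")
        df = pd.DataFrame(vals, columns=list(ENV_PREDICTORS))
        df.insert(0, "population", [f"Pop{i+1}" for i in range(n_populations)])
        return df
    raise ValueError(f"unknown mode {mode!r}")


def inject_env_effect(truth: SyntheticTruth, table: pd.DataFrame,
                      coefficients: dict[tuple[str, str], float],
                      config: CohortConfig = CohortConfig()) -> SyntheticTruth:
    """Shift per-population trait parameters linearly in a z-scored predictor.

    ``coefficients`` maps (trait, predictor) -> effect size per predictor SD:
    growth shifts the slope (g/day), ctmax the cell mean (deg C), rmr the
    log reference rate, mmr the intercept, "as" the AS maximum.  Zero
    coefficients leave truth untouched.
    """
    new = replace(truth,
                  growth_slope=dict(truth.growth_slope),
                  growth_intercept=dict(truth.growth_intercept),
                  ctmax_mean=dict(truth.ctmax_mean), ctmax_sd=dict(truth.ctmax_sd),
                  rmr_ref=dict(truth.rmr_ref), mmr_0=dict(truth.mmr_0),
                  as_max=dict(truth.as_max), as_topt=dict(truth.as_topt),
                  as_curv=dict(truth.as_curv))
    for (trait, predictor), coef in coefficients.items():
        if predictor not in table.columns:
            raise ValueError(f"unknown predictor {predictor!r}")
        if coef == 0:
            continue
        x = table[predictor].to_numpy(float)
        z = (x - x.mean()) / x.std(ddof=1)
        zmap = dict(zip(table["population"], z))
        for cell in list(new.ctmax_mean):
            p, _a = cell
            if p not in zmap:
                continue
            if trait == "growth":
                new.growth_slope[cell] = max(0.005, new.growth_slope[cell] + coef * zmap[p])
            elif trait == "ctmax":
                new.ctmax_mean[cell] = new.ctmax_mean[cell] + coef * zmap[p]
            elif trait == "rmr":
                new.rmr_ref[cell] = float(new.rmr_ref[cell] * np.exp(coef * zmap[p]))
            elif trait == "mmr":
                new.mmr_0[cell] = new.mmr_0[cell] + coef * zmap[p]
            elif trait == "as":
                new.as_max[cell] = max(1.0, new.as_max[cell] + coef * zmap[p])
            else:
                raise ValueError(f"unknown trait {trait!r}")
    return new
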