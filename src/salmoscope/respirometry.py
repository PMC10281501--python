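"""Intermittent-flow respirometry: oxygen traces to metabolic rates.

A swim-tunnel respirometer alternates *flush* phases (fresh aerated water)
with *sealed* phases in which the fish depletes oxygen.  Dissolved-oxygen
saturation (%) is logged every second; within each sealed period the
saturation is converted to concentration,

    [O2] (mg L^-1) = (%O2Sat / 100) * alpha(O2) * BP,

where ``alpha(O2)`` is the temperature-corrected oxygen solubility
(mg O2 L^-1 mmHg^-1) and ``BP`` the barometric pressure (mmHg).  The slope
``R`` (mg O2 L^-1 s^-1) of an ordinary least-squares regression of
concentration on time is converted to a mass-specific oxygen-consumption
rate,

    MO2 (mg O2 kg^-1 min^-1) = |R| * V / M * 60,

with tunnel volume ``V`` (L) and fish mass ``M`` (kg).  No allometric
scaling exponent is applied; the fish in the emulated study were of similar
size.

Routine metabolic rate (RMR) is the mean of the three lowest per-period MO2
values measured overnight at rest; maximum metabolic rate (MMR) is the
steepest MO2 sustained over any window of at least five minutes while the
fish swims against an incremental current; aerobic scope (AS) is their
difference.  Quality control drops periods whose regression r^2 falls below
a linearity threshold, fish whose saturation floor (80%) was breached,
fish active during their lowest RMR periods, and fish that died during the
trial or recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurePeriod",
    "O2Trace",
    "SlopeEstimate",
    "MetabolicResult",
    "o2_concentration",
    "fit_period_slope",
    "mo2_from_slope",
    "extract_rmr",
    "extract_mmr",
    "aerobic_scope",
    "fulton_k",
    "qc_filter",
    "process_trace",
    "read_trace_tables",
    "results_to_frame",
    "SATURATION_FLOOR_PCT",
    "R2_THRESHOLD",
    "MMR_MIN_WINDOW_S",
]

#: QC defaults; all overridable at call sites.
SATURATION_FLOOR_PCT = 80.0
R2_THRESHOLD = 0.90
MMR_MIN_WINDOW_S = 300.0


class InvalidPhysicsError(ValueError):
    """A physically impossible parameter (non-positive solubility, pressure...)."""


class InsufficientDataError(ValueError):
    """Too few samples inside a measurement period to fit a slope."""


@dataclass(frozen=True)
class MeasurePeriod:
    """One phase of the intermittent-flow cycle.

    ``kind`` is ``"sealed"`` (respirometer closed, fish depletes oxygen) or
    ``"flush"`` (fresh water restores saturation); ``context`` separates the
    overnight routine protocol from the incremental swim test.
    ``velocity_cm_s`` is the tunnel water velocity (0 while routine).
    """

    start_s: float
    end_s: float
    kind: str = "sealed"
    context: str = "routine"
    velocity_cm_s: float = 0.0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"period end {self.end_s} not after start {self.start_s}")
        if self.kind not in ("sealed", "flush"):
            raise ValueError(f"unknown period kind {self.kind!r}")
        if self.context not in ("routine", "swim"):
            raise ValueError(f"unknown period context {self.context!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class O2Trace:
    """A fish's oxygen-saturation time series plus trial metadata.

    ``samples`` is an (n, 2) array of (time_s, saturation_pct), strictly
    increasing in time; ``phases`` are non-overlapping MeasurePeriods within
    the sampled range.  ``activity_flags`` marks sealed periods during which
    video review showed the fish swimming (index-aligned with ``phases``).
    """

    fish_id: str
    test_temp_C: float
    acclim_temp_C: float
    tunnel_id: str
    tunnel_volume_L: float
    fish_mass_kg: float
    barometric_pressure_mmHg: float
    alpha_O2: float
    samples: np.ndarray
    phases: list[MeasurePeriod] = field(default_factory=list)
    activity_flags: list[bool] = field(default_factory=list)
    survived: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array of (time_s, saturation_pct)")
        t = self.samples[:, 0]
        sat = self.samples[:, 1]
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any((sat < 0) | (sat > 110)):
            raise ValueError("saturation_pct outside [0, 110]")
        if self.tunnel_volume_L <= 0:
            raise ValueError("tunnel_volume_L must be positive")
        if self.fish_mass_kg <= 0:
            raise ValueError("fish_mass_kg must be positive")
        if not self.activity_flags:
            self.activity_flags = [False] * len(self.phases)
        if len(self.activity_flags) != len(self.phases):
            raise ValueError("activity_flags must align with phases")
        last_end = None
        for p in sorted(self.phases, key=lambda p: p.start_s):
            if last_end is not None and p.start_s < last_end:
                raise ValueError("phases overlap")
            last_end = p.end_s
            if p.start_s < t[0] or p.end_s > t[-1]:
                raise ValueError("phase outside sampled time range")

    def sealed_periods(self, context: str | None = None) -> list[tuple[int, MeasurePeriod]]:
        out = []
        for i, p in enumerate(self.phases):
            if p.kind == "sealed" and (context is None or p.context == context):
                out.append((i, p))
        return out


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS depletion slope for one sealed period.

    ``slope_mgO2_L_s`` is signed: oxygen depletion by the fish is negative;
    a positive slope indicates an anomalous oxygen gain and is kept signed
    so it can be flagged rather than silently folded into a magnitude.
    """

    period: MeasurePeriod
    slope_mgO2_L_s: float
    r_squared: float
    min_saturation_pct: float


@dataclass
class MetabolicResult:
    """RMR, MMR and AS for one fish at one acute test temperature."""

    fish_id: str
    test_temp_C: float
    acclim_temp_C: float = np.nan
    rmr: float = np.nan
    mmr: float = np.nan
    aerobic_scope: float = np.nan
    n_periods_used: int = 0
    qc_flags: set[str] = field(default_factory=set)
    min_saturation_pct: float = np.nan


def o2_concentration(saturation_pct, alpha_O2: float, bp_mmHg: float):
    """Convert % air saturation to oxygen concentration (mg O2 L^-1).

    Linear in each argument: (sat/100) * alpha * BP.
    """
    if alpha_O2 <= 0 or bp_mmHg <= 0:
        raise InvalidPhysicsError(
            f"alpha_O2 and barometric pressure must be positive (got {alpha_O2}, {bp_mmHg})"
        )
    return (np.asarray(saturation_pct, dtype=float) / 100.0) * alpha_O2 * bp_mmHg


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Return (slope, intercept, r_squared); r^2 of a flat response is 0."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    yc = y - y.mean()
    stt = float(tc @ tc)
    syy = float(yc @ yc)
    if stt == 0.0:
        raise InsufficientDataError("degenerate time axis")
    slope = float(tc @ yc) / stt
    intercept = float(y.mean() - slope * t.mean())
    if syy == 0.0:
        # zero-variance response: define r^2 = 0 so it fails linearity QC
        return slope, intercept, 0.0
    r2 = (float(tc @ yc) ** 2) / (stt * syy)
    return slope, intercept, float(r2)


def fit_period_slope(trace: O2Trace, period: MeasurePeriod, min_samples: int = 30) -> SlopeEstimate:
    """OLS slope of oxygen concentration on time within a sealed period."""
    if period.kind != "sealed":
        raise ValueError("slopes are fit only on sealed periods")
    t = trace.samples[:, 0]
    mask = (t >= period.start_s) & (t <= period.end_s)
    if int(mask.sum()) < min_samples:
        raise InsufficientDataError(
            f"{int(mask.sum())} samples in period [{period.start_s}, {period.end_s}] "
            f"(need >= {min_samples})"
        )
    sat = trace.samples[mask, 1]
    conc = o2_concentration(sat, trace.alpha_O2, trace.barometric_pressure_mmHg)
    slope, _, r2 = _ols_slope(t[mask], conc)
    return SlopeEstimate(
        period=period,
        slope_mgO2_L_s=slope,
        r_squared=r2,
        min_saturation_pct=float(sat.min()),
    )


def mo2_from_slope(slope: SlopeEstimate | float, volume_L: float, mass_kg: float,
                   gain_tolerance: float = 1e-12) -> tuple[float, bool]:
    """Convert a depletion slope to MO2 (mg O2 kg^-1 min^-1).

    Returns ``(mo2, gain_flagged)``; a slope more positive than
    ``gain_tolerance`` (tunnel gaining oxygen while sealed) sets the flag but
    the magnitude is still converted.
    """
    r = slope.slope_mgO2_L_s if isinstance(slope, SlopeEstimate) else float(slope)
    if volume_L <= 0 or mass_kg <= 0:
        raise InvalidPhysicsError("volume and mass must be positive")
    gain = r > gain_tolerance
    return abs(r) * volume_L / mass_kg * 60.0, gain


def extract_rmr(mo2_values: Sequence[float], activity_flags: Sequence[bool] | None = None,
                period_starts: Sequence[float] | None = None) -> tuple[float, int]:
    """Mean of the three lowest retained MO2 values.

    Periods flagged for activity (fish swimming on video) are removed first.
    Ties among equal values are broken by earliest period start so the
    selection is deterministic.  Raises ``InsufficientDataError`` with fewer
    than three retained periods; callers translate that into an exclusion.
    """
    mo2 = np.asarray(mo2_values, float)
    if activity_flags is None:
        activity_flags = [False] * len(mo2)
    flags = np.asarray(activity_flags, bool)
    if len(flags) != len(mo2):
        raise ValueError("activity_flags must align with mo2_values")
    if period_starts is None:
        period_starts = np.arange(len(mo2), dtype=float)
    starts = np.asarray(period_starts, float)
    keep = ~flags
    mo2_kept, starts_kept = mo2[keep], starts[keep]
    if mo2_kept.size < 3:
        raise InsufficientDataError(
            f"only {mo2_kept.size} periods retained after activity exclusion (need 3)"
        )
    order = np.lexsort((starts_kept, mo2_kept))
    lowest3 = mo2_kept[order[:3]]
    return float(lowest3.mean()), 3


def extract_mmr(trace: O2Trace, min_window_s: float = MMR_MIN_WINDOW_S,
                r2_threshold: float = R2_THRESHOLD,
                step_s: float = 1.0) -> tuple[float, SlopeEstimate]:
    """Highest MO2 over any contiguous sub-window of >= ``min_window_s``
    within sealed swim periods.

    The window start slides in ``step_s`` increments (1 s default, the
    sampling resolution) and the slope is refit by OLS on each window; the
    steepest-depletion window wins.  Windows failing the r^2 linearity
    threshold are skipped.  Raises ``InsufficientDataError`` when no
    qualifying window exists.
    """
    best: tuple[float, SlopeEstimate] | None = None
    t_all = trace.samples[:, 0]
    for _, period in trace.sealed_periods(context="swim"):
        if period.duration_s < min_window_s:
            continue
        mask = (t_all >= period.start_s) & (t_all <= period.end_s)
        t = t_all[mask]
        if t.size < 30:
            continue
        start = period.start_s
        while start + min_window_s <= period.end_s + 1e-9:
            end = min(start + min_window_s, period.end_s)
            sub = MeasurePeriod(start, end, kind="sealed", context="swim",
                                velocity_cm_s=period.velocity_cm_s)
            try:
                est = fit_period_slope(trace, sub)
            except InsufficientDataError:
                break
            if est.r_squared >= r2_threshold:
                mo2, _ = mo2_from_slope(est, trace.tunnel_volume_L, trace.fish_mass_kg)
                if best is None or mo2 > best[0]:
                    best = (mo2, est)
            start += step_s
    if best is None:
        raise InsufficientDataError("no sealed swim window of sufficient length and linearity")
    return best


def aerobic_scope(rmr: float, mmr: float) -> tuple[float, bool]:
    """AS = MMR - RMR; a negative scope is returned with a warning flag,
    never clipped."""
    if not (np.isfinite(rmr) and np.isfinite(mmr)):
        raise ValueError("rmr and mmr must be finite")
    diff = mmr - rmr
    return diff, diff < 0


def fulton_k(mass_g: float, fork_length_cm: float):
    """Fulton's condition factor, K = 100 * mass / length^3 (g, cm)."""
    mass_g = np.asarray(mass_g, float)
    fork_length_cm = np.asarray(fork_length_cm, float)
    if np.any(mass_g <= 0) or np.any(fork_length_cm <= 0):
        raise ValueError("mass and fork length must be positive")
    out = 100.0 * mass_g / fork_length_cm**3
    return float(out) if out.ndim == 0 else out


def process_trace(trace: O2Trace, r2_threshold: float = R2_THRESHOLD,
                  saturation_floor_pct: float = SATURATION_FLOOR_PCT,
                  mmr_min_window_s: float = MMR_MIN_WINDOW_S,
                  mmr_step_s: float = 1.0) -> MetabolicResult:
    """Run the full per-fish chain: period slopes -> RMR, MMR, AS with QC flags.

    Flags set here (``low_r2``, ``saturation_floor``, ``activity_excluded``,
    ``mortality``, ``negative_scope``, ``oxygen_gain``) are consumed by
    :func:`qc_filter`, which decides retention.
    """
    res = MetabolicResult(fish_id=trace.fish_id, test_temp_C=trace.test_temp_C,
                          acclim_temp_C=trace.acclim_temp_C)
    if not trace.survived:
        res.qc_flags.add("mortality")

    mo2s, starts, flags, minsats = [], [], [], []
    for i, period in trace.sealed_periods(context="routine"):
        try:
            est = fit_period_slope(trace, period)
        except InsufficientDataError:
            continue
        if est.r_squared < r2_threshold:
            res.qc_flags.add("low_r2")
            continue
        mo2, gain = mo2_from_slope(est, trace.tunnel_volume_L, trace.fish_mass_kg)
        if gain:
            res.qc_flags.add("oxygen_gain")
            continue
        mo2s.append(mo2)
        starts.append(period.start_s)
        flags.append(trace.activity_flags[i])
        minsats.append(est.min_saturation_pct)

    try:
        rmr, n_used = extract_rmr(mo2s, flags, starts)
        res.rmr, res.n_periods_used = rmr, n_used
        # activity during any of the three lowest periods poisons the RMR
        order = np.lexsort((np.asarray(starts)[~np.asarray(flags, bool)],
                            np.asarray(mo2s)[~np.asarray(flags, bool)]))
        used_sats = np.asarray(minsats)[~np.asarray(flags, bool)][order[:3]]
        res.min_saturation_pct = float(used_sats.min()) if used_sats.size else np.nan
        if np.asarray(flags, bool).any():
            retained = np.asarray(mo2s)[~np.asarray(flags, bool)]
            flagged = np.asarray(mo2s)[np.asarray(flags, bool)]
            if flagged.size and retained.size and flagged.min() <= np.sort(retained)[:3].max():
                res.qc_flags.add("activity_excluded")
    except InsufficientDataError:
        res.qc_flags.add("activity_excluded" if any(flags) else "insufficient_periods")

    try:
        mmr, mmr_est = extract_mmr(trace, min_window_s=mmr_min_window_s,
                                   r2_threshold=r2_threshold, step_s=mmr_step_s)
        res.mmr = mmr
        if np.isfinite(res.min_saturation_pct):
            res.min_saturation_pct = min(res.min_saturation_pct, mmr_est.min_saturation_pct)
        else:
            res.min_saturation_pct = mmr_est.min_saturation_pct
    except InsufficientDataError:
        res.qc_flags.add("no_mmr_window")

    if np.isfinite(res.rmr) and np.isfinite(res.mmr):
        as_val, negative = aerobic_scope(res.rmr, res.mmr)
        res.aerobic_scope = as_val
        if negative:
            res.qc_flags.add("negative_scope")

    if np.isfinite(res.min_saturation_pct) and res.min_saturation_pct < saturation_floor_pct:
        res.qc_flags.add("saturation_floor")
    return res


_EXCLUDE_FLAGS = ("mortality", "activity_excluded", "saturation_floor")


def qc_filter(results: Iterable[MetabolicResult]) -> tuple[list[MetabolicResult], pd.DataFrame]:
    """Apply the trial-level exclusion rules.

    Drops fish that died during trial or recovery, fish active during their
    lowest RMR periods, and fish with any used sealed period whose minimum
    saturation fell below the floor.  Returns the retained list and an
    exclusion log (fish_id, reason) with one row per excluded fish.
    """
    retained, log_rows = [], []
    for r in results:
        reasons = [f for f in _EXCLUDE_FLAGS if f in r.qc_flags]
        if reasons:
            log_rows.append({"fish_id": r.fish_id, "test_temp_C": r.test_temp_C,
                             "reason": ";".join(sorted(reasons))})
        else:
            retained.append(r)
    log = pd.DataFrame(log_rows, columns=["fish_id", "test_temp_C", "reason"])
    return retained, log


# ---------------------------------------------------------------------------
# CSV I/O

def read_trace_tables(samples_csv, phases_csv, fish_csv) -> list[O2Trace]:
    """Assemble O2Trace objects from the three long-format CSVs.

    samples: fish_id, time_s, saturation_pct
    phases:  fish_id, start_s, end_s, kind, context, velocity_cm_s, activity_flag
    fish:    fish_id, test_temp_C, acclim_temp_C, tunnel_id, tunnel_volume_L,
             fish_mass_kg, barometric_pressure_mmHg, alpha_O2, survived
    """
    samples = pd.read_csv(samples_csv)
    phases = pd.read_csv(phases_csv)
    fish = pd.read_csv(fish_csv)
    for df, cols in ((samples, {"fish_id", "time_s", "saturation_pct"}),
                     (phases, {"fish_id", "start_s", "end_s", "kind", "context"}),
                     (fish, {"fish_id", "test_temp_C", "acclim_temp_C", "tunnel_id",
                             "tunnel_volume_L", "fish_mass_kg",
                             "barometric_pressure_mmHg", "alpha_O2"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
    traces = []
    for _, meta in fish.iterrows():
        fid = meta["fish_id"]
        s = samples[samples.fish_id == fid].sort_values("time_s")
        ph = phases[phases.fish_id == fid].sort_values("start_s")
        plist, aflags = [], []
        for _, row in ph.iterrows():
            plist.append(MeasurePeriod(row.start_s, row.end_s, row.kind, row.context,
                                       float(row.get("velocity_cm_s", 0.0))))
            aflags.append(bool(row.get("activity_flag", False)))
        traces.append(O2Trace(
            fish_id=str(fid), test_temp_C=float(meta.test_temp_C),
            acclim_temp_C=float(meta.acclim_temp_C), tunnel_id=str(meta.tunnel_id),
            tunnel_volume_L=float(meta.tunnel_volume_L),
            fish_mass_kg=float(meta.fish_mass_kg),
            barometric_pressure_mmHg=float(meta.barometric_pressure_mmHg),
            alpha_O2=float(meta.alpha_O2),
            samples=s[["time_s", "saturation_pct"]].to_numpy(),
            phases=plist, activity_flags=aflags,
            survived=bool(meta.get("survived", True)),
        ))
    return traces


def results_to_frame(results: Iterable[MetabolicResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({"fish_id": r.fish_id, "test_temp_C": r.test_temp_C,
                     "acclim_temp_C": r.acclim_temp_C, "rmr": r.rmr, "mmr": r.mmr,
                     "aerobic_scope": r.aerobic_scope,
                     "n_periods_used": r.n_periods_used,
                     "qc_flags": ";".join(sorted(r.qc_flags))})
    return pd.DataFrame(rows)
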