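# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the package's known
limitations. It is the design record; empirical claims here are limited to
what the test suite and `scripts/acceptance.py` compute.

## Respirometry signal processing

A sealed-phase oxygen-saturation record is converted to concentration,
`[O2] = (%sat/100)·α(O2)·BP`, and the OLS slope of concentration on time
(signed; depletion negative) becomes `MO2 = |R|·V/M·60` in
mg O2 kg⁻¹ min⁻¹. Slopes are stored signed so anomalous oxygen-gain periods
are detectable; a positive slope beyond tolerance sets a QC flag and the
magnitude is still converted. No allometric mass exponent is applied — the
emulated cohorts are deliberately size-matched, and mass-specific rates are
comparable without one.

Numerical/QC choices:

* **Linearity filter.** Visual linearity checks are replaced by a
  programmatic r² threshold, default 0.90 and configurable. The emulated
  study's regressions were highly linear (median r² ≈ 0.98), so 0.90 is
  permissive yet protective. The r² of a zero-variance response is defined
  as 0 so flat traces fail the filter deterministically rather than
  propagating NaN.
* **RMR** is the mean of the three lowest retained per-period rates; ties
  are broken by earliest period start so selection is deterministic. All
  retained sealed routine periods are eligible (no clock-time window —
  which overnight periods qualify is not otherwise specifiable). A fish
  with fewer than three retained periods is excluded, not imputed.
* **MMR** scans every contiguous sub-window of ≥ 300 s inside sealed swim
  periods, refitting the slope per window. The scan step defaults to the
  1 s sampling resolution — the conservative superset of any coarser
  reading of "a minimum of 5 min" — and is configurable (the pipeline demo
  uses 30 s; tests verify 1 s equals the exhaustive oracle).
* **Exclusions** (mortality, activity during the lowest RMR periods, any
  used period dipping below the 80% saturation floor) are logged one row
  per fish with reason codes; retained + excluded always equals input.
* **Units.** Rates are mg O2 kg⁻¹ min⁻¹ throughout (the rate equation's
  60 s min⁻¹ factor). Published summary tables of the emulated study label
  aerobic scope at the optimum "per hour" while printing values of
  per-minute magnitude; this package standardizes on per-minute and treats
  those printed values as per-minute.

## Trait models and sampler

All five traits use Gaussian linear models on standardized scales:
responses and continuous covariates are z-scored with the sample SD
(`[1,2,3] → [−1,0,1]`), time and age scaled to [0, 1]; scaling parameters
are stored so every report is back-transformed to natural units and the
transform round-trips exactly.

Families (fixed structure; population × acclimation cells always present):

| trait  | response            | acute-temperature form              | extra fixed terms |
|--------|---------------------|-------------------------------------|-------------------|
| growth | mass (g)            | per-treatment linear in scaled time | starting mass     |
| ctmax  | LOE temperature (°C)| —                                   | mass, age         |
| rmr    | log rate            | linear in T (exponential curve)     | tunnel, age       |
| mmr    | rate                | linear in log₂ T                    | tunnel, K, age    |
| as     | rate                | per-treatment quadratic in T        | K                 |

Growth rate is reported **only at treatment level** (fish are not
individually marked; each biweekly date is a fresh sample), as the posterior
of the per-cell mass change across the scaled time range divided by its
span in days.

**Priors** are weakly regularizing on the standardized scale: Normal(0, 1)
on all design coefficients, half-Normal(0, 1) on the residual SD and each
random-effect scale; both scales are configurable.

**Sampler.** The posterior is drawn by block Gibbs: (1) a conjugate joint
multivariate-normal draw of all fixed and random coefficients given the
variances; (2) univariate slice-sampling updates of log σ and each log τ;
(3) an interweaved non-centered update that re-draws each τ as a regression
coefficient on the normalized random effects — the standard remedy for the
funnel geometry that otherwise slows τ mixing with few grouping levels.
Defaults are 2 chains × 1000 retained draws after 500 warmup; split-chain
R-hat is computed for every parameter and a fit whose worst R-hat exceeds
1.01 raises rather than returning. A seed is mandatory everywhere.

**WAIC** uses the stored per-draw, per-observation conditional
log-likelihoods with log-sum-exp stabilization:
`lppd = Σᵢ log meanᵈ exp(llᵢᵈ)`, `p = Σᵢ varᵈ(llᵢᵈ)`,
`WAIC = −2(lppd − p)`. Stepwise selection is greedy forward addition
followed by one backward pass; every model tried is recorded in a ledger
table so the search path is auditable. A candidate whose fit fails
convergence is ineligible rather than fatal.

**Marginal means** evaluate the linear predictor per draw at reference
covariates — z-covariates at the grand mean (0), time/age at the
cell-specific mean, random effects at 0 — averaged with equal weight over
the levels of fixed nuisance factors (swim tunnel), then back-transformed.
Contrasts difference cell draws pairwise by draw index; the significance
rule is `p = max(Pr(q>0), Pr(q<0))` with inclusive thresholds: strong at
p ≥ 0.945, weak at p ≥ 0.85. Acclimation capacity is the (20 °C − 11 °C)
paired-draw difference per population.

## Thermal optimum

T_opt estimation follows the posterior-simulation recipe rather than
reading vertices off coefficients: for each of 500 posterior draws
(subsampled without replacement; seed required), the cell's AS curve is
predicted on a fixed 0.5 °C grid over 8–26 °C and a quadratic is refit;
for an exactly quadratic model the refit reproduces the draw's own vertex,
so the two formulations agree identically while the grid version remains
well-defined if the prediction ever carries non-quadratic terms.
Upward-opening refits are dropped and counted; a cell with more than half
non-concave draws fails estimation outright instead of averaging
meaningless vertices. A mean vertex outside 8–26 °C is flagged
`extrapolated` (a monotone-in-range curve still has a vertex — beyond the
tested range). ΔT_opt pairs draws by index when counts match and otherwise
combines SDs in quadrature; both modes exist because draw pairing across
acclimation groups is a reporting choice, not a model property.

## Environmental screen

Each of the 75 models (15 predictors × 5 traits) carries the z-scored
predictor, its interaction with acclimation temperature, the trait's
covariates, a random intercept for source population, and — metabolic
traits — a predictor × test-temperature interaction plus the acclimation
fixed effect. The reported estimand per cell is the posterior of the
marginal slope ∂(response)/∂(predictor) on the standardized scale,
computed exactly via a unit finite difference of the linear predictor; for
growth the slope is taken on the growth rate (difference of the predictor
effect across the time range). The predictor × acclimation interaction is
the minimal structure that lets the effect vary by acclimation group, which
is how results are reported; classification reuses the trait-model rule.
Cell bookkeeping: 15 × (3 growth + 3 CT_max + 9 × 3 metabolic) = 495.

With six populations a population-level predictor competes with the
population random intercept; the screen therefore refuses to classify
non-converged fits (cells marked `unavailable`) instead of reporting
noise. Growth associations are screened twice — with and without the
outlier population — and keep their class only when direction and class
agree (otherwise `robust_to_trinity=False` and class `none`).

The historical-versus-current habitat temperature comparison is a
descriptive utility (the predictor table carries both metric families);
stream-temperature modelling itself is out of scope — the twelve
temperature metrics are treated as given inputs.

## Synthetic-data generator

The generator emulates the *structure* of the six-population ×
three-acclimation (11/16/20 °C) rearing study: biweekly growth samples of
30 fish per treatment per date over 42 days; CT_max trials of 18–25 fish
per treatment with a 30-min hold, a 0.33 °C/min ramp logged every 5 min,
Normal loss-of-equilibrium endpoints and ~6% non-recovery; respirometry
cohorts of 32–46 fish per treatment spread over acute test temperatures
from the 8–26 °C menu. Default trait magnitudes emulate the study's
published treatment summaries (growth 0.06–0.27 g/day; CT_max
27.8–30.1 °C with SD growing in acclimation temperature; RMR ≈ 2.2–2.7
mg O2 kg⁻¹ min⁻¹ at 16 °C with Q10 ≈ 1.7; AS domes peaking 7–12 mg O2
kg⁻¹ min⁻¹ at 17.5–23.5 °C); they are an emulation, not data. Noise is
Gaussian on saturation (sensor), on mass (growth), on LOE temperature, and
on each metabolic response — the minimal structure the Gaussian trait
models assume.

Oxygen traces are built by running the rate equations backwards from the
target RMR/MMR, with flush phases restoring saturation and sealed periods
shortened automatically if a requested rate would breach the 80% floor.
The default solubility (α·BP ≈ 9 mg O2 L⁻¹ at full saturation) and 0.1%
sensor noise jointly reproduce per-period regression r² near 0.98. With
zero noise the round trip through the extraction chain recovers generating
rates to numerical precision — the core identifiability check.

The predictor table's latitude, migration distance and migration slope are
the published population metadata (migration slope = hatchery elevation /
migration distance, m/km — the published table's verbal description
inverts this, but the stated calculation and the units identify
elevation/distance). The twelve stream-temperature columns are synthetic
stand-ins constructed from a latitude-driven warmth index plus independent
hydrological jitter, anchored to the published aggregate facts (current
habitats warmer than historical; rearing-season averages near 9.2/7.5 °C;
same-kind metric correlations near 0.9). `inject_env_effect` shifts
per-population trait parameters linearly in a z-scored predictor so screen
power and null calibration are measurable by construction.

What passing tests on these data do **not** show: robustness to probe
drift, background (microbial) respiration, non-Gaussian trait noise,
tank effects beyond metadata, body-size allometry, or real spatial
correlation among the temperature metrics. The generator is a calibration
harness, not a field-data simulator.

## Problem sizes used in the shipped checks

The validation suite runs at reduced scale chosen to keep the experiments
informative: parameter-recovery uses two populations with 10–18
observations per treatment, 2 × 600 retained draws, 50 replicates per
family (89% interval coverage must reach ≥ 80%); screen calibration uses
the full six-population design at 12–14 CT_max fish per treatment and two
replicate screens (~90 cells) for the null rate; the trace-level round
trip uses one population, 30 fish per treatment over six test
temperatures. The pipeline demo configuration runs three populations with
three predictors. All sizes are configuration, not constants — the default
`CohortConfig` is the full study design.

## Known limitations

* Gaussian responses only; the five published families are the scope.
  No Sharpe–Schoolfield or other mechanistic TPC shapes.
* The sampler targets modest-dimension GLMMs (tens of coefficients, few
  grouping factors). It enforces R-hat but does not compute effective
  sample sizes per parameter.
* Exact random-effect structures of the study's final per-trait models
  live in unpublished supplements; the defaults follow the main-text
  descriptions and are editable spec objects, so any structure can be
  configured.
* With six populations, population-level predictor effects are weakly
  identified by construction; the screen's honesty mechanisms (convergence
  refusal, robustness gating) mitigate but cannot remove this.
* The printed derived cells of the emulated study's tables are rounded
  from unrounded posteriors; exact-arithmetic checks use only the
  self-consistent rows.
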