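# salmoscope

Thermal physiology of salmon populations: a tested, reusable pipeline for
swim-tunnel respirometry, Bayesian thermal-performance trait models,
thermal-optimum estimation, and environment–phenotype association
screening — with a synthetic-data generator that emulates a six-population
common-garden rearing study of juvenile fall-run Chinook Salmon
(*Oncorhynchus tshawytscha*), so every stage can be exercised and validated
against known ground truth without raw field data.

It is written for ecophysiologists and quantitative ecologists who run
intermittent-flow respirometry and common-garden experiments and want the
full chain — raw oxygen traces to population-level inference — in one
scripted, seeded, auditable place.

## The models

**Respirometry.** Oxygen saturation logged each second in a sealed
swim-tunnel is converted to concentration and then to a mass-specific
oxygen-consumption rate:

    [O2] = (%O2Sat / 100) · α(O2) · BP                (mg O2 L⁻¹)
    MO2  = |R| · V · M⁻¹ · 60                          (mg O2 kg⁻¹ min⁻¹)

where *R* is the OLS slope of concentration on time within a sealed period,
*V* the tunnel volume (L), *M* fish mass (kg), α(O2) the temperature-
corrected oxygen solubility (mg O2 L⁻¹ mmHg⁻¹) and *BP* barometric pressure
(mmHg). Routine metabolic rate (RMR) is the mean of the three lowest
per-period MO2 overnight; maximum metabolic rate (MMR) is the steepest
window of ≥ 5 min during incremental swimming; aerobic scope AS = MMR − RMR.
QC drops periods with regression r² < 0.90, fish whose used periods fell
below 80% saturation, fish active during their lowest RMR periods, and
fish that did not survive trial or recovery.

**Trait models.** Five Gaussian linear mixed models, one per trait (growth
rate, CT_max, RMR, MMR, AS), all with population × acclimation-temperature
interacting categorical effects, z-scored responses and covariates, and
trait-specific acute-temperature forms: RMR exponential (linear on
log RMR), MMR linear in log₂ T, AS a second-order polynomial in T.
Posteriors come from a block Gibbs sampler (conjugate joint coefficient
draws; slice-sampled half-Normal scales; split-chain R-hat < 1.01
enforced); model search is stepwise by WAIC. Treatment means, pairwise
contrasts and acclimation capacities (20 °C − 11 °C cell differences) are
posterior summaries classified by the posterior-mass rule: **strong** if
≥ 94.5% of the posterior mass shares one sign, **weak** if ≥ 85%.

**Thermal optimum.** T_opt is the vertex −b/(2a) of the quadratic AS
thermal performance curve, estimated by posterior simulation: 500 draws
from the AS posterior, each predicted over an 8–26 °C grid and refit by a
quadratic; the vertex mean ± SD is reported, with extrapolation and
non-concavity flagged.

**Environmental screen.** Fifteen population-level predictors (latitude,
migration distance/slope, twelve stream-temperature metrics of current and
historical rearing habitat) are screened one at a time against the five
traits — 75 models, 495 classified associations — each model carrying a
population random intercept and, for metabolic traits, a predictor ×
test-temperature interaction so effects are read at 11/16/20 °C. Growth
associations must additionally survive excluding the slowest-growing
outlier population.

## Worked example

`examples/03_thermal_optimum.py` fits the quadratic AS model to synthetic
data for two populations and estimates each cell's thermal optimum:

```
thermal optimum (deg C, mean +/- sd | generating truth):
  Coleman      @  11C  18.59 +/- 0.23   | 18.68
  Coleman      @  16C  19.93 +/- 0.29   | 19.68
  Coleman      @  20C  22.48 +/- 0.48   | 21.88
  Trask River  @  11C  18.76 +/- 0.21   | 18.52
  Trask River  @  16C  19.89 +/- 0.28   | 19.52
  Trask River  @  20C  22.06 +/- 0.36   | 21.72

T_opt shift with warm acclimation (20C - 11C):
  Coleman      +3.90 +/- 0.53 C
  Trask River  +3.30 +/- 0.42 C
```

Each line is a treatment cell's posterior T_opt against the value the
generator used to build the data; every estimate lands within about one
posterior SD of truth. The positive shifts say warm-acclimated fish reach
peak aerobic capacity at warmer temperatures — the acclimation response the
models are built to quantify. The other examples cover the respirometry
round trip (`01`), treatment means and contrasts (`02`), the environmental
screen with an injected effect (`04`), and the full seeded pipeline with
manifest (`05`). A thin CLI mirrors the stages:
`salmoscope --demo --seed 1 run-all`.

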