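# Methods

## The problem

Cavity-nesting solitary bees provision each brood cell with pollen
gathered during a short nesting window. If the nesting period drifts away
from the flowering period of the plants a species actually uses, each nest
is provisioned more slowly and holds fewer cells — and, summed over a
population, fewer cells mean a lower per-year growth rate. The
match/mismatch hypothesis predicts that this penalty is strongest for
diet specialists, which cannot switch to alternative pollen sources, and
weakest for generalists. `matchdem` implements the full chain of
estimators needed to test that prediction on trap-nest field data:
phenology → mismatch → diet breadth → recruitment models → demography.

## Estimators

**Weighted mean date (WMD).** The phenological centre of a season is the
abundance-weighted arithmetic mean of observation days,
`WMD = Σ dᵢ aᵢ / Σ aᵢ`. Weights are relative, so the estimator is
invariant to uniform scaling of counts and to whether per-plot counts are
summed or averaged. Dates are whole days since a season anchor (1 July by
default, configurable), which keeps an austral spring–summer season inside
one `season_year`.

**Main floral resources.** For each bee species, per-nest pollen grain
counts are normalized to proportions (removing the counted-grains total as
a nuisance), summed across nests, and plant taxa are taken in descending
order of that summed abundance until they first reach 85% (configurable)
of the total. Equal abundances are broken lexicographically so the set is
deterministic. The set is identified once per species from all pollen
nests pooled, mirroring a pollen study restricted to the first seasons.
The flowering WMD of the set is computed on the day-wise *pooled* counts
of its members — a single composite curve in which each plant weighs in
proportion to its floral abundance — rather than an average of per-taxon
WMDs.

**Mismatch.** Nest-level: `|end_day − flowering WMD|` of the nest's own
season. Population-level: `|nesting WMD − flowering WMD|`, the nesting WMD
weighting each nest equally. Seasons with no nests of a species are
excluded (logged), not imputed; a season whose resource flowers were never
recorded is likewise excluded.

**Diet generalization.** Shannon diversity `H = −Σ pᵢ ln pᵢ` of the
summed per-nest pollen proportions. Natural log by default (the base is
configurable); only rank order across species is interpreted, so the base
is immaterial downstream.

**Brood-cell imputation.** Species whose cells cannot be counted directly
carry the length of the occupied cavity instead. A per-species OLS of
cells on length (≥ 3 training nests, non-degenerate lengths) provides
predictions, rounded to the nearest integer and floored at 1 — cells are
counts and a completed nest holds at least one. Direct counts are never
overwritten; imputed rows are flagged `estimated`.

**Mismatch–recruitment models.** Per species, two linear mixed models with
a random intercept per season: response `cells` (linear form) or
`ln cells` (exponential form), predictor mismatch days. Estimation is
maximum likelihood so the two AICs are comparable across mean structures;
the lower-AIC form is selected, ties favouring the exponential form. Note
the caveat that the two responses live on different scales, so the AIC
comparison is heuristic — it is nonetheless the field's customary
procedure and is implemented as such. For cross-species comparison the
standardized slope is obtained by z-scoring predictor and response before
fitting. The 95% interval for a slope uses a t quantile with
`n_years − 1` degrees of freedom: Wald z intervals are anti-conservative
with a single-digit number of year clusters, and a between-cluster df
correction is the standard small-sample remedy. Population-level
relationships use Spearman's rank correlation over seasons (≥ 4 required)
with the analytic standard error `√((1 − ρ²)/(n − 2))`; a bootstrap over
years is available behind a flag. Cross-species summaries are unweighted
means with a percentile bootstrap over species — intervals are wide by
construction at five species.

**Demography.** Yearly population size `N_t` is the summed brood cells of
all of a species' nests in season `t`; `λ_t = N_{t+1}/N_t` over
consecutive seasons, and the average growth rate is reported on the log
scale as `λ̄ = mean ln λ_t` (the log of the geometric mean of the
`λ_t`): `λ̄ > 0` growth, `< 0` decline. Transitions touching a zero or
missing season are dropped and logged rather than propagating infinities.
Uncertainty: 95% percentile bootstrap over 1000 resamples of nests with
replacement, stratified within season by default (preserving the
per-season nest counts the year structure of `λ̄` depends on); pooled
resampling is available for sensitivity. One reproducible random stream
per (seed, species) drives all replicates.

## The synthetic-data generator

The generator emulates the statistical structure of a 9-season, 2-site
trap-nest study so every stage is testable without field data:

* **Flowering**: per plant, a Gaussian day-of-season abundance curve
  (peak day, width, height) whose peak shifts each year by a normal
  deviate (sd 6 d), sampled at weekly surveys and rounded to integer
  counts split over sites and plots.
* **Nesting**: nest end days are normal around the species' resource
  flowering WMD of that season plus a *shared* climate-driven yearly
  offset (sd 6 d) — an early spring advances every species together —
  with a within-season spread of 15 d.
* **Recruitment**: `cells = max(1, round(exp(ln mean_cells + effect ·
  mismatch + year effect + noise)))`, with residual sd 0.12 and year-effect
  sd 0.06 on the log scale.
* **Pollen**: per nest, a Dirichlet composition around the species'
  preference vector (concentration 20, floor 0.002 on unused plants),
  counted multinomially with ≈ 300 grains; sampled only for nests of the
  first three seasons, as in a field pollen study.
* **Cavity lengths**: for length-measured species, `10 + 9·cells ± 4` mm,
  with 60% of their direct counts masked for imputation.

The default five species span diet preferences from near-monolectic
(92% on one plant) to uniform over eight plants, with per-species nest
totals over nine seasons following a 45/62/75/151/433 abundance ladder
(most-abundant species = most generalized) and mismatch effects of
−0.065, −0.020, −0.0098, −0.0032 and −0.0003 per day of mismatch on log
cells.

**Why these numbers.** The effect gradient, noise levels and year
structure were fixed by a power analysis so that the programmed
specialization/effect gradient is statistically identifiable at the
study-scale sample sizes above: the sampling error of a standardized slope
is ≈ √((1 − r²)/n), and adjacent species were spaced ≈ 2 standard errors
apart along the attainable range. Two structural choices matter for that
identifiability: yearly nesting offsets are shared across species (so
realized mismatch variances co-fluctuate and comparisons between species
are stable), and preference vectors keep each species' cumulative pollen
share comfortably away from the 85% threshold (so the estimated resource
set — and hence the flowering WMD the mismatch is measured against — is
stable across replicates; a set that flips adds classic errors-in-variables
attenuation).

**What the generator does not emulate.** Real floral curves are skewed and
multimodal; real year effects correlate with weather covariates; bees
compete for cavities; detection of nests is imperfect; pollen
identification has taxonomic error. Passing the recovery tests therefore
shows the estimators are correct and calibrated under the assumed
structure, not that the field design is unbiased.

## Numerical and degenerate-input choices

* WMD with no positive abundance, all-zero pollen, or an empty nest table
  raise typed errors; a zero-nest season is a logged exclusion, not an
  error.
* Resource-set threshold comparison is `≥` (first reach stops the greedy
  scan).
* Imputed predictions below 1 clamp to 1 with a warning; negative fitted
  slopes warn but do not abort.
* A constant model response yields a flagged degenerate fit with slope 0
  rather than an exception; a constant predictor is an error.
* A noiseless mixed-model problem (singular random effect) falls back to
  the fixed-effects fit with a warning.
* Mixed models fit by ML via `statsmodels.MixedLM`; OLS via
  `statsmodels.OLS`; Spearman via `scipy.stats.spearmanr`.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; generator output is bit-reproducible.

## Problem sizes used by the test suite

Closed-form and oracle checks run on printed examples and 1000 random
small inputs. Stochastic calibration checks use: 100 replicates of a
single-species scenario (9 seasons × ~150 nests/season, effect
−0.03/day) for slope-CI coverage and AIC form selection; 50 replicates of
the default five-species scenario for the slope-vs-H ordering; and 200
replicates of a 9-season × 60-nest population growing at 0.2/year for
bootstrap-CI coverage. These sizes match the scales the generator's
defaults describe.

## Known limitations

* AIC across response transformations (cells vs ln cells) omits the
  Jacobian correction; the selection mirrors the customary procedure, and
  with multiplicative data the exponential form wins decisively anyway.
* The Spearman SE is an analytic approximation, poor below ~8 seasons;
  treat per-species ρ intervals at n = 9 as indicative.
* λ̄ over a complete series telescopes to `(ln N_last − ln N_first)/k`;
  with interior zero seasons the dropped-transition rule makes λ̄ depend
  on the surviving pairs only, which is a choice, not the only one.
* The cells-vs-length regression pools trap diameters; if provisioning
  density varies with diameter the imputation inherits that bias.
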