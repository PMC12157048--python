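# Methods

## The estimation chain

Three whole-body fat-mass percentages (FM%) are computed per participant.

**Evans 3-skinfold equation.** FM% = 8.997 + 0.24658·ΣSKF − 6.343·sex −
1.998·race, where ΣSKF is the triceps + abdominal + thigh skinfold sum in mm,
sex is 0 for men and 1 for women, race 0 for white and 1 for black
participants. It is applied twice: to caliper skinfolds and to
ultrasound-derived skinfolds, i.e. the raw single-layer US thickness
(epidermis to muscle fascia) multiplied by 2. Because the equation is linear
in ΣSKF, the group mean FM% equals the equation at the group mean sum — the
package exploits this (`group_mean_reproduction`) to recompute group-level
differences from published summary rows alone.

**Modified four-component reference.** Wang's 4C equation,
FM% = 100·(2.748·BV − 0.699·TBW + 1.129·BMC − 2.051·BM)/BM, with body volume
from DXA compartments at fixed densities (fat 0.9007, lean soft tissue 1.064,
bone mineral 2.982 kg/L) and total body water from 50 kHz foot-to-hand BIA
resistance (TBW = 0.286 + 0.195·stature²/R + 0.385·BM + 5.086·sex). Units:
stature in cm, R in ohm, masses in kg, BV in L; TBW in kg is used
interchangeably with L (density 1) inside Wang's expression, the convention
of the source equations. Note the coding trap: the TBW equation codes male =
1 while Evans codes male = 0; `ParticipantRecord` stores both codings and
validates that they are inverses rather than inferring one at call sites.

Equation constants live in one immutable `EquationConstants` bundle; every
function takes the bundle as an argument, so a test can perturb a coefficient
and prove nothing is hard-coded. FM% outside [0, 100] is flagged, never
clamped — a validation analysis must see pathological outputs.

## Agreement statistics

* Paired t (two-sided) with the 95% CI of the mean difference from the t
  distribution on n − 1 df. Zero-variance differences are returned as flagged
  degenerate results (t = 0, p = 1 for identical sequences; t = ±inf, p = 0
  for a constant offset) so pipelines can report nulls instead of crashing.
* Bland–Altman: bias = mean(alt − ref); 95% limits of agreement =
  bias ± 1.96·SD(diff) with the sample (n − 1) SD. No small-sample exact-t
  correction is applied; 1.96 is the conventional multiplier and is
  configurable (`loa_multiplier`). The proportional-bias "trend" is the
  Pearson correlation of differences against pair means — the standard check;
  it is reported as a flagged null when either variance is zero.
* Lin's CCC with population (1/n) moments (Lin's original estimator; the
  bias-corrected variant differs at O(1/n)). McBride strength bands with the
  exact boundary semantics: poor < 0.90 ≤ moderate ≤ 0.95 < substantial ≤
  0.99 < almost perfect; boundary values are pinned in tests.
* OLS of caliper skinfold on raw US thickness via statsmodels, with site
  encoded as two indicators against the triceps reference level and gender as
  one indicator (male = 0). Any full-rank coding yields the same R² and SEE,
  which is what is compared. SEE = sqrt(SSE/(n − p)), p = number of estimated
  coefficients. Rank deficiency raises a collinearity error naming columns;
  saturated designs (n ≤ p) are rejected.
* R² classes: substantial [0.75, 1.00], moderate [0.50, 0.75), weak
  [0.25, 0.50), below-weak otherwise.
* Reliability: CV% = sample SD/mean × 100; TEM = sqrt(Σd²/2n) over duplicate
  trials with %TEM relative to the grand mean (the standard anthropometric
  duplicate-measurement form); ICC implemented as the two-way mixed,
  single-measure, consistency coefficient ICC(3,1) = (MS_subjects −
  MS_error)/(MS_subjects + MS_error) for two trials — the usual model for one
  rater's test–retest.
* A-priori sample size: smallest N whose overall-F power reaches the target,
  with numerator df = number of predictors, denominator df = N − predictors −
  1 and noncentrality λ = f²·N (the total-sample-size convention used by
  standard power software). f² = 0.3, α = 0.05, power = 0.8, 2 predictors
  gives N = 36, cross-checked in the tests against an independent
  Poisson-mixture noncentral-F series.
* No multiple-testing adjustment is applied anywhere; p-values are reported
  unadjusted at α = 0.05, and printed to 3 significant figures (never
  "p = 0.000").

## Synthetic cohort generator

Raw individual data for this design are not publicly available, so the
generator emulates the study conditions: 19 men and 18 women by default, with
per-sex means ± SDs transcribed from the published group table for body mass
(79.1 ± 9.7 / 57.4 ± 5.7 kg), stature, DXA fat % (19.4 ± 5.4 / 24.9 ± 6.0),
bone mineral content, the three caliper skinfolds, the three US-derived
skinfolds (halved to give raw US parameters), and the three site-specific
compressibility ratios (men 1.0/1.4/1.7, women 1.2/1.2/1.8 at
triceps/abdominal/thigh).

Mechanism, per subject:

1. a latent adiposity score z ~ N(0, 1);
2. raw US thickness per site = mean + SD·(λ·z + √(1 − λ²)·ε), λ = 0.6 by
   default (the cross-site correlation loading), truncated and rounded to the
   0.1 mm recording grid;
3. compressibility ratio per site from a truncated normal with floor 0.5
   (ground truth returned for recovery tests);
4. caliper skinfold = ratio × raw US × (1 + δ), δ ~ N(0, 0.05) — a caliper
   re-measurement CV at the 5% technical-error bound — rounded to 0.1 mm;
5. DXA fat % = mean + SD·(λ·z + …), truncated to (0, 100): adiposity couples
   US thickness and DXA fat;
6. **mass balance**: lean soft mass = body mass − fat mass − BMC + N(0,
   0.6 kg), re-centred so its population mean matches the configured lean
   soft mass mean. The 0.6 kg residual represents the typical discrepancy
   between DXA total mass and scale mass; drawing lean mass independently of
   body mass would violate mass conservation and inflate the 4C FM% SD to
   tens of percentage points, which no real cohort shows.
7. **hydration chain**: TBW = h·(lean soft + BMC)·(1 + ν), ν ~ N(0, 0.02),
   with the per-sex hydration fraction h anchored so the configured mean
   resistance reproduces the published mean TBW (h ≈ 0.79 men, 0.76 women —
   slightly above the textbook 0.73 because these equations' lean soft mass
   excludes residual mass); BIA resistance is then back-solved through the
   impedance equation (≈ 436 Ω men, ≈ 529 Ω women at the means).

Consequences of 6–7: the configured lean-soft-mass and resistance SDs are not
independent dials — those spreads emerge from the balance — while all means
are honoured. Truncation at a lower bound uses a *symmetric* window about the
(latent-shifted) mean, [low, 2·centre − low], so configured means recover
exactly in expectation; one-sided truncation at the ratio floor 0.5 would
bias the male triceps ratio mean upward by ≈ 0.08 and defeat parameter
recovery. Seeding: one integer seed; each subject draws from a substream
keyed by (seed, sex, index), so enlarging the cohort never reshuffles
existing subjects.

What the generator does *not* emulate: the internal inconsistency of the
published women's summary row (the printed 4C chain at the female means
yields ≈ 22% FM, not the printed 15.4 ± 1.6 — the generator is
self-consistent, so its female 4C FM% is ≈ 22%); between-site ratio
correlations beyond the single shared factor; any skewness, age structure, or
measurement-operator effects. Passing tests therefore demonstrate internal
consistency of the pipeline and recovery of the generating structure, not
agreement with the unavailable individual data; individual-level published
statistics (CCC 0.33, trend r 0.8, R² 0.52/0.62/0.63, t 7.1) are *not*
reproduction targets.

## Pipeline choices

* Input: plain CSV, one row per subject; schema errors are collected per row
  and column and raised together. A missing `race` column defaults to white
  for all subjects (the study population makes the Evans race term vanish; a
  logged note records the default).
* Inclusion filters mirror the study: BMI < 30 kg/m² always; age ≥ 16 only
  when an optional `age_y` column is present (the schema carries no age).
  Each exclusion is logged with its reason. Filters are configurable.
* Nested regressions pool the three sites — one observation per subject ×
  site (111 rows at full sample) — since the design reports a single R² with
  site as a covariate; per-site and per-gender stratified fits are reported
  alongside. The nested R² sequence is non-decreasing by construction.
* Ratio summaries are means of per-subject ratios, not ratios of group means.
* The report serializes to versioned JSON and round-trips losslessly;
  re-fitting the same input reproduces the report except for the provenance
  timestamp. No figures are generated by the pipeline; plotting is left to
  the caller's tooling.
* Degenerate statistics surface as flagged nulls with reasons, never silent
  NaNs.

## Problem sizes used by the test and acceptance suites

Oracle-agreement checks run each statistic against an independent brute-force
implementation on 1,000 random instances of 6–12 pairs. Parameter-recovery
checks use 2,000 subjects per sex (ratio means within ±0.05; noise-free
regression slopes within 5%). The overestimation-direction check runs 200
seeded cohorts at the study's own size (19 + 18) and requires the doubled-US
Evans mean to exceed the 4C mean in at least 95% of them. The full suite
completes in well under a minute on one core.

## Known limitations

* The published female summary row is internally inconsistent under the
  printed 4C chain (see above); the package computes internally consistent
  values and does not force the printed ones. The published abstract's limits
  of agreement and CI likewise do not bracket their own stated mean
  difference; no attempt is made to match them.
* The Evans equation is population-specific (active young adults); nothing
  here validates its use elsewhere.
* The generator's truncated-normal marginals ignore the mild right-skew
  typical of skinfold data.
* ICC is implemented for the two-trial test–retest case only.
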