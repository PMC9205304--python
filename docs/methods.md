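# Methods

## The classification problem

Sex in young gopher tortoises cannot be read externally; the validation
standard is laparoscopy. Plasma testosterone distributions of the two
sexes overlap but males sit higher, with separation increasing by age
class: heavily overlapping in neonates (<7 days), moderately in
hatchlings (4–8 months), and completely in juveniles (~3.5 years). All
calibration in this package is nonparametric — estimators operate on
empirical per-sex proportions — because male testosterone in this species
is poorly fit by standard positive families (lognormal, gamma), and a
misfit tail would directly corrupt a threshold.

## Threshold estimators

Candidate cutoffs form a grid from the pooled (both-sex) minimum to
maximum observed value in fixed steps of 0.1 pg/mL (configurable). The
grid follows `seq(min, max, by=step)` semantics: the minimum is always a
grid point; the maximum is included only when the range is a multiple of
the step. At each cutoff `t`:

- `err_F(t)` = fraction of females strictly above `t` (non-increasing);
- `err_M(t)` = fraction of males strictly below `t` (non-decreasing).

"Above"/"below" are strict throughout; a value exactly at a two-way
threshold is called female. **T_m** minimises `err_F + err_M` (rates, not
counts, so uneven sex ratios do not bias the optimum); **T_E** minimises
`|err_F − err_M|`. Ties between equally optimal grid values resolve to
the smallest value by default, with a midpoint-of-the-first-optimal-run
alternative behind a flag; the tie rule is a reporting convention, not a
statistical choice, and both are deterministic.

The error-rate curves are computed as exact counts over sorted arrays
(`count/n`, never `1 − complement/n`), so floating-point ties in the
objective resolve identically to naive enumeration — the grid search is
bit-for-bit equal to exhaustive brute force, which the test suite checks
on random datasets.

## Likelihood thresholds and the "unknown" band

Under equal prior probability of either sex, Bayes' theorem gives

    P(F | T < x) = P(T < x | F) / (P(T < x | F) + P(T < x | M)),

estimated by per-sex empirical proportions at each grid point (strict
inequalities), and mirrored for `P(M | T > x)`. Grid points whose
conditioning event is empty (e.g. nothing strictly below the pooled
minimum) are flagged undefined and excluded — never imputed to 0 or 1,
which would fabricate certainty exactly where data run out.

A cubic smoothing spline (`scipy.interpolate.make_smoothing_spline`,
penalty chosen by generalised cross-validation) is fitted to the defined
points and clamped to [0, 1]. `T_PF` is the largest grid value whose
smoothed female posterior still reaches the level (0.80/0.90/0.95);
`T_PM` the smallest grid value whose male posterior does. Values between
the two are scored "unknown"; the per-sex fractions so excluded are
reported alongside. When the sexes separate well the band *inverts*
(`T_PF > T_PM`): the package signals band collapse rather than returning
a nonsensical band, since the two-way `T_E` call already exceeds that
accuracy level. The exact spline settings of historical analyses are not
recoverable, so likelihood thresholds are inherently approximate at the
level of a few grid steps; the band-collapse behaviour and exclusion
fractions are the robust outputs.

Juveniles need no estimator: the distributions separate completely and a
conventional cutoff of 700 pg/mL (roughly midway between the observed
ranges) is exposed as a constant, not fitted.

## Uncertainty and validation

**Bootstrap.** Females and males are resampled independently with
replacement at their original sizes (stratified, preserving the design's
fixed per-sex n); the estimator is refit entirely within each of 1,000
replicates; the 2.5%/97.5% quantiles give a 95% percentile interval.
Replicates where the estimator fails are recorded missing; more than 10%
failures aborts. Simulation places the interval's coverage of the true
equal-error point at ~95% for n = 200/sex (checked in the test suite at
200 outer simulations).

**Leave-one-out cross-validation.** Each animal is held out, the
threshold refit on the rest, and the animal classified female iff its
value ≤ the refit threshold. Per-sex errors and a pooled overall error
(which therefore reflects the sample's sex ratio) are reported; these are
comparable to a random forest's out-of-bag error. The refit threshold
uses the midpoint-of-optimal-run tie rule by default: with the
smallest-value rule, removing the boundary animal of a well-separated
sample moves the optimal run's lower edge below that animal's value, so
the largest female of *every* perfectly separated dataset would be
scored an error — LOOCV would report nonzero error where the apparent
error is zero. The midpoint rule removes this artefact while remaining
deterministic.

**Permutation t-tests.** The FSH-response contrast (male vs female
changes, absolute and percent) uses the Welch t statistic with a null
distribution from 10,000 random label permutations and the add-one
p-value `(1 + #{|t*| ≥ |t|}) / (1 + n_perm)`. A conventional Welch 95% CI
on the mean difference is reported alongside. Test size is ~5% at
α = 0.05 (checked over 1,000 null simulations).

## Morphometrics and the random forest

From MCL, SH, CW, PMIN, PMAX (mm) the package derives
`VOL = MCL·SH·CW`, the five volume-corrected measurements `X/VOL`, and
the ratios CW/MCL and CW/SH — thirteen core features, plus raw and
volume-corrected AW, AN, GW, TL for hatchlings. Volume-corrected features
scale as c⁻² and ratios are scale-invariant (property-tested). A
testosterone column can be joined by animal id.

The classifier is a random forest because the derived features are
strongly multicollinear (a linear discriminant is inappropriate) and the
signal is weak and multivariate. Trees are scikit-learn
`DecisionTreeClassifier`s; the package owns the bagging: each tree trains
on a *balanced* bootstrap — x draws with replacement from each class,
x = rarer-class size — so uneven sex ratios cannot be absorbed into the
prior. Out-of-bag votes from trees that did not sample an animal give
per-class and overall OOB error; variable importance is OOB permutation
importance (mean decrease in accuracy). `mtry` is 5 for combined
hormone+morphology models and 1 for testosterone-only models; `ntrees`
defaults to 10⁴, by which point OOB error has stabilised (10⁵ is
available via config for final runs). Vote ties resolve to female,
deterministically. RF results are seed-deterministic but tolerance on
reported OOB values is ±3 percentage points across seeds.

## Assay quality control

Extraction efficiency per spiked sample is
`E = (M_spiked − M_unspiked)/S` with S the known spike (pg); E > 1
(over-recovery) is reported, not clamped. `%CV = 100·SD/mean` with the
n−1 SD. Plate summaries: within-plate CV = mean of per-plate reference
CVs; between-plate CV = CV of per-plate means; within-replicate CV =
mean CV of technical duplicate pairs. The pooling convention is the
standard plate-QC one; it is stated here because other decompositions
exist.

## Synthetic scenarios

Each scenario draws per-sex testosterone from lognormal distributions
whose (log-location, log-scale) are back-solved from the study groups'
published sample means and standard errors at the published sizes
(SD = SE·√n): neonates F 17.9/M 51.7 pg/mL (44/18), hatchlings
F 27.9/M 206.0 (66/25), juveniles F 79.8/M 3341 (11/12); a null scenario
gives both sexes the hatchling-female distribution. Where only mean/SE
is printed, the implied SD is approximate. The heavy male tail (observed
extreme values near 1,200 pg/mL in hatchlings) comes from the lognormal
tail itself, not a mixture.

The paired FSH scenario models `post = pre × factor × noise` with
mean-one lognormal noise (log-SD 0.3) and factors 3.61 (M) / 2.04 (F),
so expected percent rises are exactly 261% and 104% regardless of the
noise scale; paired sizes are 65 F / 23 M.

Morphometrics: each animal gets a shared lognormal size factor (log-SD
0.06) times per-feature lognormal noise (log-SD 0.025) around age-class
baseline dimensions; PMAX = PMIN × (1 + gap) with a strictly positive
gap, so PMIN < PMAX always. Sex dimorphism is a log-scale shift on
selected features, specified in units of the feature's total SD; the
default ({CW: 0.5, SH: 0.4, PMAX: 0.3}) is deliberately weak. Note that
shifting *all* features equally is a pure size change that the ratio
features cancel — dimorphism here is shape, not size.

What the generator does **not** emulate: assay measurement error and
plate effects on the hormone values, year/cohort structure, any
correlation between an animal's testosterone and its morphology, or
non-lognormal features of the real distributions. Passing tests
therefore demonstrate correctness of the estimators under a controlled
data-generating process, not field performance of the thresholds.

## Problem sizes used in checks

Simulation-based tests use n = 2,000/sex (parameter recovery, 20 draws),
n = 200/sex with 1,000 bootstrap replicates × 200 simulations (interval
coverage), 1,000 null permutation tests at n = 20/group, and a
10⁴-tree forest on 200 animals (chance baseline). The acceptance script
runs every scenario at its published sample sizes with 1,000 bootstrap
replicates and 10⁴ trees.

## Known limitations

- Likelihood thresholds depend on the spline smoothing; only band
  structure and ~grid-step accuracy are guaranteed.
- The equal-error threshold is a step-function estimator; its sampling
  SE at the hatchling preset is ~0.6 pg/mL even at n = 2,000/sex, so
  single-draw agreement with the population crossing is limited by
  sampling noise, not by the grid.
- Bootstrap intervals are percentile-based; no BCa correction.
- LOOCV refits per fold with the midpoint tie rule (see above); reported
  calibration thresholds use the smallest-value convention, so the two
  can differ on data with wide optimal runs.
- The forest's per-class errors vary a few percentage points across
  seeds at realistic sample sizes; treat reported OOB values accordingly.
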