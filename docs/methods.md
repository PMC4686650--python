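# Methods

## The visual scale

Incomplete hippocampal inversion (IHI, also called hippocampal malrotation)
is an atypical anatomical pattern — a round, verticalized, medially
positioned hippocampal body with a deep collateral sulcus — of presumed
developmental origin, observed in healthy subjects as well as in epilepsy
populations. The package encodes a five-criterion visual rating scale for
coronal T1-weighted MRI:

| criterion | feature | codomain |
| --- | --- | --- |
| C1 | roundness x verticality of the hippocampal body | {0, 0.5, 1, 1.5, 2} |
| C2 | depth and verticality of the collateral sulcus | {0, 0.5, 1, 1.5, 2} |
| C3 | medial positioning (dentate-gyrus coverage of subiculum), modulated by the temporal horn | {0, 0.5, 1, 1.5, 2} |
| C4 | subiculum thickness (bulging upward) | {0, 2} |
| C5 | fusiform-gyrus sulci crossing the subiculum level | {0, 1, 2} |

The grading maps are exhaustive lookup tables; the only undefined cell is
C1 = (flat, vertical), which is anatomically impossible and raises a
not-applicable error. The composite IHI score is the plain sum of the five
grades, ranging 0–10 on a 0.5 grid. A global criterion C0 (0 no IHI /
1 partial / 2 total) is rated independently of the individual criteria.

### Geometric adapters

The scale is defined visually: raters do not trace segments. For pipelines
that record landmark measurements anyway, three adapters quantify the
qualitative judgments, with tolerances that are package choices (the scale
itself prescribes none beyond "around 10 degrees"):

* roundness: C1a and C1b count as equal ("round") when they differ by at
  most `rel_tolerance` (default 0.1) of the larger segment;
* verticality: horizontal within `tol` (default 10°) of 0°, vertical within
  `tol` of 90°, oblique otherwise;
* C3 exposure: the ratio C3a/C3b is binned at cutpoints (0.25, 0.8, 1.25,
  4.0), chosen roughly symmetric on the log scale around 1; an invisible
  C3a always maps to the most-medial bin.

All three are configurable; none affects analyses that ingest grades
directly.

### Threshold fitting

The binary IHI / non-IHI classification thresholds the composite score.
The threshold is fitted by maximizing classification accuracy against the
reference classes C0 = 0 and C0 = 2 (partial-IHI hippocampi are excluded
from the fit but classified afterwards). Candidate thresholds are midpoints
between consecutive distinct observed scores; accuracy ties resolve to the
smallest maximizing candidate. Because scores live on a 0.5 grid, perfect
separation between 3.5 and 4.0 yields the threshold 3.75, and the strict
rule "score > threshold" is then identical to "score >= 4". The fit is
invariant to record order and duplication by construction.

## Agreement statistics

Reliability uses Cohen's kappa for the nominal/two-level criteria (C0, C4,
C5) and linearly weighted kappa (disagreement weights |i−j|/(k−1) over
category ranks) for the graded criteria (C1, C2, C3). Linear rather than
quadratic weights were chosen because the grades are equally spaced
half-steps; quadratic weights are available via the `weighting` argument.
Confusion tables always span the criterion's full category set, so chance
agreement and the weight matrix refer to the scale rather than the sample;
a criterion whose series are constant and identical across raters (chance
agreement 1) is reported as not-evaluable rather than assigned a kappa.

Standard errors use the large-sample Fleiss–Cohen–Everitt form with a
normal 95% interval clipped to [−1, 1]; a seeded bootstrap percentile
interval is available. The implementation was cross-checked against
statsmodels' kappa (point estimate and SE agree to machine precision);
published interval values for the original rating sessions are not
reproduced because the underlying ratings are not public and the original
interval method is not identifiable from the printed values.

## Prevalence and lateralization

Binomial proportions use the Wald normal approximation clipped to [0, 1]
(the method that reproduces the published per-side confidence intervals at
n = 2008 exactly to printed precision); Wilson intervals are available.
`proportion_ci` accepts fractional counts so an interval can be
reconstructed from a published rounded percentage.

Chi-square tests are Pearson without continuity correction. The side
comparison stacks left and right hippocampi of the same subjects as
independent samples, replicating the original analysis; a Stuart–Maxwell
marginal-homogeneity variant (`paired=True`) is provided for the
methodologically paired reading. Subjects with missing C0, missing sides,
or missing covariates are excluded listwise per test and the exclusion
counts are reported, never silently dropped.

The threshold-based frequency table supports two modes: `classify_all`
(every hippocampus classified by score) and `exclude_partial` (only C0 in
{0, 2} classified, whole side population as denominator, so the two class
shares leave out the partial mass).

## Sulcal-morphometry association

Group construction: subjects classified IHI on the left (right) form the
left (right) IHI group; non-IHI subjects have IHI on neither side; a
subject with only a contralateral IHI enters neither group of a given
comparison. Four directions pair each IHI side with each hemisphere's
sulci. Per (sulcus, measure) cell, complete-case pooled-variance Student's
t (as in the original analysis; Welch is deliberately not the default) and
Cohen's d = (mean_IHI − mean_nonIHI)/pooled SD, with the algebraic identity
d = t·sqrt(1/n_a + 1/n_b) holding per cell. Degenerate cells: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means a signed
infinite t; zero pooled SD makes d undefined (NaN) unless the means agree.

Bonferroni correction multiplies raw p-values by the fixed design family
size m = 45 sulci × 5 measures × 4 directions = 900, regardless of cells
missing in a given dataset. The "length" measure appears in the data model
and output (it occurs in published association results) but is not one of
the five family measures; the results carry the family definition in their
metadata so the discrepancy is visible.

The packaged 45-label nomenclature uses BrainVisa-style abbreviations and
is an editable plain-text resource; it includes the labels appearing in the
published association table. The package consumes Morphologist-style
tabular output only — sulcus extraction, labeling and any image processing
are out of scope.

## Synthetic cohort generator

The original cohort (2008 adolescents, two rated hippocampi each) is
access-restricted, so a generator emulates the statistical structure the
analyses depend on:

1. Per subject, a latent severity pair (z_L, z_R) is drawn bivariate normal
   with correlation `side_coupling` (default 0.85).
2. Per criterion and side, a Gaussian-copula uniform with loading
   `criterion_coupling` (default 0.65) on the side latent is inverted
   through the side's configured grade marginal. Defaults are the published
   grade repartitions. (The published right-hemisphere C1 row sums to 69%
   as printed — an apparent typesetting defect; the grade-0 cell is
   completed to the row total before normalizing.)
3. The score is the sum of grades; C0 is drawn from a per-side band rule on
   the score. Bands below 4 never emit total IHI and bands at/above 4 never
   emit absent IHI, which (a) mirrors the published separation of the score
   histograms by C0 and (b) guarantees the fitted threshold lands at 3.75
   whenever scores 3.5 and 4.0 are both observed.

The two couplings and the band probabilities were calibrated once against
the published per-side prevalence and left×right co-occurrence tables using
a 200 000-subject pilot: band masses were measured, then the band
probabilities solved linearly so the expected C0 marginals match the
printed frequencies. A single band table cannot fit both sides (their score
distributions differ in shape), hence the per-side rule; the total-IHI band
probabilities are shared. Residuals at n = 60 000: left C0 frequencies
(0.708, 0.122, 0.170) against printed (0.709, 0.119, 0.171); right (0.845,
0.089, 0.066) against (0.846, 0.090, 0.065); the (total-left, no-right)
co-occurrence cell 0.107 against 0.108. The frozen defaults are the study
conditions for every test; they are not adjusted per test.

Rater noise is an independent adjacent-grade perturbation with probability
`rater_error` (default 0.1), reflecting that real disagreements on an
ordinal visual scale are overwhelmingly one-step. Sulcal measures draw
group-conditional normals in the configured effect cells — defaults are the
published association cells with pooled SDs back-computed from the printed
means and d — and a per-measure baseline with no group difference
elsewhere. When ipsi- and contralateral effects target the same cell, the
later-listed effect's IHI group takes precedence.

What the generator does **not** emulate: inter-site/scanner heterogeneity,
age effects, correlations between sulcal measures, non-normal measure
distributions, and any spatial structure. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the modeled
structure, not robustness to real-data messiness.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 250–2000 subjects (5000–60 000 for
marginal-recovery and calibration checks), 1000 replicates for the t-test
type-I calibration, and restricted sulcus sets where the full 45-label
table adds nothing — sizes chosen to keep the suite fast while leaving
sampling error well inside the asserted tolerances. Grades are validated
against their codomains with exact half-step comparison (isclose at machine
tolerance); CSV round trips write grades as one-decimal strings. All
randomness flows through `numpy.random.default_rng` seeded explicitly;
identical seeds give byte-identical pipeline output bundles (provenance
hashes cover analysis parameters, not file locations).

## Known limitations

* Published chi-square and kappa values that depend on unpublished
  subject-level data are reproduced only in magnitude (the side comparison
  reconstructed from rounded percentages gives ≈127–128 against a printed
  129.2) or not at all (rating-session kappas); the published association
  t/d values are mutually inconsistent under any single group size, so the
  association study is validated by recovery on synthetic data instead.
* The CLI maps the package's error taxonomy to exit codes 1/2/3; malformed
  command lines handled by click itself exit with click's own code.
* Handedness comparison of the original study reports degrees of freedom
  inconsistent with its p-values; the package simply computes the standard
  group × C0 table test.
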