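# Methods

This note documents the statistical models implemented in `longomics`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## The deviation statistic and its null model

For one molecular feature and one pooled set of stress events, let
X<sub>s</sub> be the (transformed) value of sample *s*. The null model
is a subject-intercept Gaussian: X ~ N(μ<sub>i</sub>, σ²) for subject
*i*, i.e. the feature has a personal setpoint but no event response.
Event samples fall into stages EE (event days 1–6), EL (days 7–14) and
RE (days 15–40); each subject-event unit also has n<sub>b</sub> healthy
baseline visits (healthy samples within 186 days before onset or after
the last event visit).

Baseline correction subtracts the unit's baseline mean: X̃<sub>s</sub> =
X<sub>s</sub> − b̄<sub>u(s)</sub>. The statistic is

AUC = (m̃<sub>EE</sub> + m̃<sub>EL</sub> + m̃<sub>RE</sub>) / std̃,

with m̃<sub>α</sub> the mean of corrected samples in stage α over the
pooled events (samples weighted equally; stages missing from the pooled
set simply drop out of the sum).

**Variance bookkeeping.** Writing the numerator as a linear combination
of raw observations, an event sample in stage α carries weight
w<sub>s</sub> = 1/|G<sub>α</sub>|; each of unit *u*'s baseline visits
carries weight −c<sub>u</sub>/n<sub>b,u</sub>, where c<sub>u</sub> is
the summed event-sample weight of the unit. The subject mean
μ<sub>i</sub> then cancels exactly within every unit, and

Var(numerator) = σ² · Σ<sub>u</sub> ( Σ<sub>s∈u</sub> w<sub>s</sub>² + c<sub>u</sub>²/n<sub>b,u</sub> ).

σ² is estimated by pooling the within-unit variance of baseline visits
(summed squared residuals around unit means over summed degrees of
freedom). With std̃ = σ̂·√(Σ …), the statistic is standard normal under
the null up to the σ̂ estimation noise; with the 20-subject × 5-baseline
design of the calibration runs that noise is a t-like inflation of the
variance by df/(df−2) = 80/78 ≈ 1.03, well inside the calibration
band. Monte-Carlo calibration (10,000 replicates) and the closed-form
power prediction Φ(−z<sub>α/2</sub> + Σδ<sub>α</sub>/std̃) are both
exercised in the acceptance tests.

Degenerate inputs: features with constant baselines (σ̂ = 0) are flagged
and carry no p-value; units with no baseline visit are dropped and
recorded; a healthy visit lying in two events' windows serves both
(per-event analyses are treated as independent). p-values are two-sided
from N(0, 1); q-values are Benjamini–Hochberg.

Stage-wise comparisons use the classical paired t-test on per-subject
(stage mean, baseline mean) pairs. The time-regression comparator is
OLS with calendar day as a real covariate and subject indicators.

## Variance decomposition of healthy baselines

Per feature, healthy-visit values are standardized to total variance 1
and fitted with a linear mixed model — fixed covariates Days, A1C,
SSPG, FPG and a random subject intercept — by maximum likelihood (not
REML), so the ICC is the random-intercept variance on the unit-total
scale. Two numerical details:

- When the residual variance collapses toward zero (e.g. exact
  within-subject replicates) the profiled variance-ratio parameter is
  numerically unbounded and the reported absolute components are
  arbitrary; the ICC is therefore derived from the between/within
  *ratio* times the non-fixed variance share, which is exact in both
  degenerate limits. If the mixed fit fails outright, a one-way ANOVA
  moment estimator on covariate-adjusted residuals is used instead.
- Fixed-covariate shares are attributed sequentially (type-I
  incremental R², in the order Days, A1C, SSPG, FPG) and rescaled to
  the fitted fixed-effect variance so ICC + fixed + residual = 1
  exactly.

Subjects without SSPG are excluded from these fits. Days enter in days
(not years); the ICC is scale-free so this choice is cosmetic.

The individuality score is computed in standardized feature space (not
embedding space): per-subject medians over healthy visits, mean
Manhattan distance over subject pairs, divided by the number of
features. It is translation-invariant and positively homogeneous in
between-subject offsets. The MDS embedding is non-metric, 2-D, on
Manhattan distances, seeded for reproducibility up to
rotation/reflection.

## Correlation machinery

**rmcorr** is computed from within-subject-centred variables: r is the
correlation of the centred pairs, df = N − k − 1 for k subjects,
p from F(1, df), and the 95% CI uses Fisher's z with SE = 1/√(df−1)
(the CI method is unspecified in common usage; this is the standard
meta-analytic choice). The implementation is verified against an
explicit ANCOVA (subject dummies + common slope) to 1e-10 and against
`pingouin.rm_corr`.

**Partial correlation** residualises both variables on the covariates
(with intercept) and correlates the residuals; df = n − 2 −
p<sub>cov</sub>. With no covariates it equals Pearson exactly. A
variable fully explained by the covariates returns r = 0, p = 1 rather
than a 0/0 artefact. SSPG and IR/IS screens apply this to per-subject
healthy medians with BMI, age and sex as covariates (IR/IS as a 0/1
dummy), BH within the screen.

**SparCC.** Counts at one taxonomic rank are converted to fractions by
Dirichlet posterior draws (pseudocount 1); log-ratio variances
t<sub>ij</sub> = Var log(f<sub>i</sub>/f<sub>j</sub>) are inverted
under the sparsity assumption to basis variances (negative solutions
clamped to a small positive floor) and correlations; the most strongly
correlated pair above the exclusion threshold (default 0.1) is removed
from the linear system iteratively (default 10 exclusion rounds, never
letting a taxon drop below 3 partners); the estimate is the median over
20 outer draws. Edge p-values come from null datasets built by
permuting each taxon's counts independently (default 100), two-sided
on |r|. At n = 200 samples any basis-correlation estimator carries
per-pair noise of about 1/√n ≈ 0.07, so independent pairs concentrate
near zero individually (mean |r| ≈ 0.05) while the maximum over ~200
pairs is necessarily ≈ 0.2; validation therefore checks typical, not
maximal, null estimates. CLR + rmcorr edges are the alternative route
for taxon–host networks; CLR is applied within one taxonomic rank, with
zero replacement by half the smallest nonzero value only when zeros are
present.

## Trajectory clustering

Significant features (q < 0.1) are summarised by their corrected
category means over the ordered states (−H, EE, EL, RE, +H), z-scored
per feature (flat trajectories map to zeros; a missing category is
linearly interpolated from neighbours and flagged). Fuzzy c-means uses
fuzzifier m = 2, tolerance 1e-6 on the centre shift, at most 1000
iterations and a seeded centre initialisation; the objective is
non-increasing and membership rows sum to 1. The cluster count is
chosen at the maximum curvature (second difference) of the
hard-assignment SSE versus c, with the c = 1 SSE (distance to the
global centroid) anchoring the curve — the fuzzy objective itself is
not scale-comparable with a c = 1 anchor, and without an anchor c = 2
could never be selected. Clustering is performed jointly across omes by
default.

## Outlier profiles

Only subjects with ≥ 3 healthy visits enter; analytes missing or zero
in more than half the samples are dropped. Values are centred at the
subject's healthy median; the scale is the cohort sd of the centred
values (the centring is standard, the scale is our choice — a personal
scale would be too noisy with a handful of visits). Calls are one-sided
above the analyte's 95th percentile of the z distribution (a two-sided
option on |z| exists). Per-ome call counts are normalised by the ome's
analyte count, then rescaled to 100% per subject.

## Event classification

Event-early and event-late samples versus healthy baselines; healthy
points with HS-CRP > 10 are excluded when that lab is supplied (the
marker itself is never a feature). Features are standardized across
time points; multi-ome models concatenate the standardized blocks and
drop samples missing from any block. Splits are subject-disjoint at
~70/30 by time-point count; the l1 penalty C is selected from
{0.1, 0.5, 1, 2, 3, 5, 10} by 5-fold subject-aware validation error on
the training set only; logistic regression and a linear SVM are the two
model families. ROC areas are computed as the Mann–Whitney rank
statistic (identical to the trapezoid on the empirical ROC). The
variance-stabilizing transform sometimes used for transcript counts is
replaced by size-factor normalisation plus log2(x+1); this is a
documented simplification.

## The synthetic cohort generator

The generator emulates the sampling design of a multi-year
deep-phenotyping study: quarterly healthy visits (mean spacing 91 days,
jitter sd 10, configs that could produce non-positive gaps are
rejected), a Poisson number of events per subject (rate 1), event
visits at days {2, 5, 10, 21, 35} after onset (two early visits, one
late, two recovery — the dense early sampling of the design),
infection/immunization event types, and an insulin-resistant subgroup
(default 30% of subjects, SSPG ≥ 150 mg/dl) whose event responses are
multiplied by 0.5.

Feature values are built on a latent Gaussian scale — subject intercept
with variance σ²·ICC/(1−ICC), residual σ², plus piecewise-constant
stage shifts for responders — and mapped to each assay's raw scale so
the standard transform recovers the latent value exactly (exp for
intensities, 2^x − 1 for transcript counts). Null features therefore
satisfy the deviation test's Gaussian null exactly on the analysis
scale. Responder trajectory classes are {up-early, up-late, down-early,
down-late}; active stages carry the full effect size (up-early shifts
EE and EL by +δ, up-late shifts EL and RE, mirrored for down), matching
the piecewise-constant category-mean model of the test and keeping the
expected statistic computable in closed form. The default effect size
is 1 residual sd — the magnitude of real responses is unknown, so this
is a convention, not a calibration.

Microbiome layers draw correlated log-normal basis abundances (unit
variance, declared pairwise correlations, rejected if not jointly
positive definite), add subject intercepts on the log scale, close to
fractions and sample multinomially (default depth 20,000 for the cohort
matrices; the standalone compositional generator defaults to 1,000;
validation of SparCC recovery uses 10,000, a typical 16S library size).
The metabolome gets QC injections every 10 biological samples (a fixed
latent reference profile with 5% iid noise) and multiplicative
exponential run-order drift exp(coef·order), default coefficient
0.0015/injection. Missingness is injected completely at random on the
intensity omes (never on QCs), consistent with the kNN imputation
stage downstream.

**What the generator does not emulate:** batch effects other than
smooth run-order drift, non-Gaussian heavy tails, informative
missingness, uneven or spontaneous sampling, viral-load dynamics,
taxon-host feedback, or any sequence/spectrum-level structure. Passing
tests therefore establish correctness of the estimators under their
stated models and recoverability of planted effects — not robustness to
every pathology of real cohort data.

## Problem sizes used in validation

Null calibration uses 10,000 simulated events (20 subjects, 5 baselines
each, 2+1+1 stage samples); power uses 1,200 replicates per effect
size; ICC recovery uses 100 subjects × 6 visits × 50 features; SparCC
recovery uses 20 taxa × 200 samples; the end-to-end pipeline runs on a
50-subject cohort with ~390 features across seven omes. These sizes
give Monte-Carlo error comfortably below the tolerances being checked
while keeping the whole suite quick to run. The end-to-end
responder-recovery sensitivity is assessed on the intensity omes, where
"effect size 1σ" is defined on the analysis scale; compositional omes
run through the same pipeline but closure distorts latent effect sizes
non-linearly, so they are not counted in that sensitivity.

## Known limitations

- The deviation statistic treats σ̂ as known; with few baseline visits
  its null is t-like rather than exactly normal (quantified above).
- Sequential (type-I) attribution of fixed-effect variance depends on
  the covariate order; the order is fixed to the model formula's.
- SparCC's sparsity assumption fails for densely correlated
  communities; the exclusion heuristic mitigates but does not remove
  this.
- The elbow criterion for the cluster count is a heuristic; for flat
  objective curves it falls back to the smallest c with a warning.
- Subject-disjoint splitting can fail on tiny cohorts where a class is
  carried by a single subject; this is reported as an error rather than
  silently relaxed.
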