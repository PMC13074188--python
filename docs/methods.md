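# Methods

## Data model

Each primary study reports one 2×2 table (TP/FP/FN/TN) obtained by
dichotomising CSF heparin-binding protein (HBP, ng/mL) at a study-specific
cutoff, optionally annotated with categorical covariates (underlying
pathology, design, assay, reference-standard stringency). Raw counts are
integers and immutable; continuity-corrected counts are kept separately.
The default correction adds 0.5 to all four cells of any study containing
a zero cell (the convention of mainstream DTA software); `only-zero-cells`
and `always` modes are available because the convention used by any given
published analysis is rarely stated, and reproducing one may require
toggling the mode.

Study-level summaries are `y1 = logit(sens)`, `y2 = logit(FPR)` with
delta-method variances `v1 = 1/tp + 1/fn`, `v2 = 1/fp + 1/tn` on the
(corrected) counts.

## Bivariate random-effects model

`y_i ~ N(X_i beta, Sigma_b + diag(v1_i, v2_i))`. Assumptions: the two
disease arms are independent within a study (no within-study covariance);
between-study effects are bivariate normal on the logit scale. Variance
components are estimated by REML; maximum likelihood is used whenever
log-likelihoods must be compared across fixed-effect structures
(metaregression), since REML values are not comparable there.

Numerics: the objective is profiled — at each candidate `Sigma_b` the
fixed effects are the GLS solution — and optimised by Nelder–Mead over
`(ln tau1, ln tau2, atanh rho_b)`, which enforces positivity and
|rho_b| < 1 smoothly. REML surfaces for k ≈ 12 are often multimodal near
boundaries, so five deterministic starts (small/moderate/large tau,
positive/negative correlation) plus five seeded random starts are used and
the best optimum kept. `ln tau` is floored at −8; estimated taus below
1.5e−3 are reported as exact boundary zeros, and the between-study
correlation is reported as undefined (NaN) when either tau sits at that
boundary rather than fabricating a number. The optimizer is audited two
ways in the tests: against 100 random feasible points, and against an
exhaustive vectorised grid search over `(tau1, tau2, rho_b)` at 0.01
resolution, which must agree with the optimum to better than 1e−3 in
restricted log-likelihood.

Pooled sensitivity/specificity CIs are Wald intervals on the logit scale.
LR+/LR−/DOR point estimates are algebraic transforms of the pooled pair;
their 95% CIs come from 100,000 Monte-Carlo draws of the fixed effects
from `N(mu, vcov_fixed)` (percentiles 2.5/97.5), with the seed recorded in
every output. DOR ≡ LR+/LR− holds as an identity on unrounded values.
Cochran Q and I² are computed per axis by univariate inverse-variance
fixed-effect pooling of the logit outcome and are labelled descriptive:
the hierarchical model, not Q/I², is the inferential object.

Convention note: the threshold-effect correlation is reported as
`corr(logit sens, logit FPR)` (`rho_b`), alongside its sign-flipped
counterpart versus logit specificity. A cutoff-driven threshold effect
makes `rho_b` positive in this convention; published reports sometimes
quote the specificity convention, so both are serialized and diagnostics
should be read as |rho_b|.

## SROC curve and regions

The summary curve is the conditional-expectation line
`logit TPR = mu1 + (tau12/tau2^2)(logit FPR − mu2)`, the common default
for this model family; it is truncated to the observed FPR range by
default (an extrapolation flag exists). The 95% confidence region is the
chi-square(2) ellipse with shape `vcov_fixed` on the logit plane; the
prediction region uses `vcov_fixed + Sigma_b`. Ellipses are discretized at
360 points and mapped through the inverse logit, which is monotone per
coordinate and therefore preserves containment. A non-positive-definite
shape matrix triggers a 1e−10 ridge with a warning. With `tau2 = 0` the
curve degenerates to the horizontal line at the pooled TPR (warned).

## Subgroups and metaregression

Subgroup levels are refit independently by REML; levels with fewer than
three studies are skipped with a reason, never modeled. Metaregression
adds one covariate at a time to both mean components (df = 2 per binary
contrast, matching a single joint p-value per covariate) and compares ML
fits with a chi-square LRT. The chi-square reference is asymptotic and
anticonservative for very small corpora (k ≈ 12); the package's seeded
null-calibration test verifies near-nominal type-I error from k = 24
upward. Small-corpus metaregression p-values should therefore be read as
exploratory.

## Clinical utility

Fagan updating is exact Bayes on the odds scale. Display rounding is
half-up to whole percent — required to match convention for printed
nomogram values — with unrounded probabilities retained. Deeks' test
regresses ln DOR on `1/sqrt(ESS)`, `ESS = 4 n1 n2/(n1+n2)`, with weights
ESS and a two-sided t test on the slope at k − 2 df (standard small-sample
practice); asymmetry is flagged at p < 0.10, the conventional level for
this low-powered test. Zone classification is inclusive at both bounds:
value ≤ rule-out → rule-out, value ≥ rule-in → rule-in, else gray.

## Multiple-cutoff model

With one cutoff per study, study-level random effects are unidentifiable,
so the default is fixed-effects weighted least squares of
`logit(spec)` and `logit(1 − sens)` on `f(cutoff)`,
`f ∈ {identity, log, sqrt}`, with group sample sizes as weights (the
natural precision proxy here; an equal-weights option exists). The
combined AIC is computed from the joint weighted Gaussian likelihood of
both lines (6 parameters: two intercepts, two slopes, two error scales);
ties break toward log, the natural transform for a positive concentration
scale, and are logged.

The evaluation grid spans `[0.5·c_min, 1.2·c_max]` of the observed
cutoffs (2000 geometric points): decision thresholds frequently sit just
outside the observed cutoff range, and the extrapolated region is flagged
in every curve table. The Youden optimum is a grid argmax refined by
bounded scalar minimisation on the log-cutoff scale; the bootstrap CI
resamples studies (clusters) with replacement, refits the selected
transform, and takes percentile 2.5/97.5 over successful refits — more
than 20% failed refits marks the interval unstable. Rule-in/rule-out
cutoffs are bracketed sign changes of LR+ − target and LR− − target
refined by Brent's method; if a target is met across the whole grid the
corresponding grid edge is returned, if never met the threshold is
reported as "not achieved" rather than extrapolated; multiple crossings
are resolved toward the one nearest the Youden optimum and the
multiplicity is reported.

Gray-zone ordering (rule-out < rule-in) is *not* a mathematical
invariant: at the LR− = 0.1 crossing the fitted DOR may exceed 100, in
which case the LR+ ≥ 10 zone already overlaps the LR− ≤ 0.1 zone and the
three-tier scheme degenerates. The package reports whatever the fitted
curves imply.

## Synthetic data generator

The generator draws from a latent log-normal biomarker model: `ln HBP` is
normal in each disease group, study-level random shifts of the two group
means (bivariate normal, sds `tau_d`/`tau_nd`, correlation
`shift_correlation`) create heterogeneity, and each study dichotomises at
its own cutoff, so the threshold effect emerges mechanically from cutoff
variation. Truth curves are closed-form normal CDFs, giving analytic
oracles for every downstream stage.

Default calibration (`published_corpus_config`) emulates the corpus the package
targets: 12 single-center studies; per-study size log-uniform on 58–390
(study pools are right-skewed in size; a uniform draw would inflate the
expected total well above the ≈ 1800 patients being emulated); common
prevalence 841/1761 ≈ 0.478 (per-study prevalences are not available, a
simplification); cutoffs log-uniform on 14.96–92.5 ng/mL; group
parameters solved so that at 30 ng/mL population sensitivity is 0.86 and
specificity 0.85 (`sigma_d = 1.1`, `sigma_nd = 1.4`, wider spread in the
non-diseased group reflecting heterogeneous sterile inflammation);
`tau_d = tau_nd = 0.5` with shift correlation 0.5 (assay-calibration
differences move both group means together). These defaults yield
visibly heterogeneous forest plots and a between-study |rho_b| > 0.5 in
at least 90% of replicates (asserted, together with pooled-estimate
tracking of the truth at the median cutoff, by the generator-calibration
test). Studies whose
diseased or non-diseased group would fall below 5 subjects are redrawn to
avoid degenerate tables.

A second generator draws `(logit sens, logit FPR)` directly from the
bivariate normal for parameter-recovery experiments where the estimand
must equal the generating `mu` exactly, and a third draws counts from the
logistic two-line cutoff model.

The two-line truth is anchored on the decision thresholds the pipeline is
designed to estimate: coefficients `a_d = −7.4406, b_d = 1.5,
a_nd = −1.5252, b_nd = 1.0433` are the exact solution placing the Youden
argmax at 28.4 ng/mL, the LR+ = 10 crossing at 41.3, and the LR− = 0.1
crossing at 30.1, with monotone LR curves over 7.5–111 ng/mL. These three
anchors are jointly satisfiable, but no monotone two-line model can
additionally reproduce a Youden index above 0.83 at the optimum together
with both crossings above it (the implied LR values contradict
monotonicity), so J at the anchored optimum is 0.796; reported accuracy
figures of that magnitude are mutually inconsistent at the rounding level
and the anchors take precedence.

Recovery experiments scale both slopes by 0.7 about the 28.4 pivot (which
preserves the optimum and the accuracy pair there) and use 60 studies of
150–400 subjects with cutoffs over 5–150 ng/mL. Rationale: at the
unscaled slopes the fitted DOR at the rule-out crossing is ≈ 92, adjacent
to the DOR = 100 boundary where the gray zone collapses, so gray-zone
ordering is not identifiable from noisy replicates there; widening the
zone and the cutoff span, and enlarging the corpus, makes transform
identity and zone ordering properties of the data rather than of
sampling luck. Replicates are seeded, making every stochastic check
deterministic.

## What passing tests do and do not show

The generator reproduces the statistical structure the methods assume —
binomial within-study noise, logit-normal between-study heterogeneity, a
cutoff-driven threshold effect, a pathology-like moderator in the
analysis corpus — but not reference-standard misclassification,
assay-platform shifts in absolute concentration, two-gate spectrum bias,
or per-study prevalence variation. Calibration results (bias, CI
coverage, type-I error) therefore certify the estimators under the
model's own assumptions, not robustness to those violations.

## Problem sizes

Defaults: 100,000 Monte-Carlo draws for LR/DOR CIs; 1000 bootstrap
resamples (500 in the acceptance script); 2000-point evaluation grids.
Simulation studies in the test suite use 200 replicates (2000 for the
funnel-test calibration, where each replicate is a single weighted
regression), sizes chosen to keep Monte-Carlo error well inside the
asserted bands.

## Known limitations

* One cutoff per study: the cutoff model cannot separate within- from
  between-study variability (fixed-effects WLS only; a random-intercept
  variant would need multi-cutoff inputs).
* k = 12 sits near the lower stability boundary of the bivariate model;
  subgroup fits on 3–8 studies are exploratory by construction.
* Wald CIs on the logit scale and chi-square LRTs are asymptotic; the
  recovery tests assert coverage only within a 90–99% band at k = 12, and
  LRT calibration only from k = 24 upward.
* The sign convention for the threshold-effect correlation differs across
  software; compare |rho_b| across reports, not signed values.
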