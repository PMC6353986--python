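# Methods

## The poolability question

A multi-site study that wants to publish a single international standard for
a developmental outcome must first show that site membership explains little
of the outcome's variance and that no site's adjusted mean sits far from the
pooled mean. `sitepool` operationalises that with three linked analyses —
between-site variance fractions from random-intercept models, standardised
site differences against an equivalence band, and Monte-Carlo power — all
driven by a synthetic cohort generator whose ground truth is known, so every
estimator can be checked for recovery rather than against unavailable study
data.

## Synthetic cohort generator

The generator emulates a five-site 2-year follow-up: site sizes
(199, 318, 311, 311, 168), 47.7% boys, and assessment ages from a Normal
fitted to the reported median/IQR (mean 24.2, SD = IQR width / 1.349 ≈ 0.96
months) truncated to the 22–30-month assessment window by rejection
sampling. Each of 16 outcomes (7 primary domains, 7 secondary domains, two
milestone ages) follows

    y = grand_mean + beta_age·(age − 24) + beta_sex·1[boy] + u_site + eps,

with `Var(eps) = sigma2_within` and the site effect drawn from a Gaussian or
a discrete (mass-point) family scaled so the between-site share of total
variance equals a per-domain target. Default targets span 1.3%–14.2%, the
range observed for these domains in practice. Published sources do not fix
the score scales of the underlying instrument, so `grand_mean = 50` and
`sigma2_within = 100` are arbitrary scale choices (milestone ages instead
use ~11 and ~13 months with within-site SDs of 1.5 and 1.8 months, typical
attainment windows, and no dependence on assessment age). Growth covariates
are drawn as z-scores: fetal head circumference (0, 1); 2-year length
(−0.15, 1.00), head circumference (0.13, 1.08), weight (0.23, 1.05).
Missingness is completely at random per cell at a configurable rate.

Two features matter for testing. First, with only five sites the realised
variance of five Gaussian draws is itself highly variable, so
`fix_site_effects=True` replaces the draws with distribution quantiles at
probabilities (i − 0.5)/m, re-centred and re-scaled so the *sample* (n−1)
variance of the realised effects equals the target `sigma2_between` exactly
— this is the estimand of REML/ANOVA for a fixed, realised set of sites, so
recovery tests have an exact truth. Second, discrete supports supplied by
the user are affinely rescaled to mean 0 and the target variance, keeping
the percent-between target meaningful for any support.

What the generator does **not** emulate: item-level responses and
ceiling/floor effects of the psychometric instrument, non-Gaussian residual
shapes, informative missingness, correlation between domains, and
site-specific covariate distributions. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to real-data violations of it.

## Covariate adjustment and SSD

Adjusted scores come from a single pooled least-squares fit
`outcome ~ 1 + (age − 24) + 1[boy]` on complete cases; the adjusted value is
the residual plus the prediction at age 24 and the pooled boy-fraction
(marginal standardisation). A pooled model is deliberate: per-site
adjustment would absorb the site differences under study. Residual-based
adjustment (rather than stratified means) is this package's interpretation
of "means adjusted by sex and age". Constant covariate columns are dropped
from the design, so degenerate samples (single sex, single age) reduce to
intercept-only adjustment and leave scores unchanged; a genuinely singular
non-constant design raises a collinearity error. The pooled SD is the n−1
SD of adjusted child-level values over all sites together — not a mean of
per-site SDs — and per-site SDs with n = 1 are reported as missing.

SSD_i = (site mean − pooled mean)/pooled SD. The equivalence band is closed:
|SSD| ≤ 0.5 counts as adequate, matching the convention that only values
strictly beyond ±0.50 are "outside". SSD adjusts for age and sex only (not
the growth covariates), matching the definition of the site-comparison
display it implements. A (domain, site) cell with no complete cases is
dropped and logged, not an error. Item-set membership is configuration; the
default assigns the 7 primary domains + 2 milestones to the primary set and
the 7 language/behaviour domains to the secondary set, giving 45/35/80
comparisons at five sites.

## Gaussian random-intercept fits

For a single random intercept the (restricted) likelihood depends on the
variances only through `lambda = sigma2_b/sigma2_w`. For fixed lambda the
GLS fixed effects, the quadratic form Q(lambda), and hence the profiled
objective are closed-form via per-site sufficient statistics (site sizes,
site sums of y and X, and cross-products), costing O(p²·m) per evaluation.
The profile is scanned on {0} ∪ logspace(−8, 6, 141) and refined by bounded
Brent search (xatol ~1e-13 relative), with the lambda = 0 boundary checked
explicitly; `sigma2_b` is therefore exactly 0 at the boundary, never
negative. This hand-profiled fitter was chosen over a general mixed-model
optimiser for boundary exactness, ~1e-7 agreement with the balanced one-way
ANOVA closed form, and speed (hundreds of fits in the recovery suites);
statsmodels' MixedLM serves as an independent cross-check in the tests, not
as the implementation. ML reports the exact multivariate-normal
log-likelihood; REML reports the standard restricted objective, and its
AIC/BIC are flagged not comparable across fixed-effect sets
(`criteria_comparable=False`); `compare_models` refuses such comparisons.
Model degrees of freedom: p_fixed (incl. intercept) + 2.

## NPML mass-point fits

The marginal likelihood over sites,

    L = prod_i sum_k pi_k prod_j phi(y_ij − x_ij'beta − theta_k; sigma2_w),

is maximised by EM. E-step: posterior responsibilities r_ik from per-site
residual sums and sums of squares (so each iteration is O(m·K + N p²)).
M-step: joint weighted least squares for (beta, theta) — because
responsibilities sum to one over k, the beta block of the normal equations
is the unweighted X'X and only the cross terms carry weights — then
responsibility-weighted updates for pi and sigma2_w. The intercept is
excluded from X during EM (theta carries the level); afterwards the
pi-weighted mean of theta is moved into the intercept and the locations are
re-centred to mean 0, so `sigma2_between` is the centred mass-point
variance. The log-likelihood is checked to be non-decreasing at every
iteration and a decrease raises an estimation error.

Numerical policy: convergence when the relative log-likelihood change
< 1e-8 **and** the maximum parameter change < 1e-6, capped at 2000
iterations; three successive sub-tolerance likelihood changes without
parameter convergence return a converged-with-warning status. Locations
closer than 1e-4 × (range of site-mean residuals) are merged
(mass-weighted). Starts: theta at the K quantiles of per-site mean OLS
residuals with uniform masses, plus 4 jittered starts (seeded,
sd = 0.5 × SD of site means); the best final likelihood wins, making fits
deterministic given `start_seed`. With K = 1 the M-step is a single exact
OLS solve, so the fit equals the fixed-effects-only Gaussian model to
floating precision. `K='auto'` fits K = 1..m and selects by BIC (AIC by
flag); degrees of freedom are p_covariates + 1 (sigma2_w) + (2K − 1), the
2K − 1 counting K locations and K − 1 free masses with the mean location
absorbed into the intercept. BIC is the default because the mass-point
dimension is a model-selection problem where the conservative criterion is
the safer default. Only identity-link Gaussian outcomes are supported: all
outcomes here are continuous scores.

With five sites the random-effect distribution is weakly identified (the
module warns below 10 sites); the variance fraction remains well defined and
is the reported quantity.

## Power simulation

Balanced one-way layouts with total variance 1 and the target between-site
share; site effects are redrawn every replicate — with few sites they
dominate the Monte-Carlo variability, and that is the honest design noise.
Both test statistics come from closed forms (for the balanced layout the ML
estimates are SSW/(N−a) and SSB/a, with the boundary case pooling to
SST/N), so no iterative fitting is needed and 2000 replicates take well
under a second. All replicates derive from one seeded stream of standard
normals scaled by the target variances, so calls sharing a seed share their
randomness — power curves over a grid use common random numbers and are
monotone in the effect.

The F test is exact under the null at any design. The chi-bar-square
reference (0.5·chi2(0) + 0.5·chi2(1)) for the boundary LRT is asymptotic in
the number of sites: at 5 sites the probability that the unconstrained
optimum is infeasible (LRT = 0) is P(chi2_4/5 < chi2_{N−5}/(N−5)) ≈ 0.71
rather than 0.5, so the mixture under-rejects (measured size ≈ 0.015 at
alpha 0.05) — conservative, never anti-conservative. Size-control checks
therefore use the F test at the 5 × 261 study design and the LRT at a
many-site design (500 sites × 4, measured size ≈ 0.048) where its
asymptotic regime applies. No claim is made of reproducing any particular
published post-hoc power figure: the published procedure (test statistic,
whether site effects were redrawn) is unspecified, and a naive balanced
F-test power at these sizes is far higher than typical printed values.

## Flow accounting

Pure integer arithmetic with validation (no stage exceeds its parent;
analysed = assessed − medical exclusions, derived when omitted) and half-up
rounding to one decimal for percentages, computed in decimal arithmetic so
ties never fall to floating-point representation. The shipped study flow
contains one known printing discrepancy: 1128 of 1307 children assessed in
the 22–26-month window computes to 86.3% although the source narrative
prints 86.4%; the computed value is reported.

## Problem sizes

The test suite and acceptance script run the full 1307-child, 16-domain
pipeline directly; recovery suites use 200 replicates of the 5 × 261 design
(REML fits cost ~10 ms each via the profiled likelihood); power estimates
use 2000 replicates. The whole suite completes in well under a minute on a
single CPU.

## Known limitations

* One random intercept only: no nested/crossed structures, no site-specific
  residual variances, no non-identity links.
* The NPML likelihood is multimodal; multi-start EM reduces but cannot
  eliminate the risk of a local maximum, and with five sites K > 2 is rarely
  supported by BIC.
* SSDs are reported without confidence intervals, and the ±0.5 band is a
  fixed convention, not a formal equivalence test.
* The generator's independence assumptions (across domains and between
  outcomes and covariates) make multi-domain summaries optimistic relative
  to correlated real data.
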