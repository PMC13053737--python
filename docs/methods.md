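# Methods

## The scientific problem

Socioeconomic status (SES) robustly predicts physical functioning in old age,
but the association may be causal, genetically confounded (genes influence
both SES attainment and aging), or confounded by the rearing environment.
Twins provide a natural experiment: co-twins share their rearing environment
and either all (MZ) or on average half (DZ) of their segregating genes.  The
package implements the co-twin control version of a longitudinal growth
model: SES enters as a pair mean (between-family) and a member deviation
(within-family), and the attenuation pattern of the within-pair effect across
zygosity groups separates the three explanations.

## Outcome: the Functional Aging Index (FAI)

Four components per visit: grip strength (regression-adjusted for sex on the
baseline reference), peak expiratory flow (divided by height in metres
squared), gait time, and a sensory component (self-rated vision and hearing
each z-scored and averaged).  Each component is z-scored against baseline
(first visit per person) means and SDs; grip and PEF z-scores are reversed so
higher always means poorer.  The composite is the unweighted mean of the
available component z-scores, requiring at least `min_components` (default 3
of 4) and otherwise missing.  The composite is then re-standardized against
the baseline composite distribution and mapped to T-scores, 50 + 10 z, so the
baseline reference is exactly mean 50 / SD 10 and follow-up waves are scored
on the frozen baseline metric.  Re-standardizing the *composite* (rather than
relying on the average of component z-scores) keeps the T-scale anchored to
the composite's own distribution; the alternatives differ only by a positive
affine map, which none of the downstream analyses would notice, but the
anchoring makes the T units interpretable.  Standardization parameters are
serializable to YAML so later waves can be scored without re-estimation.

Choices the construction leaves open, and what this package does: the
baseline reference is the pooled first visit of every person (a per-study
option would be a one-line change in `fit_standardization`); gait is treated
as time-to-walk (higher = poorer, no reversal) and the orientation is
configurable via `reverse_flags`; the two sensory self-reports are collapsed
into one component before composite formation so the index has exactly four
components.

## Financial strain

Four ordinal items, oriented so higher = more strain, summarized by a
single-factor maximum-likelihood model on standardized items (estimated with
scikit-learn's `FactorAnalysis`; loadings sign-fixed to a positive sum;
uniquenesses floored at 0.005 with a Heywood flag).  Individual scores use
the regression (Thomson) method restricted to each respondent's observed
items — the posterior mean of the factor under the fitted Gaussian model
given whatever items were answered — and are then mapped to mean 50 / SD 10
within each declared study sample.  Scoring from the observed-item submodel
is exactly Gaussian conditioning, which the test suite verifies against a
generic conditional-expectation computation.

## Growth model

Let t = (age − 75)/10, s1 = min(t, 0), s2 = max(t, 0).  The outcome for
member m of pair p at visit j is

    y_pmj = x_pmj' beta + z_pmj' b_p + z_pmj' c_pm + e_pmj

with pair-level effects b_p ~ N(0, G_P), individual effects c_pm ~ N(0, G_I)
over a configurable subset of {intercept, s1, s2}, and residuals
e ~ N(0, sigma^2).  The intercept is the expected level at age 75; slopes
are change per decade before/after 75.  Fixed effects typically include
intercept, s1, s2, a male indicator, optionally parental SEI, and SES terms
(raw, or between/within, optionally interacted with s1/s2).

Estimation is exact maximum likelihood.  G_P and G_I are log-Cholesky
parameterized (diagonal of the Cholesky factor on the log scale), which
keeps them positive semi-definite without constraints; sigma is a log
parameter.  Fixed effects are profiled out by GLS inside the variance
optimization (quasi-Newton, L-BFGS-B, gradient norm tolerance 1e-6).  For
speed, pair blocks are zero-padded to a common size with unit variances on
the padded diagonal — padded rows then contribute exactly nothing to the
log-determinant or any quadratic form — so the whole likelihood evaluates as
one batched Cholesky/solve over an (n_pairs, n_max, n_max) array.  The test
suite verifies this block likelihood against a dense single-covariance
assembly to 1e-10 relative, against a derivative-free dense optimizer at the
optimum, and against statsmodels MixedLM's log-likelihood at MixedLM's own
estimates.

ML rather than REML is the default because the model comparisons are
fixed-effect likelihood ratio tests, which are invalid under REML.  Wald
p-values use a normal reference — samples here are large enough (thousands
of observations) that t-type small-sample corrections are immaterial, and no
principled residual df exists for this two-level design anyway.  Singleton
persons (incomplete pairs) are retained in phenotypic models with pair- and
individual-level effects of their own, whose variances simply add in the
marginal covariance.  Rows with a missing outcome or covariate are dropped
listwise (MAR assumed).  On non-convergence the random structure falls back
unstructured → diagonal → intercept-only, and the fallback path is recorded
in the `FitResult`.

The LRT statistic is 2(l_full − l_null) on ML fits of the same rows,
compared to chi-square with df = the parameter-count difference.

## Co-twin decomposition and the confounding classification

For complete pairs, between = pair mean of the SES value and within = member
value − pair mean (the within values of a pair sum to zero and the parts
reconstruct each member exactly).  Both enter the growth model as covariates
of the intercept and/or slope 1; models run on the full co-twin sample and
separately per zygosity.  The MZ-vs-DZ comparison of within effects uses
z = (w_DZ − w_MZ)/sqrt(SE_MZ² + SE_DZ²) with both estimates sign-aligned to
the full-sample between estimate so the statistic is invariant to reversing
the SES variable's direction; a joint model with a zygosity × within
interaction gives an equivalent comparison when the strata are balanced.

The published decision logic is verbal; the classifier makes it reproducible
with explicit thresholds on the attenuation ratio r_g = within_g/between_g:

1. within significant in both strata and r_MZ, r_DZ ≥ 0.7 → consistent
   with causation;
2. within_MZ non-significant AND (the MZ-vs-DZ z exceeds 1.645 one-sided OR
   r_MZ < 0.3) while r_DZ ≥ 0.7 → genetic confounding;
3. within non-significant in both strata and |r_MZ − r_DZ| < 0.2 → shared-
   environment confounding;
4. otherwise indeterminate.

All cutoffs are `Thresholds` fields; a `low_power` flag is set when a
stratum's within SE exceeds its between estimate.  Every verdict carries the
evidence needed to replay the rule.

Sex-interaction models add male × between and male × within terms on the
intercept only (no sex differences in slopes are modelled), so the base
coefficients are the women's estimates and the interactions are the
corrections for men.

Twin correlations are double-entry Pearson correlations (each pair
contributes both orderings, making the estimate order-invariant), and the
Falconer point decomposition is a² = 2(r_MZ − r_DZ), c² = r_MZ − a²,
e² = 1 − r_MZ, truncated to [0, 1] and renormalized with a boundary flag
when the raw solution is inadmissible.  Fisher's z test compares independent
correlations.

## The twin simulator and its oracle

Per pair: latent A (correlation 1 within MZ, 0.5 within DZ), C (shared), E
(independent), all unit variance.  Observed SES = mean + sd(aA + cC + eE)
with (a², c², e²) the configured ACE shares.  Each person's intercept is
mu + beta_sex·male + delta·SES_latent + kappa_a·A + kappa_c·C + pair and
individual random intercepts; slope 1 has its own optional cross-paths;
slope 2 is unconfounded by default.  Visits follow a shared per-pair
schedule: baseline age uniform on 42–93, waves 2–4 years apart, monotone
per-wave attrition (default 0.3, giving a mean near 3.3 waves and follow-up
spans up to about 27 years).  Default pair counts are 142 MZ and 371 DZ with
about half the DZ pairs opposite-sex; an MZ-free, all-opposite-sex cohort is
a configuration choice, which the reporting layer handles by skipping the MZ
stratum with an explicit note.  Biomarkers (grip, PEF, gait, sensory
self-reports) are derived from the latent trajectory with measurement noise
so the FAI pipeline can run end to end; measurement noise in the outcome
attenuates nothing downstream except by inflating residual variance, and
attenuation *ratios* are unaffected.  Ordinal SES variants (education-like
9-level codes, parental occupation classes, strain items) are thresholded
from the relevant latent variables with marginals resembling an older
Swedish cohort.

Closed-form projections serve as the analytic oracle, in T units per latent
SES SD:

    within_MZ  = delta
    within_DZ  = delta + kappa_a a / (a² + 2e²)
    between_MZ = delta + (kappa_a a + kappa_c c) / (a² + c² + e²/2)
    between_DZ = delta + (0.75 kappa_a a + kappa_c c) / (0.75 a² + c² + e²/2)

The first identity is the design's inferential core: MZ within-pair
contrasts carry no A or C variance, so the within-MZ coefficient estimates
the direct path under any confounding.  The simulator's correctness gate is
agreement of empirical between/within OLS coefficients with these formulas
within Monte-Carlo error on large single-wave cohorts.

Scenario presets fix the three generating mechanisms at comparable marginal
effect sizes (about 2–3 T units per SES SD, the scale of the strongest
published SES–level associations): `causal` (delta = 2), `genetic`
(kappa_a = 2 with a high-heritability SES, a² = 0.6), and `shared_env`
(kappa_c = 4 with a high-c² SES, c² = 0.4).  Each mechanism is placed in the
biometrical regime where it can operate — shared-environment confounding of
an SES with c² near zero is not a representable data-generating story.

## What the simulator does not emulate

Mortality- or outcome-dependent dropout (attrition is independent of the
outcome); measurement invariance problems across studies; dominance,
assortative mating, or gene–environment interaction in SES; age trends in
SES itself; and SES measurement error as a separate construct — the e²
share absorbs both unique environment and measurement error, exactly as the
twin-correlation arithmetic conflates them.  Passing tests therefore show
the estimators and decision rule work when the model class holds, not that
the model class describes any particular registry.

## Problem sizes and numerical tolerances

Test-suite experiment sizes: fixed-effect recovery uses 500 replicates of
1000 pairs × 4 waves (bias < 0.02 outcome SD, Wald 95% coverage within
[0.93, 0.97]); LRT null calibration uses 1000 replicates of 200 pairs × 2
waves (df = 3 rejection rate within the 95% binomial band around 0.05);
verdict recovery uses 20 replicates per scenario at 2000 pairs per zygosity
(≥ 90% pooled recovery); oracle agreement uses 10⁵ single-wave pairs per
zygosity (within 3 MC SEs).  `scripts/acceptance.py` re-runs the same
experiments at 150 / 400 / 12-per-scenario replicates and 5·10⁴ pairs —
sizes chosen so a complete from-scratch rerun stays inexpensive while every
Monte-Carlo margin remains comfortably wider than the quantity's drift.

Dense-vs-block likelihood agreement is asserted at 1e-10 relative (pure
linear algebra), brute-force optimum agreement at 1e-4 relative (two
optimizers), FAI baseline moments at 1e-8 (exact by construction up to
floating point).  Convergence is declared at gradient norm < 1e-6; the
optimizer caps at 500 iterations and negative LRT statistics beyond
tolerance raise rather than clip silently.

## Known limitations

The between/within growth model treats the SES decomposition as fixed
regressors (no measurement-error correction; with low within-pair SES
variance the within estimates are noisy, which the low-power flag surfaces).
The Falconer solver is a point arithmetic, not a likelihood — it reports
boundary solutions but no uncertainty.  The classifier is a threshold rule
on point estimates and inherits their sampling noise; at a few hundred pairs
per zygosity its verdicts are unreliable and it will often (correctly)
return indeterminate.  REML is not implemented; fits are ML throughout.
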