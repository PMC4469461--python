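# Methods

## The estimation problem

`ivmr` implements two-sample Mendelian randomization (MR) for a
continuous (or binary) exposure and a binary outcome, using only
per-SNP summary statistics from two GWAS.  Genetic variants associated
with an exposure are used as instrumental variables: because alleles are
randomly assorted at meiosis, a variant that raises the exposure should
raise (or lower) the outcome risk only through the exposure, free of the
confounding and reverse causation that afflict observational
associations.  The motivating application is the analysis of modifiable
risk factors (blood pressure, lipids, glycemic traits, adiposity,
smoking, education) for Alzheimer disease, where instruments come from
large trait consortia and outcome associations from a case-control GWAS
meta-analysis.

## Estimators

For instrument *j*, let β̂_Xj (SE σ_Xj) be the per-allele exposure
effect and β̂_Yj (SE σ_Yj) the per-allele outcome log odds ratio, both
expressed on the same allele after harmonization.  The per-SNP Wald
ratio is θ̂_j = β̂_Yj / β̂_Xj with first-order delta-method standard
error σ_Yj / |β̂_Xj|; the exposure-side sampling variance is ignored, as
is standard when instruments reach genome-wide significance in very
large GWAS (the neglected term is O((σ_Xj/β̂_Xj)²), about 1% here).

The fixed-effect inverse-variance weighted (IVW) estimate is

    θ̂ = Σ_j w_j β̂_Xj β̂_Yj / Σ_j w_j β̂_Xj²,
    se(θ̂) = (Σ_j w_j β̂_Xj²)^(-1/2),   w_j = σ_Yj⁻²,

algebraically identical to the precision-weighted mean of the Wald
ratios and to the zero-intercept weighted least-squares slope of β̂_Y on
β̂_X.  Confidence intervals use the fixed multiplier 1.959964 and
p-values are two-sided normal; no small-sample correction is applied
because SNP-level standard errors come from sample sizes in the tens of
thousands.  Random-effects IVW, MR-Egger, median- and mode-based
estimators are deliberately out of scope.

Estimates are expressed per analysis unit of the exposure (one SD for
continuous traits, one log-odds unit for binary traits).  Each
instrument set carries `unit_scale`, the number of natural units per
analysis unit (e.g. 15.4 mm Hg per SD of systolic blood pressure), so an
estimate can be rescaled to any natural-unit difference: rescaling by a
factor *k* multiplies β and SE by *k* and recomputes OR/CI/p.  Rescaling
composes multiplicatively and leaves a null OR of exactly 1 unchanged.

Cochran's Q with fixed-effect weights provides the heterogeneity test,
applicable across per-study causal estimates or across per-SNP ratios;
its p-value is the upper χ² tail on (count − 1) degrees of freedom.

## Harmonization

Summary tables from different consortia may report effects on different
alleles and strands.  The outcome effect is sign-flipped when its effect
allele matches the exposure's other allele, directly or after strand
complement; irreconcilable allele sets are an error.  Both effects are
then jointly re-oriented so the exposure effect is non-negative — the
reported direction is "per exposure-raising allele", matching how
genetic risk scores are described.  Orientation never changes standard
errors, and a joint relabelling of both input records is an involution
(property-tested).

Palindromic variants (A/T, C/G) are their own strand complement, so
labels alone cannot resolve strand.  When both tables carry an
informative effect-allele frequency the variant is aligned by frequency
concordance (same side of 0.5 ⇒ same allele).  When either frequency is
missing or falls in [0.42, 0.58] — a symmetric near-0.5 window where
frequency carries no strand signal — the pair is flagged ambiguous and
excluded from estimation by default, with the exclusion count reported.
The window is a conservative convention; sensitivity of results to it
can be probed by re-harmonizing with a different window.

LD pruning to an approximately independent instrument panel is greedy:
variants are visited in ascending exposure p-value (ties broken
lexically by rsid) and kept iff their r² with every kept variant is
below the threshold (default 0.01).  Pruning is by statistical
correlation only; genomic coordinates are never required.

## Sensitivity analyses

*Pleiotropy screen.*  Instruments whose outcome association is stronger
than expected by chance are candidate pleiotropic variants.  The
threshold is α / N with N the number of unique SNPs across **all**
instrument sets analysed (a cross-set quantity passed by the caller —
302 in the motivating analysis, giving 0.05/302 ≈ 1.7 × 10⁻⁴), not the
size of the current set.  The screen partitions the set exactly;
estimation on the retained part gives the sensitivity estimate, and the
combined report leaves sensitivity columns blank exactly when nothing
was excluded.

*Leave-one-out.*  The IVW estimate is recomputed with each instrument
excluded in turn; the OR range over exclusions shows whether a single
variant drives the result.

*Scatter outliers.*  Each SNP's outcome effect is compared with the
value predicted by the overall causal slope and standardized by its
outcome SE.  |z| > 3 flags a variant.  The numeric rule is this
package's own: visual inspection of effect-size scatter plots does not
make a testable artifact, and three SEs is the conventional choice; under
normality the per-SNP false-flag rate is ≈ 0.27% (verified by
simulation).

*QQ statistics.*  Observed −log₁₀ p-values against (i − 0.5)/n
plotting-position quantiles of the uniform null.  A display floor
(default 10⁻³⁰) truncates only plotted copies — extreme APOE-region
p-values would otherwise dominate the axis — never the values used in
any decision.

## Genetic score analyses

Unweighted allele scores sum exposure-raising-allele dosages per
individual; dosage columns counting the opposite allele are reflected as
2 − dosage.  Missing genotypes are skipped, not mean-imputed, and the
per-individual count of contributing SNPs is exposed so users can filter
(the score of a merged SNP set is the sum of subset scores, which
mean-imputation would break).

Score-trait associations use ordinary least squares (optionally on the
SD-standardized outcome) or logistic regression fit by Newton/IRLS
(convergence 1e-8 on the coefficient max-norm, at most 100 iterations;
separation and non-convergence are reported as estimation errors, rank
deficiency as a configuration error).  Fits are delegated to
statsmodels; the reported quantity is the score coefficient with a
normal-approximation p-value.  Categorical covariates are expanded to
reference-coded dummies.  Stratified fits run independently per stratum
with per-stratum failure isolation.  Quartile summaries assign
boundary ties to the lower bin for determinism.  Observed outcome values
are used as-is; in particular blood-pressure-style outcomes are not
adjusted for treatment.

## Synthetic cohorts

The generator draws independent SNPs G_ij ~ Binomial(2, maf_j), a
standard-normal confounder U, exposure
X = Σ γ_j G_j + δU + ε (ε ~ N(0, σ_ε)), and outcome
Y ~ Bernoulli(logistic(b₀ + θX + Σ_{j∈P} α_j G_j + φU)) with P the
pleiotropic subset.  The outcome is generated on the log-odds scale
directly (not via a liability threshold) so that θ is an exact log-odds
parameter and recovery targets are unambiguous.  Optional case-control
subsampling to stated counts mimics outcome-GWAS designs; per-allele
logistic coefficients remain log odds ratios under outcome-dependent
sampling.

Default parameters are chosen to resemble the motivating setting: minor
allele frequencies uniform on (0.1, 0.5); per-allele exposure effects γ_j
uniform on (0.05, 0.15) SD-scale units, so a 15–30-SNP panel explains
roughly 6–13% of exposure variance (typical of blood-pressure or lipid
scores); unit exposure noise; baseline log-odds −2 (≈12% outcome
prevalence); confounder loadings δ = φ = 0.5 in the confounded scenario;
direct outcome effects α = 0.3 on 20% of SNPs in the pleiotropic
scenario, large enough (≈6 outcome SEs at n = 10,000) for the Bonferroni
screen to detect.  Scenario presets fix these choices and their seeds:
`null` (θ = 0, nothing else), `causal` (θ = −0.3, n = 20,000, 30 SNPs),
`confounded_null` and `pleiotropic` (both θ = 0, n = 10,000, 15 SNPs).

The SNP panel (frequencies, alleles, effects) is a pure function of the
configuration seed, while individual-level draws take an optional
separate seed.  Replicated studies exploit this to draw an exposure
cohort and an *independent* outcome cohort from the same panel — a
faithful two-sample design that avoids the weak-instrument bias toward
the observational association that one-sample designs incur.  Summary
statistics are produced the way consortia produce them: per-SNP simple
linear regression for the exposure, per-SNP univariate logistic
regression for the outcome, observed allele frequencies, and two-sided
normal p-values (floored at 1e-320 to stay in the open unit interval).
The per-SNP logistic scans use a small vectorized Newton solver that
fits all SNPs simultaneously (thousands of independent two-parameter
models per replicate); it is tested to 1e-8 agreement against
column-by-column statsmodels fits.

What the generator does **not** emulate: linkage disequilibrium between
instruments (LD pruning is exercised on synthetic r² matrices directly),
population stratification, survival/selection bias, and
non-collapsibility-free effect transfer — because the outcome model is
logistic, the marginal per-allele GWAS coefficient is attenuated by a
few percent relative to θγ_j (non-collapsibility over the residual
linear predictor), and estimated exposure effects add a ~1% regression
dilution.  Under the causal preset these compress the recovered effect
by roughly 4–5%, which the recovery checks absorb within Monte-Carlo
error; passing them shows calibration under this generating model, not
under real LD structure or selection.

## Replication scale and determinism

Calibration checks use 200 replicates (recovery, coverage, screen
utility) or 500 replicates (type-I error) at the preset sample sizes;
module-level tests use scaled-down replicate counts of the same studies.
At these scales the type-I-error estimate itself has a binomial SD of
about 0.01, so individual seeded runs scatter accordingly.  Every
stochastic quantity in the package is a pure function of (inputs, seed):
replicate streams are spawned from a root `SeedSequence`, hypothesis
profiles are derandomized, and pipeline outputs are byte-reproducible
(the run log carries versions, seed, thresholds and exclusion counts but
no timestamps).

## Known limitations

Only the fixed-effect IVW estimator is provided; pleiotropy-robust
estimators (Egger, weighted median/mode) and multivariable MR are out of
scope, as are proxy-SNP discovery, liftover, multi-allelic variants and
indels.  The pleiotropy screen can only detect direct outcome effects
large relative to the outcome SE; balanced or weak pleiotropy passes it.
Binary exposures are consumed in log-odds units and reported per unit
log-odds without conversion to prevalence differences.
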