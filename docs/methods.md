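# Methods

This note documents the statistical models `toxgwas` implements, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## The screen being modelled

The target design is a toxicant-susceptibility screen of an inbred-line
panel: each line is scored in both sexes, at a sex-specific discriminating
dose, in four replicate vials of 15–20 flies, and the response is the
proportion surviving a 24-hour exposure. Because lines are (near-)isogenic,
among-line variance is genetic variance, and the line-by-sex interaction
captures genetic variation in sexual dimorphism.

## Phenotypes

Replicates are pooled per line × sex by summing counts:
p = Σ survived / Σ exposed, N = Σ exposed, SE = √(p(1−p)/N). Count-weighted
pooling is the default (a replicate-averaging alternative is available)
because the SE formula is defined on total N; with equal replicate sizes
the two coincide. The LD50 is the dose where linearly interpolated survival
crosses 0.5, between bracketing doses only — a deliberate minimal estimator
for range-finding data; no probit/logit fit is attempted. The
discriminating dose maximizes among-line variance subject to mean survival
within ±0.2 of 50% (ties, to a relative tolerance of 1e-9 on the variance,
break toward the mean nearest 0.5).

## Variance components

The full model is Y = μ + L + S + L×S + ε with L and L×S random and S
fixed; reduced models Y = μ + L + ε are fitted per sex. Phenotypes are
analyzed untransformed, as proportions (or latent values in simulation).

Estimation is REML by direct maximization of the restricted log-likelihood
over (σ²_L, σ²_{L×S}, σ²_ε) with non-negativity bounds. The marginal
covariance is block-diagonal by line — observations from different lines
are independent — so the likelihood is accumulated per line block (at most
2 × replicates observations each). This makes a 204-line fit a few tens of
milliseconds and is exact, not an approximation. For balanced designs the
ANOVA expected-mean-squares estimators

    σ̂²_ε  = MS_error
    σ̂²_LxS = (MS_LxS − MS_error) / r
    σ̂²_L  = (MS_L − MS_LxS) / (s·r)

are the REML optimum whenever they are interior, and are used as the
optimizer start; the test suite asserts agreement to 1e-6 relative.
Negative method-of-moments solutions are clamped at zero and flagged.
Method of moments is refused on unbalanced data; REML handles it natively.

Derived statistics:

* H² = (σ²_L + σ²_{L×S}) / (σ²_L + σ²_{L×S} + σ²_ε); per-sex H² uses the
  reduced-model components.
* r_GS = σ²_L / (σ_LF σ_LM): the full-model among-line variance estimates
  the between-sex covariance of line effects, each reduced-model line
  variance the per-sex genetic variance. Sampling noise can push r_GS
  outside [−1, 1]; it is reported as computed and flagged.
* The r_GS standard error is a leave-one-line-out jackknife — a
  distribution-free choice that is directly testable; on balanced data the
  jackknife refits use the (equivalent) closed-form solution for speed.
* The fixed sex effect is tested with F = MS_S / MS_{L×S} on
  (s−1, (l−1)(s−1)) df in the balanced case (the interaction mean square is
  the correct denominator when lines are random), falling back to a GLS
  Wald z-test otherwise.

## Association

Genotypes are homozygous-inbred coded 0/2 so the regression coefficient is
a per-allele additive effect (half the difference between homozygote class
means). Variants are filtered to missingness ≤ 0.1 and MAF ≥ 0.015
(inclusive). Endosymbiont infection is called from indicator-gene read
counts (> 7,000 reads = infected, strict); infection and inversion
covariates enter an analysis only if their single-covariate linear
regression against that phenotype gives P < 0.1.

The GRM is G = (1/m) Σ_k (x_k − x̄_k)(x_k − x̄_k)ᵀ with per-variant mean
imputation of missing genotypes (imputation is used only for G; association
itself uses case deletion).

The mixed model y = Wα + xβ + g + e, g ~ N(0, σ²_g G), e ~ N(0, σ²_e I) is
fitted EMMAX-style: the null variance ratio is estimated once by REML on
the eigendecomposition of G (grid search plus bounded refinement on
log δ), then every variant is tested by generalized least squares with the
null covariance held fixed. This is a documented deviation from exact
per-variant REML; at panel scale the difference is negligible and the
approximation is deterministic. The per-variant residual scale is
re-estimated under the alternative, so with an identity-proportional GRM
the statistic collapses exactly to ordinary least squares — a property the
tests assert to 1e-8. Significance is the Wald statistic (β̂/SE)² against
χ²₁. Variants with missing genotypes are tested on the observed lines
against the corresponding submatrix of the fitted covariance (exact GLS on
the subset). Suggestive hits are P ≤ 10⁻⁵; the family-wise threshold is
α/m.

Effect classes combine the four analyses: significant in one sex only →
sex-specific; significant for the female−male difference with
opposite-signed per-sex effects → sex-antagonistic; a single-sex hit also
significant for the average with a same-signed effect in the other sex
additionally carries a concordant label (the only permitted multi-label
case). Everything else is unclassified.

## Annotation

A variant is assigned to every gene whose span, extended ±5,000 bp
(inclusive), contains it; coordinates are 1-based inclusive throughout,
with BED converted at the boundary. Site classes are positional only
(genic, upstream_5kb, downstream_5kb relative to strand): transcript-aware
consequence prediction is out of scope and deliberately not imitated.
The ±5 kb window applies to the union gene span, not per transcript.

## Networks

The candidate network contains the candidate genes present in the
background interactome plus every other gene adjacent to ≥ 2 candidates,
with all background edges among retained nodes; duplicate genetic/physical
edges collapse to a single edge carrying both labels. The connectivity
index is the mean degree 2|E|/|V| of that simple graph — the simplest
statistic consistent with "degree of connectivity"; induced-subgraph
density is the plausible alternative, noted but not used. The permutation
null draws equally many genes uniformly without replacement from the
background's gene universe (not genome-wide: connectivity is only defined
on the interactome), takes the induced subgraph's mean degree, and repeats
N times (default 10,000). P = n_X/N with strict exceedance (ties count as
non-exceeding and are logged); when n_X = 0 the result is displayed as
"< 1/N" rather than zero. Ortholog tables keep the single best-scoring
human gene per fly gene (ties break lexicographically, logged) with
configurable score floors (≥3 "has ortholog", ≥7 "strong"). Edge
correctness counts fly edges whose ortholog-mapped endpoints are also an
edge of the human network, as a percentage of fly edges.

## Enrichment

One-sided (over-representation) Fisher's exact tests — computed as the
upper hypergeometric tail — with Benjamini-Hochberg adjustment across
terms. The universe defaults to the supplied annotation's gene set and is
overridable, since externally curated universes are not reproducible.

## Synthetic cohorts

The generator emulates the study conditions end to end: 204 lines,
2 sexes, 4 replicates of 15–20 flies (drawn uniformly per vial), biallelic
homozygous genotypes with MAF uniform on [0.015, 0.5] (realized MAF is
redrawn up to the spectrum floor) and configurable missingness, line
covariates, and replicate-level phenotypes from the same mixed model the
estimators assume. Default latent variance components are σ²_L = 1.0,
σ²_{L×S} = 0.70, σ²_ε = 0.373 — ratios consistent with a broad-sense
heritability of 0.82 and, with equal per-sex line variances
(σ²_L + σ²_{L×S} = 1.70), a cross-sex genetic correlation of
1.0/1.70 ≈ 0.588.

Two phenotype modes exist by design. The default "gaussian" mode emits the
latent replicate values directly, so variance-component recovery can be
tested against exact generating values. "Binomial" mode maps the latent
value to a survival probability — identity link clamped to [0.01, 0.99] by
default, because the analysis models proportions linearly and the identity
link keeps generating and fitted models aligned; a logistic link is
available by flag — then draws survived ~ Binomial(n, p). The binomial
layer adds p(1−p)/n replicate noise that inflates σ̂²_ε, and in binomial
mode variances must be chosen on the proportion scale (≈0.01–0.09; the CLI
defaults to 0.04/0.028/0.015, preserving the same ratios).

Planted variants shift carrier lines' latent values by a signed per-sex
effect, with mode invariants enforced (sex-specific ⇔ the other sex's
effect is zero; antagonistic ⇔ opposite signs). An optional
sex-antagonistic effect of the first inversion karyotype supports testing
the covariate screen. Wolbachia prevalence defaults to 0.5 and inversion
allele frequencies are drawn on (0.05, 0.5); neither is pinned down by the
study design, so these are documented field-typical choices. Indicator
read counts are lognormal with modes near 100 (uninfected) and 50,000
(infected) so the 7,000-read rule separates them essentially without
error. The background interactome is a Barabási–Albert graph with randomly
labelled genetic/physical edges.

Not emulated: linkage disequilibrium (variants are independent), realistic
gene/variant coordinates beyond uniform placement, dose-response curvature,
and any sequencing-level artefact. Passing tests therefore demonstrate
estimator correctness under the assumed generating model, not robustness
to LD, allele-frequency spectra or assay artefacts of real panels.

## Numerical choices and degenerate inputs

* REML optimizers are bounded (components ≥ 0, residual ≥ 1e-10 × phenotype
  variance) and start from the method-of-moments solution.
* Phenotypes with (numerically) zero variance short-circuit to all-zero
  components; H² on zero total variance is NaN, flagged.
* Constant GWAS phenotypes yield β = 0, P = 1 for every variant; variants
  monomorphic in an analysis subset are skipped.
* GRM eigenvalues are floored at 0 after a PSD check at −1e-8 relative.
* P-values are floored at the smallest positive double to keep logs finite.
* All generators derive independent, component-tagged random streams from
  the single configuration seed; every pipeline output embeds the seed and
  a configuration hash.

## Problem sizes

Simulation-based tests and the acceptance script use the study's panel
geometry (204 lines × 2 sexes × 4 replicates) with 20 replicate seeds for
recovery means, 5,000 variants for null-uniformity checks, and 500-draw
permutation nulls replicated 200× for calibration — sizes at which the
whole suite completes in a few minutes on one CPU while keeping Monte
Carlo error well inside the asserted tolerances.
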