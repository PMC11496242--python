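# Methods

`triomr` implements family-based Mendelian randomization (MR) for a prenatal
exposure, together with the simulation machinery needed to validate every
estimator against a known truth. The running scientific setting is maternal
coffee consumption during pregnancy and continuous offspring
neurodevelopmental scores, but all components are exposure-agnostic.

## The causal question and why ordinary designs fail

We want the *intrauterine* effect of a maternal exposure X on an offspring
outcome Y. Observational regressions of Y on X are confounded by shared
familial factors (socioeconomic position, maternal behaviour, genetic
nurture). Standard one-sample MR — instrumenting X with a maternal polygenic
score (PGS) — removes classical confounding but introduces a family-specific
pleiotropy: the mother transmits half of her instrument alleles to the
child, so a maternal PGS proxies the offspring's own genotype. Any direct
effect of the child's alleles on Y masquerades as an intrauterine effect.

## Trio simulation model

`simulate.simulate_trios` draws, for each of n families:

- parental genotypes at m biallelic loci under Hardy–Weinberg equilibrium
  (two explicit haplotypes per parent); the child inherits one uniformly
  chosen allele from each parent, so the parent–child dosage correlation is
  0.5 by construction;
- a latent familial confounder C ~ N(0,1);
- maternal coffee intake from a hurdle model: consumer status is Bernoulli
  with logistic probability (`base_rate` 0.80 by default, optionally shifted
  by per-variant log-odds loadings), and consumers draw a zero-truncated
  normal intake level `intercept + Σ w_j g_j + c_x·C + ε`
  (defaults: intercept 2.0 cups/day, residual SD 1.5, `c_x` 0.5);
- an offspring outcome
  `Y = β·X_m + δ_o·PGS_o + δ_f·PGS_f + c_y·C + Σ d_m,j g_m,j + Σ d_o,j g_o,j + ε`,
  with all genetic paths (β, δ_o, δ_f, per-variant direct effects) zero by
  default and `c_y` 0.3, plus additional pure-noise outcomes.

The default instrument panel is eight coffee-associated variants with
realistic minor-allele frequencies and per-allele effects of 0.03–0.12
cups/day, giving a weak-but-conventional instrument (F ≈ 50 at n = 20 000).
Defaults model the *study conditions* — a null causal effect with familial
confounding — and are never adjusted to make a diagnostic look better;
nonzero effects are switched on explicitly where a test or example needs a
known truth.

What the generator deliberately does **not** emulate: assortative mating,
linkage between instrument loci (available separately via a Gaussian-copula
LD generator for clumping tests), binary/ordinal outcome scales, selection
into the cohort, and measurement error in genotypes.

## Phenotype derivation

- Coffee items are summed and converted to cups (125 mL cup); totals above
  3.5 L/day are flagged for exclusion. Caffeine aggregates in mg/day.
- Scale scores are the item sum with person-mean imputation when at least
  half the items are observed, otherwise missing.
- Continuous outcomes are rank inverse-normal transformed (Blom offset 3/8,
  average ranks for ties) before analysis.
- The multiple-testing threshold divides the family-wise alpha (0.05) by the
  number of principal components needed to reach 80% of the outcome
  correlation-matrix variance (`effective_tests_threshold`).

## Estimators

**Observational** (`observational`): OLS of outcome on exposure with three
nested covariate presets; the paternal exposure serves as a negative
control, since it shares the confounding but not the intrauterine path.

**Conditional family MR** (`family_mr.conditional_mr`): the coefficient on
the maternal PGS in a regression of Y on maternal PGS plus an offspring
block — either the offspring PGS or the full offspring dosage matrix — and,
in trios, the paternal PGS as a second negative control. Conditioning on
the offspring genotype blocks the transmission path, so the maternal
coefficient isolates effects acting through the mother. Optionally the
residual structure is a single-GRM mixed model: the GRM is `ZZᵀ/m` over
standardized dosages (instrument loci excluded within 1 Mb flanks), and the
variance ratio is estimated by REML via eigendecomposition and bounded
scalar minimization. `gxe_stratified` repeats the conditional model in
consumer and non-consumer strata and compares them with a two-estimate
Cochran's Q: a real intake-mediated effect can exist only where intake does.

**Two-sample summary MR** (`summary_mr`): per-variant effect harmonization
(sign flips, strand complements, palindromic removal, audit log), Wald
ratios, fixed/multiplicative-random IVW (random-effects scale factor
`max(1, √(Q/(L−1)))`), MR-Egger (exposure betas oriented positive,
t-inference on L−2 df), the weighted median (cumulative-weight
interpolation, parametric-bootstrap SE), simple/weighted mode (KDE with the
modified Silverman bandwidth `φ·0.9·min(sd, 1.4826·MAD)·L^{−1/5}`),
Cochran's Q, and multivariable IVW (weighted least squares of outcome betas
on the exposure-beta matrix, no intercept).

**Maternal/fetal partitioning** (`partition`): maternal and offspring
marginal GWAS of the same outcome satisfy `b_m = d_m + ½ d_o` and
`b_o = d_o + ½ d_m`; the conditional (direct) effects follow from the
closed-form inverse of `B = [[1, ½], [½, 1]]`, with
`Var(d) = B⁻¹ Σ B⁻ᵀ` where Σ carries the sampling covariance
`r·se_m·se_o`. Because the B⁻¹ row weights have opposite signs, positive
sampling correlation *shrinks* the partitioned SEs
(`Var(d_m) = (20 − 16r)/9 · σ²` at equal input SEs). For full-overlap
same-outcome duo GWAS the effective error correlation is the parent–child
dosage correlation (~0.5 under random mating; verified by simulation), not
the phenotypic correlation, and callers pass it through
`overlap_correlation`.

**Instrument QC** (`instruments`): weighted/unweighted PGS construction, F
and I²_GX diagnostics, greedy p-value clumping, and a collider screen that
drops variants associated with consumer status (which would distort
stratified analyses).

## Numerical choices

- All regression estimators used inside the package are closed-form linear
  algebra (QR residualization for the vectorized per-variant GWAS); the test
  suite verifies them against statsmodels and brute-force normal equations
  to 1e-10.
- Bootstrap and KDE-grid estimators take explicit seeds; every random draw
  in the package flows from a user-supplied integer seed through
  `numpy.random.default_rng`, and the pipeline is bit-reproducible (tested).
- Default problem sizes (n = 20 000 families for validation cohorts, 8
  instruments, 5 outcomes) were chosen so parameter-recovery checks have
  power while the full test suite runs in seconds; the dense-GRM mixed model
  is capped at n = 20 000.

## Limitations

Eight instruments give wide MR confidence intervals, exactly as in real
coffee-MR applications; the partition assumes random mating and no paternal
direct effects on the transmitted-allele bookkeeping; the collider screen
is a pragmatic linear-probability filter, not a full selection model; and
the simulation's hurdle exposure means PGS-scale and cups/day-scale effects
differ by the consumer fraction unless the hurdle is disabled
(`wald_scale` converts between scales).
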