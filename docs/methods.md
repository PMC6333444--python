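# Methods

## The kin-cohort survival model

`kinspan` estimates genetic effects on lifespan without observing the
carrier's own death: subjects are genotyped, and each subject reports the
age and alive/dead status of their father and mother.  Parent survival is
modelled with a proportional-hazards model

    h(x) = h0(x) * exp(beta * X + gamma_1 Z_1 + ... + gamma_k Z_k)

where x is parent age, X the *offspring* genotype dosage (0–2), and Z the
technical covariates.  Because a subject allele has a 50% chance of
having come from the indexed parent, the coefficient on offspring dosage
is half the effect in the parent who actually carries the allele; all
reported effects are therefore doubled to the carrier scale.  Signs are
flipped to the **log protection ratio** (lnPR = −lnHR), so positive
effects mean longer life, and years of life per allele are estimated as
10 × lnPR (the actuarial rule of thumb that a 10% reduction in lifetime
hazard buys about one year; under the package's default Gompertz baseline
the exact derivative is ln2 / h(median) ≈ 9.8 years per unit lnHR).

### The residual phenotype

Fitting a full Cox model per SNP at genome scale is unnecessary: a
covariates-only Cox fit is done once per parent sex, and its Martingale
residuals (event indicator minus cumulative hazard at exit) divided by
the proportion dead form a quantitative trait whose OLS slope on dosage
estimates the parent lnHR.  The per-SNP scan is then a vectorised
Frisch–Waugh–Lovell regression (phenotype and dosages residualised on
the covariates once; per-column slopes and classical SEs afterwards),
cross-checked against `statsmodels` OLS in the tests.  Covariates are
re-included in the scan; with residualisation already done this is
harmless when they are orthogonal to dosage and guards against residual
confounding when they are not.  Missing dosages are mean-imputed per
SNP; (near-)monomorphic SNPs yield NA records with a warning.  The MAF
filter defaults to 0.005 and the genome-wide threshold to 2.5e-8 (5e-8
over the two combined tests below).

### Combining parents

* **CES** (common effect sizes): the father and mother residuals are
  summed per subject and the summed trait regressed on dosage.  Under a
  shared effect the summed trait's slope is twice the single-parent
  slope — already the carrier scale — so CES results are *not* doubled
  again (the doubling lives only in single-parent record creation, and a
  unit test enforces that it happens exactly once).  The regression SE
  of the summed trait absorbs the father–mother covariance
  automatically.
* **SSE** (sex-specific effect sizes): a MANOVA-style bivariate Wald
  statistic z'R⁻¹z on 2 df, with R the 2×2 correlation matrix of the
  parent traits (off-diagonal r ≈ 0.1).  It tests that *either* parent's
  effect is nonzero and returns no single beta.

Cross-cohort meta-analysis of CES estimates uses inverse-variance
weighting with SE inflated by √(1+r).  This is slightly conservative;
the exact two-estimate variance Var₀·(1 + 2r·s₁s₂/(s₁²+s₂²)) is also
exposed and equals the √(1+r) form when s₁ = s₂.

## The synthetic cohort generator

No real genotypes or phenotypes ship with the package; every stage is
exercised on cohorts drawn by `simcohort`.  The generator reproduces the
statistical features the analysis relies on:

* **Transmission.** Parent genotypes are Hardy–Weinberg Binomial(2, maf)
  draws; the offspring receives one Bernoulli(g/2) allele from each
  parent.  This gives r²(offspring dosage, parent genotype) = 0.25, the
  kin-cohort dilution factor.
* **Baseline mortality.** Gompertz h0(x) = a·e^{bx} with a = 2e-5/yr,
  b = 0.1/yr, putting the modal age at death in the mid-80s, and left
  truncation at age 40 (parental deaths at or before 40 are excluded by
  the study design; death ages are drawn by closed-form inverse
  transform of the survival function conditional on reaching 40).  A
  semi-parametric analysis never sees the baseline, but Gompertz gives
  closed forms — conditional median, survival curve — that the tests use
  as oracles.
* **Per-allele effects.** A SNP with carrier lnPR beta shifts the
  carrier parent's log hazard by −beta per allele (recessive variants:
  only for effect-allele homozygotes).  Contributions are centred at
  the population-mean exposure so the aggregate polygenic load is
  absorbed into the baseline and population survival keeps its
  calibrated shape however many effect SNPs are simulated.
* **Inter-parent correlation.** Father and mother log hazards share a
  Gaussian log-frailty: total frailty sd 1.0, with inter-parent frailty
  correlation rho.  rho was calibrated numerically (one-off grid over
  rho at n = 30,000) so the father–mother *residual-trait* correlation
  is ≈ 0.1, the value the combined-parent analyses assume; the
  calibrated default is rho = 0.35.  The frailty also supplies realistic
  unobserved heterogeneity, which attenuates marginal hazard ratios
  (about 10% at these settings) — both the residual method and any Cox
  fit see the same attenuated marginal effect, so method-vs-oracle
  comparisons are unaffected, and tests that compare against nominal
  simulated betas switch the frailty off.
* **Censoring.** Ages at last observation are uniform on [70, 100],
  chosen so ≈ 60% of parents are deceased under the default hazard
  (closed-form check: 0.61; empirical: 0.60) — the deceased fraction of
  the cohorts the method was designed for.  Subjects' parents being
  observed at interview rather than followed to death is the binding
  feature; the uniform shape is a modelling convenience, as no source
  states the real censoring-age distribution.
* **Risk-factor tables.** For the prior-informed stage, per-SNP effects
  on K standardised risk factors are drawn N(0, 1), the implied lifespan
  effect is the causal-weighted sum of the true factor effects, and the
  observed tables add independent noise with stated SEs — so prior
  construction and causal-effect recovery can be tested against known
  truth.

All randomness flows through a single `numpy.random.Generator` from an
explicit seed; the same seed reproduces a cohort bit for bit.

What the generator does **not** emulate: linkage disequilibrium (tests
of LD pruning build block-correlation matrices directly), population
stratification, genotyping error and imputation uncertainty, assortative
mating, secular trends in mortality, and age-varying SNP effects (the
stratified-effects tests construct those piecewise by hand).  Passing
tests therefore demonstrate correctness of the estimators under the
model's assumptions, not robustness to these real-data complications.

## Scale conversions

All conversions are pure functions; empirical anchors are always passed
in, never hard-coded.

* Rank-normalised Martingale-residual effects → lnHR: multiply by
  √c·(1/c) = 1/√c (c = proportion dead), ×2 for carrier scale.
* Recessive homozygote effect → expected additive carrier effect:
  multiply by q²/(q²+2pq) (the probability that the transmitting parent
  is homozygous, halved per transmitted allele and re-doubled to carrier
  scale).
* Longevity log OR ↔ lifespan lnHR: the empirical magnitude ratio at a
  shared anchor variant, direction-explicit because published constants
  exist in both orientations.
* Equivalent sample size: n × h² × r²_kin × c, optionally divided by a
  reference trait's heritability.

## Collective replication

Replication and discovery effects on a common scale are compared per SNP
by the ratio alpha = beta_rep/beta_disc with the first-order
delta-method SE √(SE_rep²/β_d² + β_r²SE_d²/β_d⁴); the one-sided p tests
alpha = 0 against the discovery sign.  The first-order SE is biased when
|beta_disc|/SE_disc is small — the tests document this with a parametric
bootstrap oracle.  Alphas are IVW-pooled across loci (excluding the
calibration anchor, whose ratio is 1 by construction).  Overlapping
replication studies are pooled with the covariance-inflated variance
Var₀ + 2ΣΣ w_n w_m Cov(β_n, β_m), the covariances estimated from the
correlation of Z among SNPs null (|Z| < 1) in both studies.  Overlap
adjustment is applied on the converted (lnHR) scale.

## Risk-factor-informed association (iGWAS)

Per SNP, a normal prior on the Z scale is built from the SNP's effects
b_k on risk factors and the factors' multivariate-MR causal effects
theta_k on lifespan (weighted least squares of lifespan effects on the
factor-effect matrix, no intercept, focal chromosome maskable; factor
selection by bidirectional stepwise AIC — note a plain AIC retains a
null factor with probability P(χ²₁ > 2) ≈ 0.157, which the tests assert
rather than wish away).  The prior is

    mu = Σ theta_k b_k,
    sigma² = Σ (theta_k² se_b² + b_k² se_theta²) + 1,

the delta-method propagation plus one because the prior is compared to
*observed* Z statistics (Z_obs ~ N(Z_true, 1)).  Missing factor effects
contribute zero with their variance term dropped, flagged per SNP.
Evidence is the normal–normal marginal likelihood ratio
logBF = log N(z; mu, sigma²) − log N(z; 0, 1), isolated in one function
so an alternative form can be swapped in.  Significance is empirical:
the observed Z vector is permuted against the fixed prior vector, null
logBFs pooled across SNPs and permutations, p = (1+#{null ≥ obs})/(1+N),
the attainable floor flagged, and BH applied across SNPs.  The
desk-scale default (10³–10⁴ SNPs × 10²–10³ permutations) is the same
computation as a full-scale run, smaller only in N.

## Stratified effects

Each variant is re-estimated within age bands (decades 40–90 plus
90–120) and parent sex: parents dying before a band are excluded, exit
is truncated at the band's end, entry is left-truncated at the band's
start, so the bands partition the information (total deaths across bands
equal total deaths).  Band estimates with known variances feed a
fixed-effects moderator regression beta ~ intercept + age + sex — WLS
with weights 1/se² and coefficient covariance (X'WX)⁻¹, i.e. the
known-variance meta-regression, equal to the GLS oracle to numerical
precision.  Age is coded as the band midpoint in years (so the slope has
per-year units); sex is 0 = mother, 1 = father; BH q-values are computed
over the SNP × {age, sex} family.

## Disease attribution

Disease-catalog SNPs are pruned to independent loci (greedy by ascending
lifespan p; 500 kb distance and, when an LD matrix is available, r² <
0.1 — distance-only otherwise).  Lifespan variance explained is
LVE = 2pqa² (years²).  Significance uses the one-false-positive rule:
BH q ≤ 1/n (expected false discoveries ≤ 1), displayed truncated to
three decimals.  A SNP is *secondary* when another disease category's
|Z| is at least 2× the nominal category's (boundary inclusive) with
concordant direction; Z rather than OR because attributable cases in the
population, not per-case odds, determine the lifespan burden — for the
same reason sex-specific diseases count the other sex as controls,
halving apparent effects deliberately.  A SNP is *antagonistic* when an
allele increases both a disease and lifespan.  Category totals sum
|LVE| over significant, non-secondary SNPs.  Fisher's exact test (exact
two-sided p, conditional-MLE odds ratio) serves enrichment questions.

## Polygenic scores

Clump (250 kb / r² 0.1, reusing the pruning routine) + threshold
(default p ≤ 1: the densest score is the most informative for lifespan),
score = Σ dosage × beta, Z-standardised on the scored sample.  Training
cohort labels are carried in the model and scoring a training cohort
raises — the train/test split is enforced by the API.  Survival
association is a Cox fit on the standardised score (doubled and negated
for parent phenotypes, undoubled for subjects); the top-vs-bottom decile
contrast is the difference in Kaplan–Meier median survival, doubled for
parents, with deciles defined by sample quantiles and stable
tie-breaking, and plateauing KM curves reported as censoring-time lower
bounds with a flag.  Disease associations are logistic regressions of
*not* carrying the disease (positive = protective); first-degree
relative estimates are doubled, and kin meta-analysis inflates SEs by
√(1+r) per family-member trait correlation, with a `"linear"` (1+r)
switch because the two published formulations differ; √(1+r) — the
displayed-equation form — is the default.

## Numerical choices and problem sizes

* Cox fits use `lifelines` (Newton iterations, its default convergence
  tolerances).  Its partial-likelihood ties rule is Efron; simulated
  ages are continuous so ties do not arise and Efron/Breslow coincide
  here.
* The per-SNP OLS scan uses one `lstsq` projection for all SNPs;
  degenerate (monomorphic) columns are detected by a relative
  sum-of-squares floor (1e-10·n).
* Pruning ties (identical p) break by (chromosome, position) so output
  is input-order invariant.
* Default test and acceptance problem sizes — cohorts of 3,000–20,000
  subjects, 10–5,000 SNPs, 50 paired informed-GWAS replicates of 1,000
  SNPs × 100 permutations, 1,000 alpha-coverage pairs — were chosen as
  the smallest sizes at which each statistical property is comfortably
  resolved, and are fixed by seeds for reproducibility.

## Known limitations

* The residual-trait OLS SE is the classical homoskedastic one; at the
  simulated scales it matches the Cox oracle closely, but heavy-tailed
  residual traits in real data may warrant robust SEs.
* The delta-method alpha SE degrades for weak discovery effects
  (|beta|/SE ≲ 3); the bootstrap in the tests quantifies this.
* The informed-GWAS prior variance propagation is first-order and drops
  the theta–b cross-moment (exact for independent estimates up to the
  σ²_θσ²_b term, which the tests bound by Monte Carlo).
* Distance-only pruning (no LD matrix) under-prunes in regions of
  long-range LD.
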