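# Methods

`halfsibqg` implements the quantitative-genetic analysis of a split-brood
paternal half-sib breeding design: each sire is mated to several dams and
every dam's brood is divided between two rearing environments (here 0% and
7% dietary ethanol), so that environment-specific additive genetic
(co)variances can be estimated for five traits — larval, pupal and total
development time (LDT, PDT, TDT; days), adult body mass (Mb; mg) and
routine metabolic rate (RMR; µL CO₂ h⁻¹). All genetic analyses operate on
log10-transformed traits to remove mean–variance scaling.

## The animal model

For a trait *y* the model is

    y = X b + Z_a a + Z_c c + Z_r r + e

with fixed effects *b* (sex everywhere; metabolic chamber, record hour and
a centred log10 body-mass covariate for RMR), breeding values
*a* ~ N(0, A σ²_A) where A is the pedigree numerator relationship matrix,
common-environment (dam/vial) effects *c* ~ N(0, I σ²_C), replicate-line
effects *r* ~ N(0, I σ²_R), and residuals *e* ~ N(0, I σ²_E). Heritability
is h² = σ²_A / (σ²_A + σ²_C + σ²_R + σ²_E). The bivariate model replaces
each scalar with a 2×2 matrix; the genetic correlation is
r_g = cov_A / √(V_A1 V_A2), computed per posterior draw so every draw is
bounded by Cauchy–Schwarz. Because the RMR model includes the body-mass
covariate, its h² is a *mass-adjusted* heritability.

### Sampler

A blocked Gibbs sampler on the latent-variable parameterization. All full
conditionals are conjugate: location blocks are Gaussian, univariate
variances scaled-inverse-χ², bivariate matrices inverse-Wishart. The
breeding-value block uses a one-off spectral reparameterization: with
A = L Lᵀ (dense Cholesky; adequate for pedigrees below ~10⁴ individuals)
and Lᵀ Z_aᵀ Z_a L = Q Λ Qᵀ, the coordinates v defined by a = L Q v have
diagonal conditional precision Λ/σ²_E + I/σ²_A (univariate) or a
block-diagonal stack of 2×2 precisions (bivariate), so each iteration
costs two dense matrix–vector products instead of a fresh factorization.
Fixed effects get improper flat priors; dam and line blocks have diagonal
conditional precisions by construction.

Blocked updates mix more slowly than a joint location update, so thinned
chains should be checked with the lag-1 autocorrelation diagnostic
(`autocorrelation_check`, flag threshold 0.05). Chains are exactly
reproducible from the seed.

### Priors

The total phenotypic sample variance T is partitioned equally among the k
random components (k = 4 for the complete ACRE model, 3 for the
constrained CRE model without the additive term). Each univariate
component gets a scaled-inverse-χ² prior with belief ν = 1 and scale
T/k; since ν = 1 has no finite mean, "centred on T/k" means the scale
parameter, matching the usual animal-model software convention (for
ν > 2, `solve_prior_scale` inverts the inverse-gamma mean relation
instead). Bivariate components get inverse-Wishart(ν = 2,
Ψ = diag(T/k)). Both ν and the partition are overridable.

### Chain lengths

`MCMCConfig.paper_scale()` gives the long-run settings (10⁶ iterations,
10⁵ burn-in, thin 500). The library default is a desk-scale 60k/10k/25;
the test suite uses 15k/3k/12 for replicated recovery experiments. These
are the package's own choices for routine work: with the spectral
reparameterization the retained-draw autocorrelations are already below
the 0.05 rule of thumb at these lengths on the designs simulated here.

### DIC and significance

The deviance trace is Gaussian *conditional on the latent effects*
(matching the convention of latent-variable MCMC software);
DIC = D̄ + pD with pD = D̄ − D(θ̄), where D(θ̄) is evaluated at the
posterior means of the fitted values and residual (co)variance. A genetic
parameter is reported significant only when its 95% highest-posterior-
density interval excludes zero (an interval touching zero counts as
overlap) *and* the complete model has lower DIC than the constrained
model. Point estimates are the kernel-density posterior mode; the
posterior mean is reported alongside.

## Phenotype-level models

The mixed ANOVA uses Type-III sums of squares under sum-to-zero contrasts
(computed by explicit model-comparison projections), with replicate line
nested in population as a random term. F denominators follow expected
mean squares: the population main effect is tested against the
line-within-population mean square — with two populations of three lines
each this gives the characteristic 4 denominator df — and every other
term against the residual. P-values are reported per test without
multiple-testing adjustment. Post-hoc comparisons use the Tukey–Kramer
(unequal-N) studentized-range test. Slope homogeneity of the body-mass–
RMR relation across sexes or treatments is the ANCOVA interaction F.

## Respirometry

Each multiplexed record reads seven fly chambers and one empty chamber;
the empty chamber is read at the beginning, middle and end of the record.
A least-squares line through all baseline points (not two-point
interpolation; the two coincide for two points and the fit is robust for
three or more) defines the analyzer zero and is subtracted everywhere, so
RMR extraction is invariant to any linear drift common to all chambers.
The per-fly summary is the mean corrected ppm over the fly's 10-minute
window — the mean rather than a steady-state plateau, for determinism —
converted as rate = ppm × 10⁻⁶ × flow(mL min⁻¹) × 60 × 1000, i.e. 10 ppm
at 50 mL min⁻¹ is 30 µL CO₂ h⁻¹. Chamber washout deconvolution and
activity detection are out of scope; traces are treated as equilibrated.

## G-matrix comparison

G per treatment is estimated by the half-sib moment method: nested
sire/dam mean cross-product matrices with unbalanced-design (Satterthwaite-
style) coefficients; V_A = 4 × sire component. Applying the EMS algebra to
cross-products element-wise is algebraically identical to the sum-variance
identity cov = [Var(x+y) − Var(x) − Var(y)]/2 at the component level (a
property test asserts this). Negative component estimates are retained
untruncated — truncation would bias the downstream MANOVA — so reported
matrices may lie outside the parameter space.

Delete-one-family jackknife pseudovalues p_i = n·vec(G) − (n−1)·vec(G₋ᵢ)
are formed on the 15-element unique (lower-triangle, row-major)
vectorization, one per family per treatment; each treatment's jackknife is
internal to its own data. Note the convention: *n* pseudovalues per group
(standard delete-one jackknife), which is what makes the exact Wilks' λ F
transform for 16 families per group come out at (15, 16) df; Wilks'
λ = det(E)/det(E+H) with F = (1−λ)/λ · (N−p−1)/p. Univariate follow-up
ANOVAs per element use (1, N−2) df. Nuisance fixed effects found
significant at the phenotype level are removed first by residualizing each
trait on a main-effects-only linear model. Any consistent trait order
yields the same λ (tested).

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is validated. Defaults reproduce the study
design — two populations with 29 and 16 sires split over 3 replicate
lines each (round-robin), 4 dams per sire, 6 offspring per dam per
environment (2160 offspring in all).

Cross-environment genetics uses the two-environment character-state
formulation: founders carry 10-dimensional breeding values drawn from
[[G₀, B], [Bᵀ, G₇]] with B diagonal, B_ii = ρ_GE √(G₀ᵢᵢ G₇ᵢᵢ), and zero
cross-trait cross-environment covariance; offspring get the parental
mid-value plus a Mendelian deviate with half that covariance. The block
matrix is validated positive semidefinite before sampling — note that
strong within-environment correlations combined with large |ρ_GE| can
genuinely violate PSD under this structure, and the generator refuses such
configurations. Default ρ_GE = 0.5, a moderate cross-environment genetic
correlation (genotype-by-environment interaction present but not
extreme). Dam and line effects are drawn independently per environment
(each dam's split brood occupies a different vial in each environment).

Default raw-scale trait means (LDT 22 d, PDT 11 d, Mb 1.0 mg, RMR
60 µL h⁻¹) are arbitrary figure-scale magnitudes, not estimates. Default
log10-scale total variances are 0.004–0.010 per trait with heritabilities
0.10–0.30, dam fraction 0.15 and line fraction 0.05. Sex, population and
environment effects are mean shifts only (sex enters the analysis models
as a fixed effect, so no sex-specific G is generated). RMR additionally
receives an explicit body-mass slope (β = 0.65 on the log10 scale, within
the range such regressions produce), chamber effects (7 levels) and
record-hour effects (9 levels) on top of its genetic architecture; when a
recovery test needs an interpretable truth, only one of the slope and the
G/E mass–RMR covariances should be nonzero.

Total development time is the raw-scale sum LDT + PDT by construction, so
the TDT row of a supplied G applies to the latent TDT coordinate only
approximately; recovery experiments therefore target the other four
traits. Development times are kept continuous (no rounding to 24-h
checks), so generator truths are exact.

What the generator does *not* emulate: viability selection and missing
phenotypes correlated with genotype, non-Gaussian trait distributions,
inbreeding in the parental pool, sex-specific genetic (co)variances, and
respirometry washout dynamics. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to these violations.

## Validation experiments (test suite)

Problem sizes are the package's own choices for replicated experiments:

* **Conjugate oracle** — residual-only model vs the closed-form scaled-
  inverse-χ² posterior, KS distance < 0.05 at 2000 retained draws.
* **Recovery** — 29 sires × 4 dams × 6 offspring, true h² = 0.6 for LDT:
  10 replicates at 15k/3k/12; replicate-averaged posterior mean within
  ±0.15 and HPD coverage ≥ 9/10.
* **Moment calibration** — 500 simulated 29-sire datasets, mean V̂_A
  within 5% of truth; 500 null datasets centred on zero within 2 MC SEs.
* **MANOVA level** — equal-G, 2 traits, 10 independent families per
  group, 200 replicates: rejection rate within 5% ± 3%. Independent
  family sets are used because with split broods and ρ_GE ≠ 0 the two
  groups' pseudovalues are correlated and a nominal level is undefined.
* **MANOVA power** — a 14-fold contrast of the development-trait additive
  block (the magnitude of the largest contrast this design is meant to
  resolve) at 29 families per group is detected in well over half of 25
  runs; a mere doubling of one V_A is *not* reliably detectable at this
  design size (~17% power), which is worth knowing before planning a
  comparable experiment.
* **Oracles** — tabular A vs 200k-drop gene dropping (±0.02); two-group
  MANOVA vs Hotelling T²; Tukey–Kramer p vs 10⁶-draw Monte-Carlo
  studentized range (±0.005); exact baseline correction on noiseless
  linear drift; the ppm→rate dimensional constant.

## Numerical choices and edge cases

* A + 10⁻¹⁰ I jitter before Cholesky; eigenvalues of the spectral
  operator clipped at zero.
* Covariance matrices in the generator are factorized by eigendecomposition
  with negative eigenvalues clipped, so exactly singular configurations
  (zero variance, ρ_GE = ±1) sample correctly.
* Families with fewer than 2 complete offspring are dropped (with a
  warning) before moment estimation; the observed G needs ≥ 3 families,
  leave-one-out re-estimates are allowed 2.
* A constant MCMC chain yields an undefined autocorrelation, reported as
  missing with a warning; chains shorter than 10 retained draws are
  rejected.
* Degenerate HPD intervals (all draws equal) collapse to a point; an
  interval with endpoint exactly 0 counts as overlapping zero.
* TDT ≠ LDT + PDT beyond 1 day (the 24-h recording interval) warns but
  does not error.

## Known limitations

Dense relationship-matrix algebra limits pedigrees to desk scale
(~10⁴ individuals); Henderson's sparse inverse rules would lift this but
are not implemented. The jackknife MANOVA treats the two treatment groups
as independent, which split broods violate when ρ_GE ≠ 0; the moment
estimator ignores replicate-line structure (remove line effects by
residualization first if they are large). DIC uses the conditional
deviance; marginal-deviance DIC is out of scope.
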