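# Methods

This note records the statistical model mrkit implements, the conventions
and defaults it chose where several were defensible, what the synthetic
data generator does and does not emulate, and the package's known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Two-sample summary-data MR

The data model: for SNP *j* of an instrument of independent loci,
γ*ⱼ* is the true per-allele effect on the exposure (SD units), α*ⱼ* a
possible direct ("horizontally pleiotropic") effect on the outcome, and
*b* the causal log odds ratio per SD of exposure. The observed summary
statistics are

    γ̂ⱼ ~ N(γⱼ, σ²ₓⱼ),    Γ̂ⱼ ~ N(b·γⱼ + αⱼ, σ²ᵧⱼ),

independent across SNPs (no LD) and between samples (no overlap between
exposure and outcome GWAS). A SNP is a *valid instrument* when αⱼ = 0.

### Wald ratio

β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order delta SE σᵧⱼ/γ̂ⱼ. The first-order form
ignores exposure-side uncertainty; this is the summary-data MR convention
for strong instruments and is accurate here because the packaged
instrument's F-statistics (γ̂/σₓ)² are in the hundreds. The second-order SE
(adding Γ̂²σ²ₓ/γ̂⁴) is available via `second_order=True`; for
SLC2A9-strength SNPs the two differ by well under 1% (asserted in the
tests). SNPs with γ̂ = 0 are excluded with a warning — the ratio is
undefined — rather than propagated as infinities.

### IVW

Fixed-effect by default: estimate Σwβ̂/Σw, SE (Σw)^{−1/2}. This equals the
zero-intercept weighted least-squares slope of Γ̂ on γ̂ with weights σᵧ⁻²
(the suite checks agreement with an explicit normal-equations oracle to 10
significant digits). A multiplicative random-effects variant
(`model="random"`) scales the SE by max(1, √(Q/(n−1))) and never shrinks
it. The fixed-effect model is the default because a single pooled estimate
without dispersion language is the convention this package follows;
which variant a given published analysis used is often unstated, so both
are exposed.

### MR-Egger

The same weighted regression with a free intercept, requiring n ≥ 3,
spread in γ̂, and orientation to the exposure-increasing allele (the
intercept is meaningless under arbitrary per-SNP sign conventions —
orientation is applied by harmonization and enforced here). Standard
errors use multiplicative overdispersion with a floor at one: SEs from
(XᵀWX)⁻¹ are scaled by max(1, σ̂) where σ̂² is the weighted residual mean
square. Intercept and slope p-values are two-sided normal. The slope is
consistent under InSIDE (cov(γ, α) = 0) even when every SNP is pleiotropic;
the price is much lower precision, since the slope is identified only by
the spread in instrument strengths.

### Penalized weighted median

The weighted median uses the interpolated definition: with ratios sorted
ascending and standardized cumulative weights sⱼ = (Σₖ≤ⱼwₖ − wⱼ/2)/Σw, the
estimate interpolates linearly between the ratios bracketing s = 0.5 (with
equal weights and odd n this is the sample median; below s₁ or above sₙ it
clamps to the extreme ratio). Penalization multiplies each weight by
min(1, 20·qⱼ), where qⱼ is the chi-square(1) upper tail of the SNP's
heterogeneity contribution Qⱼ = wⱼ(β̂ⱼ − β̂_anchor)² **about the unpenalized
weighted median**. Anchoring at the median rather than the IVW mean is the
published form of the estimator and matters in exactly the regime the
estimator exists for: with a large minority of invalid SNPs the IVW anchor
is dragged toward them, and penalizing deviations from a corrupted anchor
removes the valid SNPs instead of the invalid ones (measured in
development: bias 0.77 vs 0.03 on a true effect of 0.1 under 40% invalid
weight). The penalty constant 20 and the χ²(1) tail follow the published
penalization.

The point estimate is deterministic. The SE comes from a parametric
bootstrap (default 10,000 draws, seed recorded in the result): each β̂ⱼ is
resampled from N(β̂ⱼ, se²ⱼ) and the full penalized weighted median —
penalization included — is recomputed per draw; the SE is the standard
deviation of the bootstrap estimates. Fewer than 100 draws triggers a
warning.

### Diagnostics

Cochran's Q = Σwⱼ(β̂ⱼ − β̂_IVW)², df = n − 1, upper-tail chi-square p.
Q is always computed about the fixed-effect IVW point estimate, whatever
pooled model is configured, because its null distribution is defined under
that fit. Leave-one-out re-runs a chosen estimator excluding each SNP in
turn (Egger needs n ≥ 4 so each reduced fit keeps 3 SNPs). The single-SNP
table is the per-SNP Wald ratios with 95% CIs, i.e. the forest-plot data.

All 95% intervals use the normal multiplier 1.959964, not a t quantile —
the summary-data MR convention. Estimation is on the log-odds scale
throughout; ORs are exponentiated, and rounded to two decimals, only in
formatted reports. p-values keep full precision in machine output.

## Harmonization

Outcome rows are matched to exposure rows by case-insensitive rsID (no
positional fallback, no proxy search; instrument SNPs missing from the
outcome are reported and excluded). Allele reconciliation tries, in order:
direct match, effect/other swap (negate Γ̂, flip EAF), strand complement,
complement plus swap. Irreconcilable allele sets drop the record with a
note — never a hard error. Finally every pair is oriented so
β_exposure ≥ 0 (the exposure-increasing allele), negating both betas where
needed; a zero exposure beta keeps its original orientation.

Palindromic SNPs (A/T, C/G) are their own strand complement, so labels
cannot identify the strand; they are resolved by effect-allele frequency:
the orientation minimizing |EAF_exposure − EAF_outcome| is taken, and the
SNP is dropped whenever either dataset's minor-allele frequency lies within
a configurable half-window (default 0.08) of 0.5, where the comparison is
uninformative, or when either EAF is missing. The default window is a
judgment call: MAF 0.42 is the point where typical European-ancestry
frequency differences between cohorts (a few percent) start to make the
comparison unreliable. Every record carries an action tag
(unchanged / allele_swap / strand_flip / strand_flip_and_swap /
palindromic_kept / dropped) and a note; the audit table is written as TSV
and action counts are logged. Harmonization is idempotent, and a pipeline
run on strand-flipped/allele-swapped files reproduces the clean-file
estimates exactly (double sign-flips are exact in floating point), which
the acceptance suite asserts at < 10⁻¹².

## Power

For a case-control outcome with N = n_cases + n_controls and case fraction
k, the IVW log-OR estimate has approximate SE 1/√(N·R²·k(1−k)), giving
two-sided power Φ(|ln OR|·√(N·R²·k(1−k)) − z₁₋α/₂). R² — the exposure
variance explained by the instrument — is an *input* (7% for the packaged
urate instrument, as estimated in the source exposure GWAS); it is never
computed internally. At OR = 1 the formula returns α/2, the one-tail
residual of the approximation; this is a known property, documented rather
than patched. Minimum detectable ORs invert the formula by Brent
root-finding on the log-OR scale, where power is exactly symmetric
(power(OR) = power(1/OR)), and round-trip through `mr_power` to 10⁻⁸.

## The synthetic-data generator

`ScenarioConfig` defaults describe the design the packaged instrument comes
from: 31 SNPs with the packaged effect sizes and allele frequencies, an
exposure GWAS of 110,000 (the scale of the urate meta-analysis), and an
outcome GWAS of 13,708 cases / 95,282 controls. Standard errors follow the
large-sample approximations σₓ = 1/√(2p(1−p)·n_exposure) and
σᵧ = 1/√(N·k(1−k)·2p(1−p)); with the default sample sizes the generated
exposure SEs reproduce the packaged instrument's SE column within a factor
of two (asserted in the tests). `target_r_squared` rescales the γ's to hit
a chosen instrument R², which is how the analytic power formula is checked
against empirical rejection rates at matched (N, R², OR).

Pleiotropy regimes assign direct effects αⱼ to a configurable fraction of
SNPs: none; balanced (±|N(0, σ_α)|, random sign); directional with InSIDE
holding (|N(0, σ_α)|, independent of γ); or InSIDE-violating
(0.5·γⱼ + noise). Allele codings can be mangled with configurable
palindromic, strand-flip and allele-swap fractions to exercise
harmonization; outcome EAFs are written without sampling noise, so
palindromic resolution in simulations is exact whenever the MAF is outside
the ambiguity window. A master seed spawns independent substreams (one per
replicate in `replicate_study`), making every output bit-reproducible.

What the generator does **not** emulate: LD between instrument SNPs (the
instrument is defined as independent loci), individual-level genotypes,
sample overlap between the two GWAS, EAF measurement error, population
stratification, or selection/survival effects. Passing simulation checks
therefore demonstrates correctness of the estimators under their assumed
sampling model, not robustness to those real-data complications.

### Monte-Carlo study designs and problem sizes

The calibration studies in the acceptance suite use: (a) the default
31-SNP null scenario at 2,000 replicates for IVW coverage, type-I error
and the mean of Cochran's Q (which is exactly χ²(30) conditional on the
draws, so the mean should be 30); (b) a directional-pleiotropy scenario —
uniform instrument betas U(0.05, 0.15) so the Egger slope is well
identified by spread in instrument strength, half-normal pleiotropy
σ_α = 0.05 on every SNP, 1,000 replicates — contrasting Egger's
unbiasedness with IVW's failure; (c) a 40%-invalid scenario — same betas,
true effect 0.1, large pleiotropy σ_α = 0.3 so pleiotropic ratio shifts are
roughly an order of magnitude above per-SNP ratio SEs, 500 replicates —
contrasting PWM with IVW. PWM bootstrap SEs inside replicate studies use
200 draws (only CI coverage consumes them; point estimates are
deterministic). These sizes are the package's chosen balance between
Monte-Carlo resolution and a test suite that runs in seconds.

## Known limitations

* **PWM small-sample bias under one-sided contamination.** With 40% of
  SNPs carrying directional (all-positive) pleiotropy, the penalized
  weighted median retains a small positive bias (≈ +0.03 log-odds on a
  true effect of 0.1 in scenario (c); computed by the suite and by
  `examples/04_simulation_study.py`). Two mechanisms: invalid SNPs whose
  half-normal direct effect happens to be small slip past the chi-square
  penalization while still sitting above the truth, and penalization about
  a finite-sample anchor asymmetrically down-weights valid SNPs on the far
  side of it. Both the bias and the Monte-Carlo SEM scale with the per-SNP
  ratio SE, so larger simulated GWAS do not change their ratio. The bias is
  an order of magnitude smaller than IVW's in the same regime (0.03 vs
  0.85) — the estimator does its triangulation job — but "strictly
  unbiased at 3×SEM resolution with 500 replicates" is not a property this
  estimator has, and the corresponding assertion in the acceptance suite
  fails honestly rather than being loosened.
* The Egger intercept test has low power with homogeneous instrument
  strengths; nothing in the package warns about a weakly identified slope
  beyond the SE itself.
* Power uses a normal approximation whose value at OR = 1 is α/2, and
  ignores exposure-side estimation error (as does the first-order Wald SE).
* No LD pruning/clumping, proxy-SNP lookup, or genome-build liftover:
  inputs are assumed to be an already-pruned instrument and a matching
  outcome file keyed by rsID.
* Reproducing the published urate→PD estimates requires the external PD
  GWAS summary statistics; the packaged tests exercise that pathway on
  synthetic data only, and the end-to-end reproduction test runs only when
  the external file is supplied locally.
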