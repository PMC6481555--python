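# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics,
built around the question of whether circulating urate causally affects
Parkinson's disease (PD) risk. The package bundles everything that analysis
needs: the 31-SNP plasma-urate genetic instrument, allele harmonization
between exposure and outcome GWAS, the inverse-variance weighted (IVW),
MR-Egger and penalized weighted median (PWM) estimators, heterogeneity and
leave-one-out diagnostics, analytic power for binary outcomes, and a
synthetic summary-statistics generator with known ground truth so every
stage is testable without any external download.

It is a library first (`import mrkit`), with narrative scripts in
`examples/` and a thin `mrkit` command-line wrapper for file-based runs.

## The statistical model

For SNP *j*, let γ̂*ⱼ* (SE σ*ₓⱼ*) be its per-allele effect on the exposure
in SD units and Γ̂*ⱼ* (SE σ*ᵧⱼ*) its per-allele log-odds effect on the
outcome, estimated in non-overlapping samples and oriented to the
exposure-increasing allele. Each SNP gives a Wald ratio

    β̂ⱼ = Γ̂ⱼ / γ̂ⱼ,   se(β̂ⱼ) = σᵧⱼ / γ̂ⱼ,   wⱼ = se(β̂ⱼ)⁻²

and the pooled estimators are

* **IVW**: β̂ = Σwⱼβ̂ⱼ / Σwⱼ — the slope of a weighted regression of Γ̂ on γ̂
  through the origin; unbiased when every SNP is a valid instrument.
* **MR-Egger**: the same weighted regression with a free intercept; the
  intercept estimates net directional pleiotropy, and the slope is
  consistent under the InSIDE assumption (pleiotropic effects independent
  of instrument strength).
* **PWM**: the interpolated weighted median of the β̂ⱼ after chi-square
  penalization of heterogeneous weights; consistent while less than half
  the weight comes from invalid SNPs.

Cochran's Q = Σwⱼ(β̂ⱼ − β̂_IVW)² quantifies heterogeneity (a pleiotropy
signal), leave-one-out re-estimation localizes single-SNP influence, and
power for a case-control outcome uses the normal approximation
Φ(|ln OR|·√(N·R²·k(1−k)) − z₁₋α/₂) with case fraction k and instrument R².
Everything is estimated on the log-odds-per-SD scale and exponentiated only
for reporting.

## Worked example

`python examples/01_full_analysis.py` simulates a null-effect outcome GWAS
at the PD case-control scale (13,708 cases / 95,282 controls) around the
packaged urate instrument — with 30% of rows strand-flipped and 20%
allele-swapped — and runs the full pipeline:

```
SNPs shared between exposure and outcome: 31
SNPs retained after harmonization:        31
  unchanged: 22
  allele_swap: 3
  strand_flip: 3
  strand_flip_and_swap: 2
  palindromic_kept: 1

Pooled causal estimates (OR per 1-SD increase in exposure):
  IVW   OR 0.97 (95% CI 0.89-1.07); p = 0.57
  EGGER OR 0.95 (95% CI 0.83-1.09); p = 0.50
        intercept 0.00 (95% CI -0.01 to 0.01; p = 0.70)
  PWM   OR 0.95 (95% CI 0.84-1.07); p = 0.43

Heterogeneity: Cochran's Q = 17.20 (df = 30, p = 0.97)
Leave-one-out (ivw): OR range 0.96-1.00

Power at OR 1.10 per SD (R^2 = 0.07, alpha = 0.05): 0.79
Minimum detectable OR at 80% power: <0.91 or >1.10
```

Read: harmonization reconciled every scrambled allele coding (the one
palindromic C/G SNP via its allele frequencies); all three estimators agree
on an OR near 1.00 with CIs covering the simulated null; the Egger
intercept near 0 shows no directional pleiotropy; Q is unremarkable against
its 30 degrees of freedom; and a design of this size has ~79% power to
detect a 10% risk change per SD of exposure. The same pipeline runs on real
files with `mrkit analyze --exposure ... --outcome ... --out ...`.

The other examples demonstrate harmonization rules (`02`), power
calculations (`03`), and a Monte-Carlo comparison of the three estimators
across pleiotropy regimes (`04`).

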