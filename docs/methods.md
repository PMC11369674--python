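# Methods

## Setting and assumptions

The package implements summary-data Mendelian randomization (MR): genetic
variants serve as instruments for an exposure, and causal effects are
estimated from per-variant GWAS association statistics alone. Validity rests
on the three classical instrument assumptions — each variant is (1) robustly
associated with the exposure, (2) independent of exposure–outcome
confounders, and (3) affects the outcome only through the exposure. The
estimators degrade in characteristic ways when (3) fails: IVW is biased by
any net pleiotropy, MR-Egger remains consistent under directional pleiotropy
that is independent of instrument strength (InSIDE), and the median
estimators tolerate up to half the weight coming from invalid instruments.
The two-sample design additionally assumes non-overlapping cohorts drawn
from the same population; the synthetic generator reproduces exactly this
setting (independent noise across traits).

Binary outcomes are handled on the log-odds scale throughout; every estimate
is also reported as OR = exp(β) with a 95% Wald CI.

## Harmonization

Variants are matched across traits by variant ID only — no position-based
rescue, which keeps the matching rule auditable. Outcome effects are
re-expressed relative to the exposure's effect allele, flipping the beta sign
and EAF when labels are swapped directly or on the opposite strand.
Palindromic variants (A/T, C/G) carry no strand information in their labels,
so they are retained only when both cohorts' aligned EAFs fall on the same
side of 0.5 **and** outside [limit, 1 − limit]; the default limit 0.42 is a
convention (a free parameter, not an estimate) — frequencies within ±0.08 of
0.5 are considered too close to call. Variants with missing EAF are retained
for non-palindromic matching but excluded (with a warning) from any r²/F
computation that needs MAF.

## Instrument strength

Per-variant variance explained uses r² = 2·MAF·(1−MAF)·(β/SD)² with
SD = SE·√N. The unsquared variant of this formula circulates in the applied
literature; because it is dimensionally inconsistent for a variance share,
the squared form is the default, and a `paper_verbatim` mode reproduces the
unsquared expression for comparability with reports that used it. The F
statistic is ((N−K−1)/K)·(r²/(1−r²)). Per-variant F uses K = 1 with that
variant's r² (the single-instrument convention, matching per-SNP F
filtering at F > 10); a joint F with K = panel size and summed r² is also
reported, since both readings of the formula appear in practice.

LD clumping is greedy: keep the remaining variant with the smallest p-value,
discard same-chromosome variants within the window having r² above the
threshold, repeat. Ties on p are broken by chromosome, position, then
variant ID, making the result independent of input order. Cross-chromosome
pairs are never clumped regardless of the supplied matrix.

## Estimators and numerical choices

- **IVW** is fit as weighted least squares of β̂ᵧ on β̂ₓ through the origin
  with weights 1/σᵧ² (the closed-form ratio of sums is asserted against this
  regression formulation in the tests). The default model is multiplicative
  random effects for ≥ 3 variants — SE inflated by √max(1, Q/(n−1)) — and
  fixed effect otherwise, mirroring dominant MR-software behaviour. One
  variant delegates to the Wald ratio with first-order SE σᵧ/|β̂ₓ|.
- **MR-Egger** re-signs each variant so β̂ₓ ≥ 0 before fitting (the
  orientation the intercept test is defined under; results depend on it, so
  it is fixed explicitly). SEs carry the same multiplicative scale
  max(1, √(RSS_w/(n−2))).
- **Medians**: per-variant ratios weighted by the inverse first-order ratio
  variance σᵧ²/β̂ₓ², estimate = weighted 50th percentile with linear
  interpolation over cumulative normalized weights (each observation at its
  cumulative weight minus half its own). SEs come from a seeded parametric
  bootstrap (default 1000 draws of β̂ₓ, β̂ᵧ from their normal errors,
  weights recomputed per draw); identical seeds are bit-reproducible.
- **P-values** use the standard-normal reference, the usual summary-data
  convention, not t.
- **Cochran's Q** is centred on the fixed-effect IVW estimate (the standard
  definition) with ratio weights β̂ₓ²/σᵧ²; p from χ²(n−1).
- **MVMR** regresses outcome effects on the exposure-effect matrix without
  intercept, weights 1/σᵧ² (outcome SEs only); measurement error in exposure
  effects is ignored, as in standard summary-data MVMR — both stated
  limitations. An exposure whose effects are identically zero across the
  selected instruments yields a zero coefficient (infinite SE) rather than a
  singular design; genuinely collinear exposures raise an error naming them.

## Mediation decomposition

indirect = a·b, direct = c − a·b (exact identities), proportion = a·b/c,
signed. Uncertainty via the delta method assuming independence of the three
estimates: var(a·b) ≈ a²·var(b) + b²·var(a), var(ab/c) ≈ var(ab)/c² +
(ab)²·var(c)/c⁴; a seeded Monte-Carlo propagation (normal resampling of a,
b, c, percentile interval) is provided as an alternative. The independence
assumption is only approximate when c and a share instruments, but the
shared component is the exposure-side noise, which is second-order for
strong instruments.

Classification: *masking* when the indirect effect is nominally significant
and opposes the total effect's sign (total also significant), *mediation*
when aligned and significant, *none* otherwise. When SEs are unavailable —
e.g. re-entering printed point estimates — classification falls back to the
sign rule alone. With c = 0 the proportion is undefined and the
classification is *none* (no total-effect sign to compare against). Table
writers print |proportion| with the masking flag, since magnitudes are the
conventional presentation for masking rows; the signed value is kept
alongside.

`b` is estimated by univariable mediator→outcome MR by default; an option
excludes the exposure's instruments from the mediator's set
(`disjoint_instruments`), and MVMR-adjusted direct effects are available
separately through the MVMR stage.

## Screening workflow

Forward screens flag traits whose primary (IVW) p-value beats α = 0.05 —
raw p-values by default, matching the common screening convention; an
optional Benjamini–Hochberg mode (scipy's implementation) is clearly
non-default. Triplets enter mediation only when all three links
(exposure→outcome, exposure→mediator, mediator→outcome) pass α. The manifest
records package version, all thresholds, the seed, and a SHA-256 checksum of
every input table; TSVs are written with fixed float formatting so identical
runs are byte-identical.

## Synthetic generator

The generator emulates the summary-level inputs of a two-step mediation
study directly — no individual-level genotypes. Structural model:
exposure instruments with per-variant effects γⱼ, mediator
M = a·X + own genetics + noise, binary outcome Y with log-odds effects
direct·X + b·M + optional per-variant pleiotropy. Marginal GWAS effects
follow the structural identities (γⱼ; a·γⱼ; (direct + a·b)·γⱼ at exposure
variants, and γ_med,j; b·γ_med,j at mediator variants), with estimation
noise added per variant at the standard GWAS scale SE = 1/√(2·MAF·(1−MAF)·N)
independently across the three traits.

Mediator-specific instruments (a second chromosome of variants with direct
effects on the mediator only) are part of the model because the two-step
estimate of b requires instruments for the mediator that do not act through
the exposure; without them the mediator→outcome ratio at exposure variants
identifies c/a rather than b and no decomposition could be recovered. At the
default sample sizes the exposure variants' mediator effects (a·γ) stay
below genome-wide significance, so the mediator's instrument set remains
clean.

Default conditions, chosen once as a realistic desk-scale study: 60 exposure
and 40 mediator instruments; per-variant |effects| uniform on 0.03–0.10 with
random signs (comfortably genome-wide significant at the default cohort
sizes); MAF uniform on 0.05–0.5; cohorts of 100 000 (exposure, e.g. a
lipidomics GWAS), 35 000 (mediator, e.g. a plasma-proteome GWAS) and 500 000
(binary outcome, biobank scale); a = 0.3, b = 0.2, direct = 0.05 on the
log-odds scale, so c = 0.11 and the true proportion mediated is 54.5%; no
pleiotropy and no LD unless requested. The LD matrix is block-diagonal with
constant within-block r², which makes clumping verifiable against a
brute-force oracle. The masking scenario re-signs a·b against the direct
effect and ensures |direct| > |a·b|.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: realistic human LD structure (noise is
independent across variants even inside an LD block; the block matrix only
exercises the clumping machinery), sample overlap between cohorts, winner's
curse beyond simple thresholding, population stratification, case-control
ascertainment (binary effects are generated on the log-odds scale directly),
and imputation artifacts.

## Problem sizes used in the checks

The calibration study uses 2000 replicates of a 50-variant null model
(no causal effect, correct SEs); IVW and Cochran's Q rejection rates at
α = 0.05 land within ±1.5 percentage points of 5%. The recovery study uses
500 replicates of the default mediated model for delta-method CI coverage of
the true proportion, and 200 replicates of the masking scenario for the
classification rate. These sizes give binomial Monte-Carlo error of about
±1–2 percentage points on the reported rates.

## Known limitations

- No proxy-variant lookup, VCF ingestion, or genome-build liftover; variant
  matching is by ID.
- No mode-based or outlier-robust estimators (MR-PRESSO etc.); no conditional
  F-statistics for MVMR; no funnel-plot asymmetry statistics.
- The delta-method proportion CI ignores cross-estimate covariance (see
  above) and can misbehave when the total effect is near zero; the
  Monte-Carlo interval is the safer choice there.
- Screening uses raw p-values by default; with hundreds of traits the
  expected number of false selections is α × (number of null traits).
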