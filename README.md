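# mrmediate

Two-sample, multivariable and two-step **mediation Mendelian randomization**
(MR) on GWAS summary statistics — built for studies that ask how much of an
exposure's effect on a disease outcome is routed through a molecular
mediator, e.g. how much of a lipid species' effect on deep venous thrombosis
(DVT) is transmitted by a circulating inflammatory protein. A synthetic
three-trait GWAS generator with a known structural model makes every stage of
the workflow testable without downloading any real GWAS.

## What it computes

MR uses genetic variants as instruments for an exposure X. With per-variant
exposure effects β̂ₓⱼ (SE σₓⱼ) and outcome effects β̂ᵧⱼ (SE σᵧⱼ) from two
independent cohorts, the per-variant causal estimate is the Wald ratio
β̂ᵧⱼ/β̂ₓⱼ, and the package provides:

- **Instrument handling** — genome-wide-significance selection (P < 5×10⁻⁸),
  greedy LD clumping (r² = 0.001 within 5 000 kb), allele harmonization with
  frequency-based resolution of palindromic variants, per-variant variance
  explained r² = 2·MAF·(1−MAF)·(β/SD)² and the instrument-strength statistic
  F = [(N−K−1)/K]·[r²/(1−r²)], filtered at F > 10.
- **Estimators** — IVW (weighted regression of β̂ᵧ on β̂ₓ through the origin,
  weights 1/σᵧ²; fixed or multiplicative random effects), MR-Egger (free
  intercept; the intercept tests directional pleiotropy), weighted and simple
  median (robust to up to half the weight coming from invalid instruments).
  Results are reported as log-odds, OR = exp(β) and 95% CI.
- **Diagnostics** — Cochran's Q heterogeneity test, the Egger-intercept
  pleiotropy test, and leave-one-out re-estimation with sign/significance
  flags.
- **Multivariable MR** — joint direct effects of several exposures by
  weighted regression of outcome effects on the exposure-effect matrix.
- **Two-step mediation** — with total effect c (exposure→outcome),
  a (exposure→mediator) and b (mediator→outcome): indirect = a·b,
  direct = c − a·b, proportion mediated = a·b/c with a delta-method (or
  Monte-Carlo) CI, and a mediation-vs-masking classification (masking when
  the indirect effect significantly opposes the total effect).
- **Screening workflow** — forward screens of many exposures/mediators,
  reverse-causation screens, triplet formation, mediation decomposition and
  MVMR, orchestrated from one config with byte-reproducible outputs.

## Worked example

`examples/02_mediation_decomposition.py` re-enters published-style point
estimates (c, a, b) for six lipid → inflammatory-protein → DVT triplets and
prints:

```
     exposure mediator   indirect     direct  abs_proportion_pct classification
PC(17:0/20:4)    SIRT2 -0.0001044  0.0016044                6.96        masking
PC(18:0/20:4)    SIRT2 -0.0001056  0.0014056              8.1231        masking
PC(14:0/18:2)    CCL20  0.0001407 -0.0015407               10.05        masking
PC(15:0/18:2)    CCL20  9.345e-05 -0.0012934              7.7875        masking
PC(18:0/20:5)    CCL20 -0.0001134  0.0017134              7.0875        masking
    TAG(58:7)    CCL20  0.0001785  0.0012215               12.75      mediation
```

For TAG(58:7) the indirect effect 0.085 × 0.0021 = 0.0001785 is 12.75% of the
total effect 0.0014: CCL20 transmits about an eighth of that lipid's effect
on DVT risk. The five "masking" rows have an indirect effect whose sign
opposes the total effect, so the protein hides part of the direct effect
instead of explaining it.

`examples/01_simulate_and_estimate.py` runs every estimator on a simulated
study (true total effect 0.11; IVW prints 0.1078 ± 0.0048, Egger intercept
−0.0007, Q p = 0.125) and `examples/03_screening_workflow.py` runs the full
workflow end to end (estimated proportion mediated 47.7%, 95% CI
40.2–55.3%, against a true value of 54.5%).

A thin CLI mirrors the workflow for shell use:

```bash
mrmediate simulate --seed 1 --out sim/
mrmediate instruments --sumstats sim/exposure.tsv --ld sim/ld.tsv
mrmediate run --config config.yaml
```

## Layout

- `src/mrmediate/` — `sumstats` (I/O + harmonization), `instruments`,
  `estimators`, `sensitivity`, `mvmr`, `mediation`, `screening` (workflow),
  `simulate` (synthetic generator), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
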