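# Methods

## Model and assumptions

The package implements two-sample summary-statistic Mendelian randomization.
For variant j, let β_Xj be its effect on the exposure and β_Yj its effect on
the outcome, estimated in non-overlapping samples. Under the instrumental
variable assumptions (relevance, exchangeability, exclusion restriction) the
generative model is

    β_Yj = θ · β_Xj + α_j + ε_j,   ε_j ~ N(0, σ²_Yj),

where θ is the causal effect of the exposure on the outcome (log-odds scale
for binary traits, SD scale for quantitative ones) and α_j is a
horizontal-pleiotropy term that is zero for a valid instrument. Every
estimator in the package is a different compromise about α_j:

- **IVW** assumes α_j = 0 for all j; it is the efficient weighted
  least-squares slope through the origin and the primary estimator.
- **MR-Egger** allows a systematic (directional) component E[α_j] = α₀,
  provided α_j is independent of β_Xj (InSIDE); the intercept estimates α₀.
- **Weighted median** is consistent as long as variants carrying at least
  half the inverse-variance weight are valid, regardless of how the rest
  misbehave.

Two-step mediation composes three such analyses. With a the
exposure→mediator effect, b the mediator→outcome effect (estimated from the
mediator's own instruments), and T the total exposure→outcome effect, the
indirect effect is a·b and the mediated proportion a·b/T. The closed-form
truth for a simulated chain with direct effect c′ is a·b/(a·b + c′).

## Estimation details and numerical choices

- **Wald ratio SE**: first order, σ_Yj/|β_Xj|, matching common two-sample MR
  practice; a second-order delta-method option
  √(σ²_Yj/β²_Xj + β²_Yj σ²_Xj/β⁴_Xj) is available by flag. First-order
  weights are used consistently in IVW, Cochran's Q, and the weighted median.
- **Random-effects IVW** uses multiplicative overdispersion: the fixed SE is
  scaled by max(1, √(Q/(J−1))). `mode="auto"` (default) switches to random
  effects when the Q p-value < 0.05, mirroring the convention of applying
  random effects only when heterogeneity is detected. IVW p-values are
  normal; Egger p-values use t with J−2 df.
- **MR-Egger** orients every pair so β_Xj ≥ 0 before regression (the fit is
  invariant to joint negation of a pair), weights by 1/σ²_Yj, and floors the
  multiplicative overdispersion at 1. No SIMEX/measurement-error correction
  is applied.
- **Weighted median** uses the interpolated cumulative-percentile definition
  p_j = 100·(S_j − w_j/2)/S_total on the sorted ratios and linear
  interpolation at the 50th percentile. Its SE is a seeded parametric
  bootstrap (default 1,000 replicates) resampling β_Xj and β_Yj from their
  sampling distributions.
- **Cochran's Q** is evaluated at the fixed-effect IVW estimate (its
  minimiser) with χ²(J−1) reference; q_df is always J−1.
- **MR-PRESSO** follows the residual-sum-of-squares simulation scheme:
  leave-one-out IVW predictions, simulated outcome betas under the null,
  empirical p-values with the add-one convention (1+#{sim ≥ obs})/(1+n_sim)
  so p ≥ 1/(n_sim+1), per-variant outlier tests Bonferroni-adjusted by J,
  and a distortion test whose null resamples same-size subsets from the
  non-flagged variants (resampling from all variants would let the outlier
  itself enter the null and mask real distortion). With the default
  n_sim = 1,000 the adjusted outlier-p floor is J/1001, so outlier flagging
  requires n_sim to be raised for analyses with more than ~50 instruments.
- **Leave-one-out influence** flags a variant when its removal flips the
  sign of the IVW estimate or moves its p-value across 0.05 from a
  significant full-set result; flagged variants are reported, never
  auto-removed.
- **Harmonization** resolves swapped and strand-complemented alleles by a
  truth table; palindromic (A/T, C/G) variants are undecidable from alleles
  and are dropped outright (`drop_all`) or frequency-aligned with an
  ambiguity window (`drop_ambiguous`, default): dropped when either
  effect-allele frequency is missing or falls in [0.42, 0.58], otherwise
  aligned by which side of 0.5 both frequencies sit on. The window is a
  configurable convention — the underlying studies state only that ambiguous
  palindromes are excluded, not the rule.
- **LD clumping** is greedy on ascending p-value with ties broken by
  (chromosome, position, variant id) so output is independent of input
  order. The window is ±window_kb around the index variant. A within-window
  pair lacking an r² entry is an error by default (silently assuming r²=0
  would fabricate independence); a permissive flag downgrades it to a
  warning.
- **Mediation CIs**: the delta method is the default
  (se(a·b) = √(a²se_b² + b²se_a²); first-order propagation for the ratio
  a·b/T). A seeded parametric bootstrap (10,000 draws) over (a, b, T) is
  offered because the published interval for the mediated proportion is not
  reproduced by the plain delta method and the original CI construction is
  unstated; neither method is claimed to match it. The bootstrap CI
  converges to the delta CI as the SEs shrink. Opposite-sign
  (inconsistent-mediation) proportions are flagged, not truncated.
- **Eligibility gates**: a mediation claim requires both steps significant
  with an indirect-effect sign matching the total, a non-significant
  reverse-direction estimate, and no heterogeneity/pleiotropy/influence flag
  on any of the three analyses; every failed gate is named.
- **BH-FDR** is the step-up procedure applied separately within each
  screening family (exposure→taxa, taxa→outcome, taxa→exposure), since a
  microbiome-wide family is otherwise ill-defined; per-trait headline rows
  report both raw p (the gate used for printed taxa) and q.

## Synthetic data

The generator emulates the statistical structure the MR toolchain assumes,
at the scale of the consortia whose tables the formats mirror: exposure GWAS
n = 200,000 (biobank-scale disease GWAS), mediator GWAS n = 18,340
(16S microbiome consortium scale), outcome GWAS n = 50,000 (disease
case-control meta-analysis scale). Per variant: effect-allele frequency
~ U(0.05, 0.95); SEs 1/√(n·2f(1−f)); latent instrument effects
~ N(0.15, 0.03) (F ≫ 10 at these sample sizes); observed betas add
N(0, se²) noise; outcome betas follow the generative model above. Pleiotropy
modes: none, balanced (mean-zero), directional, and InSIDE-violating (α_j
correlated 0.5 with β_Xj, for demonstrating Egger failure, not used in
tests). Optional LD blocks share a declared within-block r² and are spaced
30 Mb apart so only within-block pairs fall inside the clumping window;
palindromic variants are drawn with frequencies near 0.5 specifically to
exercise the ambiguity filter. Default instrument counts are 50 per trait
(20 for the outlier preset, 10 per taxon for the null panel, typical of
taxon-level instrument yields at the 1×10⁻⁵ threshold).

What the generator does **not** emulate: realistic LD from reference panels,
allele-frequency-dependent effect sizes, sample overlap between GWAS,
population stratification, winner's-curse selection bias, and the
compositional correlation structure of real taxon abundances. Passing tests
therefore demonstrate correctness of the estimators and pipeline under the
assumed sampling model, not robustness to those real-data complications.

## Experiment suite and problem sizes

`mrmediate.experiments` (used by `scripts/acceptance.py` and the acceptance
tests) runs desk-scale Monte-Carlo batteries: 500 replicates for type-I
error and coverage of IVW/Q on the clean J=50 preset; 100 replicates for the
40%-invalid robustness comparison (invalid instruments carry ~10 ratio-SE
units of one-sided pleiotropy, enough to break IVW decisively while leaving
the majority of weight valid); 100 seeded MR-PRESSO spike-in runs; 200
replicated mediation chains with a=0.10, b=0.21, c′=0.14 (true proportion
13.04%); and 200 replicates of a 50-trait all-null panel for FDR control.
These sizes keep Monte-Carlo error comfortably below the decision margins
while the whole battery completes in minutes on one CPU.

Two arithmetic notes on the printed-OR reproduction: ln(1.108)·ln(1.237) =
0.0218, which truncates (rather than rounds) to the published 0.021, while
the derived proportion 13.74% matches the published 13.7% under either
convention; and the published total-effect CI appears once as 1.033–1.329
and once as 1.032–1.332 — the package uses the latter.

## Known limitations

- No multivariable MR, Steiger filtering, radial MR, or
  contamination-mixture/CAUSE estimators.
- LD must be supplied (long-format r² table); the package never computes LD
  from genotypes and does not look up proxy variants.
- The weighted median retains a finite-sample bias of order one ratio-SE
  when invalid weight approaches 50% from below with one-sided pleiotropy;
  this is a property of percentile estimators, not an implementation defect,
  and is visible in the robustness experiment's reported Monte-Carlo
  spread.
- MR-PRESSO outlier flagging is resolution-limited by n_sim (see above).
- Binary-trait betas are treated as log-odds ratios throughout; no
  liability-scale conversion is attempted.
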