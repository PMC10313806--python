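# Methods

## Design

`tsmr` implements two-sample Mendelian randomization: genetic variants serve
as instrumental variables for an exposure, and the causal effect of the
exposure on an outcome is estimated from two independent GWAS
summary-statistics tables. The three instrumental-variable assumptions —
the variant associates with the exposure, shares no confounder with the
outcome, and affects the outcome only through the exposure — are assumed for
the main estimator and probed by the sensitivity analyses. Everything
operates on summary data; no individual-level genotypes are touched.

## Instrument construction

1. **Selection.** Variants with exposure `p < p_threshold` (default
   `5e-7`). The strict inequality matters at the boundary and is tested. The
   default is the suggestive threshold commonly used when a trait has few
   genome-wide-significant hits; it trades instrument validity risk for
   statistical power, which is why the F-statistic screen accompanies it.
2. **Clumping.** Greedy: the most significant remaining variant becomes an
   index SNP, and every remaining variant on the same chromosome within
   `window_kb` (default 1000, closed interval on base pairs) with
   `r² ≥ r2_threshold` (default 0.01) against it is removed. p-value ties
   break by `(chrom, pos, variant_id)` so output is invariant to input row
   order. LD is an explicit caller-supplied matrix — the package never
   selects or downloads a reference panel, since the right panel is an
   ancestry-specific judgement the caller must own. With no LD supplied,
   distance alone removes; that is conservative (never keeps a correlated
   pair) and logged.
3. **Strength.** Per-variant `F = (γ/se_γ)²`, the single-SNP approximation,
   chosen as the default because it needs neither allele frequency nor
   sample size; the explained-variance route
   `F = (n-2)·r²/(1-r²)`, `r² = 2·maf(1-maf)·γ²` is available when `eaf` and
   `n` are present. `F > 10` is the conventional weak-instrument screen and
   is reported, not enforced.

## Harmonization

Both files are aligned to the exposure's effect allele. Allele-order swaps
negate the outcome beta and complement its EAF; reverse-complement pairs are
strand flips and change nothing numerically; the combination does both.
Matching is by variant ID only — chr:pos fallback matching can silently pair
records across genome builds, which is worse than dropping.

Palindromic variants (A/T, C/G) are their own reverse complement, so allele
labels carry no strand information. They are dropped when the minor-allele
frequency exceeds the ambiguity band (default 0.40, i.e. EAF in
(0.40, 0.60)) in either dataset, or when either EAF is missing. Outside the
band the two strand hypotheses imply aligned outcome EAFs `x` and `1-x`, of
which exactly one matches the exposure's minor-allele side; that hypothesis
is taken. The band edge is configurable; 0.40 is the standard choice. The
band is interpreted on MAF (two-sided on EAF) rather than one-sided on EAF —
the one-sided reading would keep variants whose frequencies are equally
uninformative about strand.

Dropped instruments stay in the output with their drop reason, so
`retained + dropped` always equals the instrument count in (tested as a
conservation law).

## Estimators

Let `γ_i ± se_γi` and `α_i ± se_αi` be the aligned per-variant effects.

- **Wald ratio**: `β̂ = α/γ`, first-order delta SE `se_α/|γ|`; the
  second-order option adds `α²se_γ²/γ⁴` and is validated against a 10⁶-draw
  Monte Carlo of the ratio distribution.
- **IVW**: ratio form with weights `w_i = γ_i²/se_αi²`, verified to 1e-10
  against independently fitted WLS-through-the-origin. Fixed-effect SE
  `1/√Σw`; multiplicative random-effects SE inflated by `max(1, √(Q/df))`.
  Both are emitted — the point estimate is identical, and reporting both
  makes the heterogeneity penalty visible.
- **MR-Egger**: weighted regression with intercept after canonically
  re-orienting instruments to `γ ≥ 0` (negating γ and α jointly), without
  which the intercept — the mean directional pleiotropic effect under
  InSIDE — is not interpretable. Coefficient covariance uses a
  multiplicative overdispersion scale bounded below by 1 (under-dispersion
  is never credited). Normal CIs by default; t-based (df = n−2) behind a
  flag.
- **Medians**: ratios sorted, weighted median taken where cumulative
  normalized weight crosses 0.5 with linear interpolation between bracketing
  ratios (midpoint convention `cum_i = Σ_{j≤i} w_j − w_i/2`). SE is the SD of
  `n_boot` (default 1000) parametric-bootstrap replicates redrawing both γ
  and α from their sampling distributions; the seed is mandatory, making
  every bootstrap bit-reproducible.
- **Cochran's Q** about the fixed-effect IVW estimate with the same weights;
  upper-tail chi-square on n−1 df.
- **Pleiotropy RSS test** (simplified MR-PRESSO: global + outlier test, no
  distortion test): observed statistic
  `RSS = Σ_i (α_i − β̂₋ᵢγ_i)²/se_αi²` with `β̂₋ᵢ` the leave-one-out IVW
  estimate; the residual weights are `1/se_αi²` because the sampling
  variance of `α_i − βγ_i` at fixed γ is `se_αi²`. The null distribution is
  built from `n_sim` parametric draws `α*_i ~ N(β̂₋ᵢγ_i, se_αi)` with the
  leave-one-out estimates recomputed per draw; `global_p = (1 + #{RSS* ≥
  RSS}) / (n_sim + 1)`, per-variant analogues Bonferroni-flagged at
  `outlier_alpha/k`. Calibration (null rejection ≈ 5%) is checked by
  simulation in the acceptance suite.

All 95% CIs use the 1.96 normal multiplier; ORs and their bounds are the
exponentials of the beta-scale values, computed at full precision and
rounded only at the presentation layer. P-values are floored at the smallest
positive double rather than reported as 0.

No multiple-testing correction is applied across traits or methods; nominal
p-values are reported and any correction is left to the analyst.

## Synthetic data generator

`simulate_pair` draws, per variant: `maf ~ U(maf_range)`,
`γ ~ N(0, gamma_sd²)`, direct effect `δ ~ N(pleiotropy_mean,
pleiotropy_sd²)` on an exact-count random subset of `round(pleiotropy_fraction
· n_snp)` variants (exact count rather than Bernoulli, so a "30% invalid" or
"one planted outlier" scenario holds by construction), and
`α = true_beta·γ + δ`. Standard errors follow
`se = 1/√(2·N·maf(1−maf))`; observed effects add independent noise on each
side, enforcing the two-sample no-overlap assumption. Outcome-side EAF gets
a small estimation wobble (SD 0.005) — realistic, but too small to flip the
minor-allele side of any variant retained outside the palindromic band.

The outcome file is then corrupted the way real consortium files disagree:
allele swaps with `sign_flip_prob`, strand flips with `strand_flip_prob`,
and `palindromic_fraction` of variants carrying A/T or C/G pairs. Every
change is recorded in a truth manifest (including the pre-corruption outcome
beta), which is what lets the test suite demand *exact* — not approximate —
recovery by harmonization.

Defaults encode the study conditions the pipeline is exercised under: 50
variants, `true_beta = 0.2`, exposure GWAS n = 186,689 (a large PTSD
symptom-severity GWAS), outcome n = 440,328 (a large ischemic-stroke
case-control meta-analysis, 34,217 cases + 406,111 controls), maf
U(0.05, 0.5), `gamma_sd = 0.05` (suggestive-threshold effect sizes at that
exposure sample size), corruption probabilities 0.25/0.10/0.20 — a
realistic mix of coding disagreements between two consortia.

Variants sit on one synthetic chromosome in LD blocks: 10 kb spacing within
a block (inside any sane clumping window), 10 Mb between blocks (outside
it), with `simulate_ld_blocks` emitting the matching block-diagonal r²
matrix. What the generator deliberately does not model: realistic LD decay,
liability-threshold binary traits (binary-outcome betas are generated
directly on the log-odds scale), winner's curse in instrument selection,
allele-frequency differences between populations, and sample overlap.
Passing tests therefore demonstrate estimator and plumbing correctness under
the stated model, not robustness to those real-data features.

## Calibration experiments

The statistical validation suite (`tests/test_acceptance.py`,
`scripts/acceptance.py`) uses an exposure GWAS of 500,000 with
`γ ~ N(0, 0.1²)` so that weak-instrument dilution (of order
`se_γ²/var(γ)` ≈ 0.05%) stays below the Monte-Carlo resolution of the
experiments; the outcome side keeps the 440,328 stroke scale. Problem sizes:
1000 replicates for recovery/coverage, 2000 for type-I error, 300 for the
Egger intercept, 200 for median robustness, 500 (at 200 null simulations
each) for RSS-test calibration. Directional-pleiotropy experiments draw
positive γ (U(0.05, 0.15)): a directional direct effect is only defined
relative to the exposure-increasing allele orientation, and with symmetric γ
the planted ratio offsets would partially cancel and the scenario would no
longer be directional.

## Pipeline behaviour

- A trait pair with zero surviving instruments produces a failed results row
  with the reason, never an exception — multi-trait batches keep going.
- One instrument → Wald ratio; ≥ 2 → IVW (+ Q); ≥ 3 → Egger and medians;
  ≥ 4 → the RSS pleiotropy test.
- The reverse analysis reuses identical thresholds with trait roles swapped
  (an assumption, since nothing forces reverse-direction thresholds to
  match; it keeps the two directions comparable).
- Runs are deterministic end-to-end under the config seed; the config is
  echoed verbatim into the output directory, logs go to stderr and
  `run.log`, results only to the results tables.

## Known limitations

- Simplified MR-PRESSO: no distortion test, and the empirical p floors at
  `1/(n_sim+1)`.
- No proxy-SNP substitution for instruments missing from the outcome file,
  no multi-allelic handling, no Steiger filtering or multivariable MR.
- The delimiter and column layout must be declared (no sniffing) — a
  deliberate reproducibility choice.
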