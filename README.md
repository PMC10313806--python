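# tsmr — two-sample Mendelian randomization from GWAS summary statistics

`tsmr` estimates the causal effect of an exposure on an outcome from two
independent GWAS summary-statistics files, the design used to ask questions
such as whether genetic liability to post-traumatic stress disorder (PTSD)
symptom phenotypes affects ischemic stroke risk. It is aimed at
genetic-epidemiology analysts who have per-variant association tables (effect
sizes, standard errors, alleles, frequencies, p-values) for two traits
measured in non-overlapping samples and want a reproducible
selection → harmonization → estimation → sensitivity pipeline, plus a
synthetic-data generator with known causal truth for validating every stage.

## The model

Each instrument *i* is a variant with association `γ_i ± se(γ_i)` on the
exposure and `α_i ± se(α_i)` on the outcome. Under the instrumental-variable
assumptions (relevance, no confounding, exclusion restriction), every valid
instrument satisfies `α_i = β γ_i`, and:

- **Wald ratio** (single instrument): `β̂ = α/γ`, `se = se(α)/|γ|`.
- **IVW**: `β̂ = Σ w_i (α_i/γ_i) / Σ w_i` with `w_i = γ_i²/se(α_i)²` —
  identically weighted least squares of α on γ through the origin.
  Fixed-effect `se = 1/√(Σ w_i)`; the multiplicative random-effects variant
  scales it by `max(1, √(Q/df))`, with `Q` Cochran's heterogeneity statistic.
- **MR-Egger**: the same weighted regression with a free intercept; the
  intercept estimates the mean directional pleiotropic effect (under
  InSIDE), the slope remains a consistent causal estimate.
- **Simple / weighted median**: the (inverse-variance-)weighted median of
  the per-variant ratios, consistent when ≥ 50% of the weight is on valid
  instruments; SE from a seeded parametric bootstrap.
- **Pleiotropy RSS test** (MR-PRESSO-style): leave-one-out residual sum of
  squares with a simulated null, giving a global p-value and per-variant
  outlier flags.

For a binary outcome `exp(β̂)` is the odds ratio per unit (1 SD) of
genetically predicted exposure.

Instruments are selected at `p < 5×10⁻⁷` (a suggestive threshold useful when
few variants are genome-wide significant), greedily clumped (1000 kb window,
`r² < 0.01`, caller-supplied LD matrix), and screened with per-variant
F-statistics (`F = (γ/se)²`; F > 10 conventional). Harmonization aligns both
files to one effect allele, undoing allele swaps and strand flips, and drops
palindromic (A/T, C/G) variants whose minor-allele frequency exceeds 0.40 in
either file.

## Worked example

Simulate a pair of GWAS linked by a true causal effect of 0.2 (log-odds per
SD), then run the full pipeline:

```bash
tsmr simulate --n-snp 50 --gamma-sd 0.1 --true-beta 0.2 --seed 1 --out sim/
tsmr run --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
         --seed 1 --out mr_out/
```

The forest table printed at the end (also in `mr_out/forest_table.tsv`):

```
   ancestry exposure outcome direction          method  n_snp               or_ci     p_str
unspecified exposure outcome   forward           egger     40 1.24 (1.221, 1.260) 4.22e-154
unspecified exposure outcome   forward       ivw_fixed     40 1.23 (1.219, 1.239) 2.23e-308
unspecified exposure outcome   forward         ivw_mre     40 1.23 (1.219, 1.239) 2.23e-308
unspecified exposure outcome   forward   simple_median     40 1.23 (1.214, 1.250) 5.38e-181
unspecified exposure outcome   forward weighted_median     40 1.24 (1.222, 1.251) 9.91e-268
```

40 of the 50 simulated variants pass selection and harmonization; every
method's OR brackets `exp(0.2) ≈ 1.22`, and the agreement between IVW and
the pleiotropy-robust methods is the consistency check one looks for in a
real analysis. `mr_out/results.tsv` holds the full numbers, including the
Egger intercept (≈ 0 here: no directional pleiotropy was simulated),
Cochran's Q and the pleiotropy RSS test, and instrument attrition counts;
`mr_out/harmonized_instruments.tsv` records the per-variant aligned effects
and the harmonization action taken. `tsmr bidirectional` reruns the analysis
with the trait roles swapped to probe reverse causation.

The same pipeline runs on real summary-statistics files: point
`--exposure/--outcome` at the tables, describe non-canonical column layouts
with a small YAML column map (`--exposure-colmap`), and supply an LD matrix
(`--ld-matrix`) for r²-aware clumping.

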