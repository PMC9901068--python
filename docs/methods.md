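# Methods notes

This note records the modelling assumptions, parameter choices and
numerical decisions behind `twaskit`, in the spirit of a simulation
study's methods appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## What the synthetic generator emulates

The generator reproduces the *statistical shape* of a post-GWAS ALS
integration study, not its biology:

- **TWAS/PWAS tables.** Signal genes (default 10% of 500) carry
  Z ~ Normal(direction × |N(0, 5)|, 1) per panel; null genes are
  standard normal; p is the exact two-sided tail of Z. Panels
  alternate FUSION/SMR and cycle blood/brain tissue classes. A
  `prop_coloc` subset (default 0.6) of signal genes receives
  colocalisation support: the ratio PP4/(PP3+PP4) is drawn directly in
  (0.9, 0.995) with PP4 > 0.8 and HEIDI p > 0.05, while non-coloc rows
  draw the ratio in (0.05, 0.75), so the strict >0.8 rule partitions
  exactly along the planted flag. This makes the calling rules
  testable with zero ambiguity; real posterior probabilities are
  noisier.
- **Reference panel.** Variants are unlinked binomial draws with
  MAF ~ Uniform(0.05, 0.5). LD realism is deliberately absent:
  clumping operates on *predicted-expression* correlation, which is
  induced by near-duplicate weight vectors across panels
  (`cross_panel_similarity`, default 0.5 — the probability a
  duplicated gene's second panel model is essentially the same model),
  spanning correlations from ~0 to ~1.
- **Expression cohorts.** Two cohorts named for the two array
  platforms of a public ALS case-control expression series, default
  300+300 samples each, log2-scale values Normal(gene baseline, 1).
  Cases shift by ±`de_effect_size` (standardized units) on signal
  genes: along the TWAS direction for a `prop_concordant` subset
  (default 0.8), opposite for the rest — creating the
  concordant/discordant structure the final analysis stage measures.
  Microarray artefacts (probe effects, batch, heteroscedasticity) are
  not modelled, so passing tests demonstrate correctness of the
  statistics, not robustness to array noise.
- **Phenotypes.** Sex ~ Bernoulli(0.5); site of onset is bulbar with
  probability 0.3 among cases; age at onset ~ Normal(60, 10) years;
  survival is uncensored log-normal (median 3 years). Survival and
  onset phenotypes are generated null (no PTS coupling) — the clinical
  outcomes exercise the regression machinery, not a planted effect.
  Censoring is intentionally out of scope; survival enters a linear
  regression as a positive continuous outcome.
- **Drug database.** Each drug has one ATC level-3 code and
  Poisson-many gene targets (mean 4, floored at 1). Protective drugs
  (default 10%) draw ~80% of targets from signal genes and oppose the
  gene's risk direction with probability 0.9; their labels come from
  the directional vocabulary, others mix directional and
  non-directional labels. Protective drugs are concentrated into
  `n_enriched_atc` groups (default 2) so the class-level Wilcoxon has
  a true positive to find.

Every output is a pure function of (config, seed); stages draw from
independent seed streams so regenerating one stage never perturbs
another. Coordinates are 1-based inclusive everywhere.

## Key thresholds and defaults

| parameter | default | note |
|---|---|---|
| FDR threshold | q < 0.05 | BH within method × molecular type, panels pooled |
| coloc rule | PP4/(PP3+PP4) > 0.8 | strict inequality |
| HEIDI rule | p > 0.05 | strict inequality |
| clump | r > 0.95 within 500 kb | greedy, ascending p |
| window anchor | gene start | midpoint available; anchor choice is unstated in the source convention, both supported |
| p-value grid | 1e-6 … 1 (8 points) | reported optimum is optimism-prone and flagged |
| prevalence K | 1/300 (case-control), 0.5 (onset) | liability conversion |
| drug filter | ≥ 2 genes with statistics | counted after dropping genes without TWAS rows |
| ATC filter | ≥ 5 drugs per group | per enrichment method |

## Numerical and design decisions

- **Clumping units are (gene, panel) pairs**, since duplicate-gene
  averaging happens *after* clumping; same-gene cross-panel units may
  remove each other. Ties in p break on larger |Z|, then lexicographic
  (gene, panel) — deterministic. Pairs outside the window are r = 0
  (never clumped together). Units lacking any correlation entry are
  retained with a warning.
- **Liability conversion** uses the Lee et al. (2012)
  ascertainment-corrected closed form; with t the upper-K normal
  quantile, z = φ(t), m = z/K, C = K(1−K)/z² · K(1−K)/(P(1−P)) and
  θ = m(P−K)/(1−K) · (m(P−K)/(1−K) − t), the conversion is
  C·R²/(1 + C·θ·R²). At K = P it is exactly linear with slope C.
- **R²_obs is the incremental R²** of the PTS over the covariate-only
  (sex) model. Binary outcomes stay in OLS because the liability
  transform presumes an observed-scale linear R². Coding:
  control/spinal = 0, case/bulbar = 1.
- **Expression standardization** uses the n−1 denominator and is
  always within cohort; platforms are never pooled before
  meta-analysis.
- **The directional drug test** is a documented GLS surrogate for
  directional gene-set enrichment: gene-level TWAS Z over the full
  universe of genes with statistics is regressed on the drug's coded
  direction vector (0 off-target, matching the 0 code for
  non-directional evidence), with error covariance equal to the
  predicted-expression correlation matrix (identity off known pairs,
  ridge-stabilized if singular). Regressing over the whole universe
  rather than each drug's few targets gives the slope test n−2
  degrees of freedom, keeps 2-gene drugs testable, and makes the null
  calibration exact; the p-value uses the t reference. The reported
  enrichment Z is the negated slope statistic so positive = predicted
  risk reduction. It preserves directionality and
  correlation-awareness but is not claimed to be bit-compatible with
  any external mixed-model implementation; drug p-values are floored
  at 1e-300 to stay in (0, 1] for BH.
- **ATC Wilcoxon** uses scipy's exact Mann-Whitney null for small
  untied samples and the tie-corrected normal approximation otherwise;
  the signed group Z for the two-sided directional test is recovered
  from the p-value and the direction of the U statistic.
- **DE meta-analysis** pools per-cohort Pearson correlations on the
  Fisher-z scale with weights n−3 (raw-r pooling available behind a
  flag for sensitivity); perfect correlations are shrunk to
  ±(1−1e−12) before the transform. The DE correlation is unadjusted
  (no sex covariate), with the covariate option open to callers.
- **Degenerate inputs**: zero-variance predicted expression and
  constant expression rows are dropped with warnings; PP3+PP4 = 0,
  missing HEIDI p on SMR rows, empty credible sets, constant
  outcomes, and non-positive standard errors raise validation errors.

## Validation experiments and problem sizes

The replicated experiments (in `twaskit.experiments`, shared by the
test suite, the acceptance script and the analysis drivers) use these
sizes, chosen to estimate each quantity stably at desk scale:

- clump-oracle agreement: 200 random instances of ≤ 50 units;
- PTS recovery: effects {0, 0.1, 0.2, 0.3, 0.5}, 50 replicates per
  point, two cohorts of 300+300 with 500 genes, fully concordant
  signal; scores use unclumped per-gene averaged weights — the
  generator's variants are unlinked, so cross-locus predicted
  correlation carries no confounding here, and the clump step is
  validated separately against the exhaustive oracle;
- null calibration: 200 replicates (200 genes, 150+150 samples) with
  `de_effect_size = 0`; the analytic null expectation of the
  incremental observed R² for one added regressor is 1/(n−2),
  mapped through the (locally linear) liability transform;
- drug/ATC null: 200 replicates (120 genes, 48 drugs, 8 ATC groups)
  with no TWAS signal and no planted protective drugs;
- protective separation: 50 replicate databases (25% signal genes,
  20% protective drugs).

## Known limitations

- The generator's colocalisation statistics partition cleanly along
  the planted flag; real PP4/HEIDI values straddle the thresholds.
- No LD, probe-level artefacts, batch structure, population
  stratification, or survival censoring.
- The max-R² threshold reported per stratum is optimistic (no
  out-of-sample thresholding); it is flagged, not corrected.
- The directional enrichment test is a surrogate with the documented
  properties, not a reimplementation of any external tool; unsigned
  MAGMA-/GCSC-style statistics are ingested, never recomputed.
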