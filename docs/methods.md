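# Methods

## The screening model

The pipeline compares the *variance* of a gene's expression across
individuals between two age groups.  Let `x_gi` be the preprocessed
log2 intensity of probe *g* in subject *i*.  After sex adjustment
(subtracting the per-sex, per-probe mean), the screen

1. ranks probes by unbiased sample variance across all subjects and
   keeps the top fraction (default 5%; an explicit `k` can override it,
   because a published probe count need not be an exact percentage of
   the working set);
2. tests each kept probe with `F = s²_young / s²_old` against
   `F(n_young − 1, n_old − 1)`, one-sided upper tail — the literal
   reading of "is the young variance ratio greater than 1";
3. adjusts the selected probes' p-values two ways (below) and calls
   significance at pFDR < 0.25 by default;
4. summarizes the selected set with the fraction of probes whose young
   SD strictly exceeds the old SD (ties count as not greater) and a
   Wilcoxon signed-rank test on the paired SD differences.

The F-test assumes normal residuals within each group; on log2
microarray intensities after quantile normalization this is the
standard working assumption.  The unbiased (n−1) variance estimator is
used throughout.

## Preprocessing

Stages run in a fixed order (detection filter → offset/log2 → quantile
normalization → replicate averaging → covariate adjustment), recorded
in the matrix provenance.

- **Detection filter.** A probe is kept when its detection p-value is
  ≤ 0.1 in at least `min_individuals` *unique subjects* (default: half
  the subjects, rounded down).  A subject with duplicate arrays counts
  as detected if any replicate is detected; an all-replicate rule is
  available because the voting convention for replicates is a genuine
  free choice.
- **Offset.** One global constant `c = 1 − min(values)` shifts the
  whole matrix so the smallest intensity is exactly 1.0 before log2;
  a single global constant (rather than per-column offsets) keeps
  between-sample differences intact.
- **Quantile normalization** follows the row-mean-of-sorted-columns
  reference; ties within a column receive the mean of the reference
  values at their tied ranks, making the transform a function of the
  value.  It is applied to log2 values, after the offset.  Note the
  map is idempotent only on tie-free columns; a tied column stabilizes
  from the second application.
- **Replicate averaging** takes the arithmetic mean of a subject's
  arrays and requires covariates to agree across them.
- **Sex adjustment** centers every probe within each sex; "unknown" is
  its own level, so a study with no sex annotation degrades to
  overall-mean centering, and the replication path skips the step
  entirely.

## Multiple testing: FDR vs pFDR

Both adjustments are always computed. `q_bh` is Benjamini–Hochberg
step-up with monotonicity enforcement.  `q_pfdr` multiplies the BH
quantities by an estimate of the null proportion π₀ obtained on the
grid λ ∈ {0, 0.05, …, 0.95} from π₀(λ) = #{p > λ}/(m(1−λ)), smoothed
with a cubic spline and evaluated at λ = 0.95, clamped into (0, 1]
(lower clamp 1/m; a fixed-λ variant is available).  With π₀ estimated
at 1 the two columns coincide; the pFDR column can sit below the raw p
when π₀ < 1, which is expected behaviour, not an error.

## Selection bias of the variance pre-filter

Ranking by pooled variance before the group comparison is not neutral:
pooled variance weights each group by its degrees of freedom, so with
29 young vs 8 old subjects a probe reaches the top of the ranking more
easily when its *young* sample variance ran high.  Under a global null
the proportion of selected probes with `sd_young > sd_old` therefore
centers above 0.5.  `permutation_null_proportion` quantifies this by
permuting group labels (the selected subset is label-invariant and is
computed once); the empirical p-value it returns is the honest null
reference for the headline proportion statistic.  With balanced groups
and no pre-filter the null centers at 0.5 by exchangeability.

## Age-trajectory exclusion

Candidates are refit with `y ~ 1 + age + age² + sex + delay` against
the reduced `y ~ 1 + sex + delay`; the two age terms are tested jointly
with `F = ((SSE_red − SSE_full)/2)/(SSE_full/df_resid)`.  Age is
centered before squaring (the F statistic is invariant to affine age
recoding; centering is purely numerical).  Design choices:

- "potential for developmental delay" is coded as a binary covariate;
  missing values impute to False with a logged warning so the screen
  stays total;
- a nuisance covariate that is constant in the study (single-sex data,
  no delayed subjects) is dropped from both models — it carries no
  information and would otherwise make the design singular; residual
  degrees of freedom adjust accordingly.  A constant *age* is an error,
  since the tested terms themselves vanish;
- degenerate fits use fixed conventions: perfect reduced fit → p = 1
  (no age signal by construction), perfect full fit over an imperfect
  reduced one → p = 0.

## Enrichment

Counting is gene-level: probes collapse to unique gene ids through the
probe→gene map before testing, so a gene with several probes votes
once.  For each term, `K` is its membership intersected with the
universe, `observed = |term ∩ study|`, `expected = n·K/N`, and the
p-value is the upper hypergeometric tail (one-sided: only excess over
expectation is of interest).  The report runs twice — universe = all
present genes and universe = top-variance genes — recomputing `N`, `K`
and p from scratch for each universe.  Terms are flat sets; term-graph
relationships are out of scope.  Terms below `min_term_size` (default
2) are skipped; zero-observed terms stay in the table.

## Replication and validation

`replicate_screen` reruns selection + F-test + summaries on an
external, already-preprocessed log2 matrix with the sex step skipped.
Set overlap is judged against `expected = |A||B|/N` for a user-supplied
shared-gene universe size (the right `N` depends on the platform
intersection and cannot be guessed).  Fisher's exact test uses the
point-probability two-sided rule (sum of table probabilities no larger
than the observed one) — the dominant convention, stated here because
alternatives exist; for 2×2 classifications whose nesting is ambiguous
(is the focal set inside the comparison set?), compute both tables.
qPCR agreement uses Spearman correlation by default because −ΔCt
(defined Ct_reference − Ct_target, increasing with expression) need
only be monotone in the log2 microarray signal; significance is called
at p < 0.05.

## The synthetic-data generator

The generator emulates the motivating study design: 29 young subjects
with ages uniform on [0.5, 14.5] years and 8 old subjects on [15, 53]
(the source material gives an age *range*, not a distribution, so
uniform is the neutral choice), three subjects arrayed in duplicate
(40 arrays, 37 biological samples), ~10% of probes unexpressed.
Per-probe log2 signal is

```
x_gi = μ_g + β_sex,g·male_i + γ1_g·a_i + γ2_g·a_i² + ε_gi,
ε_gi ~ N(0, σ_{g, group(i)})
```

with gene classes: `null` (σ_young = σ_old = base_sd, default 0.25),
`dv` (σ_young = sd_ratio·σ_old, sd_ratio default 3, 5% of genes),
`dev` (quadratic trajectories with ~0.5–1.5 log2-unit amplitude over
the age span, 2%), `sex` (|β| ∈ [0.3, 0.8], 2%).  Class assignment is
disjoint.  Baselines μ_g ~ N(7, 2); sexes Bernoulli(0.5) per subject;
a developmental-delay flag Bernoulli(0.25), plausible for a
surgical-resection cohort.  Raw intensities are `2^x` plus half-normal
background (scale 0.5) so values can dip below 1 and exercise the
offset stage.  Arrays add N(0, technical_sd) technical noise (default
0.1), so duplicate columns of one subject differ by a mean-zero
technical difference.  Detection p-values are Uniform(0, 0.05) for
expressed probes and Uniform(0, 1) otherwise.

A single RNG stream with fixed draw order — probe parameters, subject
covariates, biological noise, technical noise, detection p-values,
background — makes a seed fully determine the study.

What the generator does **not** emulate: probe-level bead replicates,
spatial or batch artifacts, heavy-tailed or correlated noise,
mean–variance dependence, and annotation-term overlap structure.
Passing recovery tests therefore show the inference machinery is
correct under its own assumptions, not that real arrays meet them.

The gene-set simulator plants one term whose members are drawn by
weighted sampling without replacement (weight = odds ratio on
differential-variability genes); at odds ratio 1 membership is
independent of gene class.  The qPCR simulator is affine-plus-noise in
the log2 signal with positive slope, matching the −ΔCt convention.

## Problem sizes and numerical choices

The test suite and acceptance script run at reduced but honest sizes —
2,000–10,000 probes per experiment, 200 permutations, enumeration
oracles up to n = 12 (signed rank) and N = 40 (Fisher) — chosen so each
check retains statistical force while the whole suite stays quick.
Calibration checks use binomial 99% confidence bands; Monte-Carlo
comparisons use 3 standard errors.  Ties in the variance ranking break
lexicographically by probe id so selections are deterministic.  Exact
Wilcoxon null distributions are used up to 25 nonzero untied pairs,
beyond which the normal approximation with continuity and tie
corrections takes over.

## Known limitations

- The F-test on variances is notoriously non-robust to non-normality;
  no robust alternative (Levene, Brown–Forsythe, moderated variance
  tests) is provided, deliberately — they answer a slightly different
  question and were not part of the procedure being reproduced.
- π₀ estimation is unstable for small probe sets; with a few hundred
  p-values the spline fit can clamp, making pFDR equal BH.
- Quantile normalization couples probes: strong systematic signal in a
  sizable minority of genes leaks into the rest, which slightly
  inflates small-panel null rates downstream (visible only on small
  simulated panels with many planted trajectory genes).
- The original study's headline counts depend on its deposited raw
  data and annotation snapshots; with synthetic data this package
  checks the machinery, not those numbers.
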