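# Methods

This document defines every statistic, generator, and numerical choice in
`coexsurv` precisely enough to reimplement them.

## 1. Co-expression screen (`coexsurv.screen`)

### Statistics

**Spearman rank correlation.** ρ(x, y) is the Pearson correlation of the
average-tie ranks of x and y (`scipy.stats.spearmanr`). It is invariant to
strictly monotone transforms of either argument and is undefined (raises
`DegenerateInputError`) on constant vectors.

**Distance correlation, standard variant.** For scalar samples x, y of
length n, let Dˣᵢⱼ = |xᵢ − xⱼ| and Dʸ likewise. Double-centre each matrix
(subtract row means and column means, add the grand mean) to get A and B.
Then

- dCov²(x, y) = mean(A ∘ B) (entrywise product),
- dVar(x) = mean(A ∘ A),
- dCor(x, y) = √( max(dCov², 0) / √(dVar(x)·dVar(y)) ), clipped to [0, 1].

dCor = 0 iff x and y are empirically independent and dCor = 1 for affine
dependence in one dimension (both properties are asserted in tests against
a separately coded loop-based oracle at 1e-10).

**Distance statistic, mean-scaled ("paper") variant.** Each distance matrix
is divided by its off-diagonal grand mean, Σᵢ≠ⱼ Dᵢⱼ / (n(n−1)); the
statistic is the off-diagonal mean of the entrywise product of the two
scaled matrices, minus 1. Because the diagonals are zero, the full-matrix
sum equals the off-diagonal sum, which the implementation exploits. This is
a covariance-style quantity (unbounded above, can be negative), selectable
via `ScreenParams(dcor_variant="paper")`.

### Permutation significance

For a statistic T, p = (1 + #{b : T(x, π_b(y)) ≥ T(x, y)}) / (B + 1) over B
uniformly random permutations π_b. Signed statistics (ρ) are compared by
absolute value; non-negative statistics (both distance variants under this
screen's one-sided use) directly. The attainable minimum is the floor
1/(B+1); p-values are never 0.

**Batched implementation.** Both statistics are symmetric in their
arguments, so permuting the *anchor* gives the identical per-pair null as
permuting each gene, and one set of B anchor permutations can be shared by
all G genes. For the distance statistic the null then becomes a single
matrix product: with M the G×n² stack of flattened per-gene centred (or
mean-scaled) distance matrices and Aπ the permuted anchor matrix
(Aπ = A[π][:, π], valid because double-centring and mean-scaling commute
with simultaneous row/column permutation), all null raw statistics are
M·Aπᵀ. Raw dCov is compared rather than dCor because dVar is
permutation-invariant, making the two comparisons monotone-equivalent.
Spearman nulls are computed the same way from centred unit-norm rank rows.
The stack is held in float32 and permutation blocks are capped at 2.5×10⁸
elements to bound memory; a test asserts the batched p-values match the
per-pair literal implementation exactly.

### Multiple testing and the intersection rule

Each statistic's p-vector is Benjamini–Hochberg adjusted
(`statsmodels.stats.multitest`, `fdr_bh`); a gene passes a statistic if
q < α (α = 0.05 default). The reported co-expressed list is the
intersection of the two pass sets. Output records are sorted by descending
distance statistic, then descending |ρ|, then gene id (total, deterministic
order).

**Choosing B.** The floor 1/(B+1) must sit below the BH threshold α·k/m for
the k true positives expected among m tests, or no gene can pass regardless
of effect size. For a ~20-gene module among m ≈ 2000 tested genes at
α = 0.05, genome-scale runs here use B = 2999: floor 3.3×10⁻⁴, which clears
the BH cutoff once k ≥ 14 genes reach the floor (q = 3.3×10⁻⁴·1999/14 ≈
0.048). The `ScreenParams` default stays B = 999 for small screens.

### Filtering

Before testing, genes nonzero in fewer than `min_nonzero_fraction` (0.05)
of samples are removed, as are constant genes (both statistics undefined;
the dropped count is logged, not an error). Counts-scale matrices are
screened on log2(1 + x); Spearman is unaffected by this monotone transform,
the distance statistics are not.

## 2. Over-representation (`coexsurv.enrichment`)

Gene-set membership is intersected with the universe (here: all genes the
screen tested) before counting; query genes outside the universe are
dropped with a logged count. For universe size U, set size K, query size N,
overlap k: p = P(X ≥ k) with X ~ Hypergeometric(U, K, N), computed as
`scipy.stats.hypergeom.sf(k − 1, U, K, N)` and clamped to (0, 1] (an
underflow guard substitutes the smallest positive float for exact-zero sf
results). BH adjustment runs across all terms with ≥ 1 member in the
universe. Tests verify exactness against direct `math.comb` summation to a
relative 1e-9 for all grids with U ≤ 60.

## 3. Survival stratification (`coexsurv.survival`)

**Score.** For 1–2 genes with positive weights (normalised to sum to 1),
each gene's expression is optionally log2(1 + x)-transformed, z-scored
across patients (ddof = 1), and the score is the weighted sum. Constant
genes raise an error naming the gene.

**Tail selection.** k = ⌈fraction · n⌉ (ceiling, so fraction = 0.2 of a
92-patient cohort gives k = 19 per tail); requires 2k ≤ n. Patients are
sorted by (score, patient_id) with a stable mergesort — ties are broken by
id, making selection deterministic — and the first/last k form the low/high
groups.

**KM and log-rank.** Kaplan–Meier product-limit curves and the two-group
log-rank test are computed with `lifelines` (KaplanMeierFitter,
logrank_test); curves are reported at observed event times only. Both are
checked in tests against hand-computed worked examples (e.g. times
[1,2,3,4], events [1,1,0,1] gives S = [3/4, 1/2, 0]; a frozen two-group
example gives χ² = 5.0516605166…) and calibration checks (null log-rank
p-values uniform; identical groups give χ² = 0). Groups with zero events
raise `DegenerateInputError`.

## 4. Synthetic generators (`coexsurv.simulate`)

### Expression with a planted module

Single-factor model on the log2 scale. Per cell, a latent factor
f ~ N(0, 1); for the anchor (gene 0) and the m module genes,
L = 4.0 + σ·(ℓ·f + √(1−ℓ²)·ε), background genes L = 4.0 + σ·ε, with
ε ~ N(0, 1) i.i.d. The pairwise Pearson correlation between any two driven
genes on the log scale is therefore exactly ℓ². Counts-scale output is
round(max(2^L − 1, 0)); Bernoulli dropout then zeroes each entry with
probability `zero_inflation`, to stress rank-tie handling.

Defaults and rationale:

- `loading` ℓ = 0.7 (driven-pair correlation 0.49 — a strong but not
  trivial module);
- `noise_sd` σ = 1.0; baseline log2 mean 4.0 (counts ≈ 15, small enough
  that rounding produces occasional zeros);
- `zero_inflation` = 0.05. This was revised from an initial 0.2: a
  permutation power analysis (B = 20 000) showed that at 0.2 dropout the
  distance-correlation p-values of module genes at the default study shape
  (20/2000 genes, 300 cells) can never clear the BH threshold for any B,
  contradicting the intended calibration that the screen recovers ≥ 80% of
  such a module. At 0.05, zeros and rank ties remain present and the module
  is recoverable.
- Presets: `panel` (200 genes × 934 samples, log scale, one planted target
  named NTN4 with ℓ = √0.573 so the pair's planted Pearson dependence is
  0.573); `single-cell` (2000 × 300 counts, 20-gene module, ℓ = 0.7);
  `cohort` (below).

### Survival cohort with a planted score effect

Two gene expressions per patient are bivariate normal (correlation
`gene_corr` = 0.3, mean 6, unit variance, clipped at 0). The patient score
is computed by the *same* `patient_scores` routine the analysis uses, so
the planted effect is on exactly the estimated quantity. Death times are
exponential with hazard h₀·exp(β·score); defaults h₀ = 0.05 per
month-like time unit (median ≈ 14 time units at score 0) and β = 0.9.
Censoring is administrative: C ~ U(0, c), with the horizon c solved by
bisection (200 iterations in log space) on the drawn death times so the
*expected* censored fraction equals `censor_rate` (0.3). `censor_rate = 0`
yields all events.

## 5. Pipeline and reproducibility (`coexsurv.pipeline`)

`run_pipeline` chains screen → enrichment (query = intersection list,
universe = all tested genes) → stratification (each score gene singly, the
pair, and optionally a control gene singly and paired with the anchor) from
one flat `key=value` config; unknown keys and missing input files are
errors before any computation. Stage seeds derive as the first 4 bytes of
SHA-256(f"{seed}:{stage}") mod 2³¹, so stages are independently
reproducible and all derived seeds fit in 31 bits. Tables are written with
`%.6g` float formatting; two runs with the same config are byte-identical
(asserted in tests). On a stage failure, partially written outputs are
removed and the raised error names the failing stage.

## 6. Limitations

- Generators are calibration devices, not realistic transcriptomes: no
  library-size variation, no gene-length effects, Gaussian log-expression,
  dropout independent of expression level.
- The screen tests marginal anchor–gene dependence only; it cannot
  distinguish direct co-regulation from shared confounding, and the
  single-factor truth makes "module recovery" easier than correlated real
  modules with heterogeneous loadings.
- The permutation null assumes exchangeable samples (no batch or donor
  structure).
- Stratifying on score tails discards the middle 60% of patients and the
  log-rank test is unadjusted for covariates; p-values for scores chosen
  *because* they screened well are not corrected for that selection.
- The mean-scaled distance variant is provided for methodological fidelity;
  it lacks the standard variant's normalisation and scale-freeness
  guarantees.
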