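# coexsurv — anchor-gene co-expression screening and survival stratification

`coexsurv` reimplements, as a reusable library plus analysis scripts, a
bioinformatic workflow common in cancer transcriptomics: starting from an
*anchor* gene of interest (the motivating use case is EGFR in glioblastoma,
where EGF signalling induces the secreted ligand netrin-4/NTN4), find the
genes whose expression co-varies with the anchor, ask which annotated gene
sets that list is enriched for, and test whether a weighted two-gene
expression score (e.g. EGFR + NTN4) stratifies patient survival better than
either gene alone.

## Methods in brief

Three statistical components, all validated against independent oracles in
the test suite (see `docs/methods.md` for full definitions and numerical
choices):

- **Dual co-expression screen.** Every gene *g* is tested against the anchor
  *a* with two complementary statistics: Spearman's ρ(g, a) (Pearson
  correlation of average-tie ranks; captures monotone association, robust to
  zero-heavy single-cell counts) and distance correlation dCor(g, a)
  (Székely's statistic from double-centred pairwise-distance matrices; zero
  iff empirical independence). A mean-scaled distance-covariance variant —
  each distance matrix divided by its off-diagonal grand mean, statistic =
  off-diagonal mean of the entrywise product − 1 — is also provided
  (`dcor_variant="paper"`). Significance comes from a permutation null,
  p = (1 + #{perm ≥ obs}) / (B + 1); both p-value vectors are
  Benjamini–Hochberg adjusted and the reported co-expressed list is the
  **intersection** of the two q < α pass sets.
- **Over-representation.** For a query list of N genes in a universe of U,
  a set with K members in the universe and overlap k has
  p = P(X ≥ k), X ~ Hypergeometric(U, K, N), BH-adjusted across sets.
- **Survival stratification.** Patients are scored by a weighted sum of
  z-scored (optionally log2(1+x)-transformed) gene expressions; the top and
  bottom k = ⌈fraction·n⌉ patients by score form the high/low groups
  (fraction = 0.2 by default, so a 92-patient cohort gives k = 19 per tail);
  the groups are compared with Kaplan–Meier curves and the log-rank test.

Synthetic generators with known ground truth (a single-latent-factor
planted co-expression module; a proportional-hazards cohort whose hazard is
h₀·exp(β·score)) support calibration and power checks throughout.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (outputs land under `results/`):

```sh
python analysis/01_simulate_data.py --seed 0
python analysis/02_screen_coexpression.py --seed 0
python analysis/03_enrichment.py
python analysis/04_survival_stratification.py
```

Output from exactly this invocation:

```
panel: 200 genes x 934 samples
single-cell: 2000 genes x 300 cells, module size 20
cohort: 92 patients, 59 events, beta=0.9

1999 genes tested, intersection list size 21
planted-module recall 1.000, background false-positive rate 0.00051
panel EGFR-NTN4 Spearman rho = 0.503 (n = 934)

query 21 genes, universe 1999, 21 terms tested
  SET:MODULE: overlap 20/20, p=5.41e-47, q=1.14e-45

EGFR:      k=19 per tail, logrank chi2=5.254,  p=0.02189
NTN4:      k=19 per tail, logrank chi2=7.895,  p=0.004957
EGFR+NTN4: k=19 per tail, logrank chi2=12.031, p=0.0005232
```

The screen recovers all 20 planted module genes among 1999 tested with one
background false positive; the planted gene set dominates the enrichment
ranking; and the two-gene score separates the survival tails more sharply
(p ≈ 5×10⁻⁴) than either single gene — the qualitative pattern the
workflow is designed to detect.

The same stages are available as a CLI (`coexsurv simulate|screen|enrich|
survive|run-all`); `coexsurv run-all --config <file>` drives screen →
enrichment → stratification from one flat `key=value` config and writes a
manifest alongside the result tables.

## Reproduction

`scripts/acceptance.py` re-derives the pipeline's headline quantities from
scratch — oracle agreement of both dependence statistics, permutation- and
log-rank-null calibration (KS distance from uniform), planted-module
recall/false-positive rate at genome scale, achieved censoring fraction,
log-rank power against the planted hazard, and the study-sized tail size
and pair log-rank p — and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Every random draw derives deterministically from `--seed`; the run takes
about two minutes. `results/acceptance.json` in this repository is the
committed output of the seed-1 invocation above.

## Layout

- `src/coexsurv/` — library: `io` (TSV/CSV/MatrixMarket expression, GMT,
  cohort tables), `screen`, `enrichment`, `survival`, `simulate`,
  `pipeline`, `cli`
- `analysis/` — numbered study drivers (see worked example)
- `scripts/acceptance.py` — headline-quantity reproduction
- `tests/` — unit + acceptance suite with independent oracles
- `docs/methods.md` — full methodological documentation
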