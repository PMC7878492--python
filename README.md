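# hmcseal

Analysis toolkit for genome-wide 5-hydroxymethylcytosine (5hmC) profiles in
circulating cell-free DNA (cfDNA), built around the question of separating
the two most common non-Hodgkin lymphoma subtypes — diffuse large B-cell
lymphoma (DLBCL) and follicular lymphoma (FL) — from plasma alone.  It is a
library for statisticians and computational biologists working with
5hmC-Seal count data: every stage is an importable function, and
`examples/` holds short scripts exercising each capability.

## What it does

Starting from aligned fragments (BED, MAPQ in the score column), a gene
annotation (GTF or BED with a cytoband map), histone-mark narrowPeak files,
and a clinical sample sheet:

1. **Feature summarization** — fragments with MAPQ ≥ 10 are counted,
   unstranded, into gene bodies (or any interval set) by ≥ 1 bp overlap.
2. **Differential modification** — median-of-ratios size factors; per-gene
   negative-binomial log-linear models
   `log mu_gi = log s_i + x_i' beta_g` adjusted for batch, age, and gender,
   with gene-wise dispersion `alpha_g` (Var = mu + alpha mu²) estimated by
   moments and refined by profile likelihood; Wald tests of the subtype
   coefficient (reported as log2 fold-change, FL vs DLBCL); empirical
   p-values from B label permutations pooled across genes; differential
   calls at empirical p < 0.05 and fold-change > 20%; hypergeometric
   cytoband enrichment with Benjamini-Hochberg correction.
3. **Signature selection** — elastic-net penalized logistic regression
   (coordinate descent over a warm-started lambda path, minimizing
   `-(1/N) Σ [y_i η_i − log(1+e^{η_i})] + λ Σ_j v_j[(1−α)β_j²/2 + α|β_j|]`
   with per-feature penalty factors `v_j`; age and gender ride along with
   `v_j = 0`), tuned by stratified 10-fold cross-validation and stabilized
   over 200 resampled repeats with a 90% selection-frequency threshold; an
   unpenalized integrated refit `logit P(FL) = β₀ + x'β` on the selected
   genes plus age and gender; ROC AUC with DeLong or bootstrap 95% CIs.
4. **Cis-regulatory co-localization** — merging of narrow peaks closer
   than 200 bp, per-mark shares of gene-body fragments, binned-coverage
   Pearson correlations, and element-level DLBCL/FL rank-sum comparisons
   on normalized log2 levels.
5. **Clinical statistics** — cohort characteristics tables (pooled
   Student's t for age; chi-square with Yates correction for complete 2×2
   variables; plain chi-square including a Missing category otherwise),
   median-split groups, Kaplan-Meier curves with log-rank tests, and
   Efron-tie Cox proportional-hazards models of overall survival.
6. **Synthetic data** — a first-class generator producing clinical tables,
   annotations, NB counts with planted subtype effects, fragment files
   that round-trip exactly through summarization, and peak sets that
   exercise the merge rule — all with ground truth for parameter-recovery
   testing.

## Worked example

```python
import numpy as np
from hmcseal import synthetic, diffmod, signature

cohort = synthetic.generate_cohort(48, 25, seed=11)
ann = synthetic.generate_annotation(800, 4, 60_000_000, seed=11)
counts, truth = synthetic.generate_counts(cohort, ann, n_planted=8,
                                          log2fc=1.0, dispersion=0.1,
                                          libsize_cv=0.3, seed=11)
counts = diffmod.filter_nonzero_variance(counts)
sf = diffmod.size_factors(counts)
table = diffmod.nb_wald_test(counts, cohort, sf=sf)
table["empirical_p"] = diffmod.empirical_pvalues(counts, cohort, sf=sf,
                                                 B=500, seed=11, table=table)
called, summary = diffmod.call_differential(table)
print(summary)
```

prints

```
{'n_called': 36, 'up_in_FL': 15, 'down_in_FL': 21}
```

meaning 36 of 800 genes pass empirical p < 0.05 with fold-change > 20%
(all 8 planted genes among them; the remainder are the expected false
calls at that threshold).  Continuing with `examples/03_signature_classifier.py`
selects a compact signature from the training half and reaches

```
train AUC 100.0%  test AUC 100.0% (95% CI 100.0-100.0%)
```

on the held-out samples — the planted subtype effects are strong enough
for a perfect held-out separation at this simulation scale.  Each script in
`examples/` is a self-contained narrative of one capability
(simulation, differential modification, signature, co-localization,
clinical/survival).

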