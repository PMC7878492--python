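# Methods

## Scope and data model

The package analyses 5hmC-Seal sequencing of plasma cfDNA summarized to
genomic features.  All intervals are 0-based half-open internally; BED is
read and written natively, GTF (1-based closed) converted at the boundary.
A fragment contributes to every feature it overlaps by at least one base,
unstranded, and only if its mapping quality is ≥ 10 (the assay's
convention; `min_mapq` is a parameter).  Whether a multi-overlapping
fragment should count once or per feature is genuinely open for gene-body
counting; counting per feature was chosen because it keeps the operation
local to each feature and matches unstranded featureCounts-style behaviour
closely at this scale.

## Differential modification

**Normalization.** Median-of-ratios size factors: for sample *i*,
`s_i = median_g (c_gi / geomean_g)` over genes with no zero count.  When no
such gene exists the default is an error; `on_all_zero="pseudo"` switches
to geometric means over positive counts.  Factors are not rescaled, so
they are identified up to one global constant — every use downstream is
invariant to that constant.

**Per-gene model.** Counts follow a negative binomial with
`log mu_gi = log s_i + x_i' beta_g` and `Var = mu + alpha_g mu²`.  The
design is intercept + subtype (FL = 1, so positive coefficients mean
higher in FL) + treatment-coded batch + standardized age + gender (M = 1).
All genes share the design matrix, so the IRLS normal equations are built
for every gene at once (einsum) and solved as a batch of p×p systems; this
is what makes permutation re-fitting of a whole matrix feasible (tens of
milliseconds per permutation for 2,000 genes × 73 samples).

**Dispersion.** Gene-wise: a Poisson fit supplies means, the moment
estimator `alpha = Σ[(y−mu)² − mu]/Σ mu²` initialises a bounded
profile-likelihood maximisation over log alpha (means re-fit once at the
moment estimate), floored at 1e-8 and capped at 10.  No empirical-Bayes
shrinkage toward a mean-dispersion trend is applied — a deliberate
simplification relative to the DESeq2 family of estimators; at the
cohort sizes targeted here (n ≈ 70) gene-wise estimates are stable enough,
and the Wald calibration is checked directly by permutation (below).

**Wald test.** The subtype coefficient and its standard error from
`(X'WX)^{-1}`, reported on the log2 scale, with a two-sided normal p and
BH FDR.  Non-converged genes (flagged by the IRLS) carry NaN statistics
and are excluded from FDR with a log entry.

**Empirical p-values.** B permutations of the subtype label (all other
covariates stay with their samples; B defaults to 10,000, scaled down in
the bundled studies).  Dispersions are estimated once on the observed
labels and held fixed across permutations — dispersion is a property of
the counts, not the labels, and re-estimating it 10,000 times would
dominate the cost for no calibration benefit (the null uniformity check
below validates the shortcut).  The null |Wald z| values are pooled across
genes (exchangeability across genes at the scale of the statistic), giving
`p_g = (1 + #{null ≥ |z_g|}) / (1 + B·G)`; `pooled=False` switches to
per-gene nulls.  Restricted within-batch permutation is not implemented;
batch enters the model instead.

**Calls and enrichment.** Differential genes: p < 0.05 on the empirical
column and |log2fc| > log2(1.2) (">20% fold-change", symmetric in both
directions); the Wald column with p < 0.005 is available for the stricter
convention.  Cytoband enrichment is a per-band hypergeometric upper tail
over the tested-gene universe with BH correction.  The
concentration-of-signal curve sorts genes by |log2fc| and accumulates
their share of the total.

## Signature selection and the integrated classifier

**Elastic net.** Penalized logistic regression minimizing
`-(1/N) Σ [y_i η_i − log(1+e^{η_i})] + λ Σ_j v_j[(1−α)β_j²/2 + α|β_j|]`,
solved by proximal-Newton steps with cyclic coordinate descent, features
standardized to unit population variance internally and coefficients
returned on the original scale.  The lambda path is warm-started from the
all-zero end with sequential strong-rule screening and full KKT checks;
the inner loop is numba-compiled.  α defaults to 0.5 — the midpoint of
the lasso/ridge blend, since nothing in the study design pins it down —
and is a parameter.  Penalty factors `v_j` allow always-in covariates:
age and gender enter with `v_j = 0` throughout selection and refit.

**Tuning.** Stratified k-fold cross-validation (k = 10, capped at the
smaller class size so folds keep both classes), choosing λ at the minimum
mean binomial deviance.  The 1-SE rule was considered and not used: at
the target sample sizes the deviance curves are shallow and the minimum
rule is the simpler default; sparsity control comes from the stability
threshold instead.

**Stability selection.** The CV-tuned fit is repeated (200 by default);
each repeat draws a class-stratified 2/3 subsample of the rows without
replacement and re-randomizes the folds, and genes with nonzero
coefficients in ≥ 90% of repeats form the signature.  Row resampling is
essential, not decorative: with the rows fixed, whichever noise genes
happen to correlate with the labels are selected in *every* repeat and
the frequency threshold separates nothing.  Two-thirds sits between
classical half-sampling (which at n ≈ 73 costs real power — strongly
planted genes drop to 60-90% frequency) and no resampling (which controls
nothing); with it, planted genes at |log2fc| = 1 stay at ~100% frequency
while individual noise genes fall well below the threshold.
`subsample_fraction=None` recovers the fixed-row variant.

**Integrated model and ROC.** An unpenalized logistic refit of subtype on
the selected genes' normalized levels (`log2(count/s_i + 1)`) plus age and
gender; perfect separation falls back to a tiny ridge (λ = 1e-6) with a
warning.  AUC uses the Mann-Whitney identity with midrank ties; the 95% CI
is DeLong by default or a stratified bootstrap.

## Co-localization

Peaks of one mark are merged transitively when gaps are < 200 bp (gap
between `[a,b)` and `[c,d)` is `c−b`; strictly less, so a 200 bp gap
survives).  A mark's element fraction is the share of a gene's MAPQ-passing
fragments that fall in the merged mark∩gene elements, pooled over samples;
marks overlap each other, so shares need not sum to one.  Coverage tracks
bin overlap counts at 100 bp (a free choice; the correlation is insensitive
to moderate bin sizes) and are compared by Pearson correlation with the
t-transform p-value.  Element-level group differences use the two-sample
Wilcoxon rank-sum test (normal approximation with tie correction, no
continuity correction) on `log2(count/s_i + 1)` with the *gene-body* size
factors reused, keeping element and gene-body levels on one scale; a
signed-rank variant exists for genuinely paired designs.  The rank-sum
choice is deliberate: DLBCL and FL groups of unequal size cannot be paired,
so a signed-rank test is not defined for this comparison.

## Clinical statistics

Characteristics tables compare age by pooled-variance Student's t; complete
two-level variables (sex, race) by Pearson chi-square with Yates
continuity correction; and variables carrying a Missing level (stage, LDH,
vital status) by Pearson chi-square over all levels with Missing as its
own category and no continuity correction.  That missing-level convention
is the one that reproduces the reference table's stage and LDH statistics
exactly (verified against an independent implementation before freezing
it).  Survival: median splits assign values strictly above the median to
"high" (an odd-n median sample is "low"); Kaplan-Meier curves use the
product-limit estimator; the two-group log-rank statistic accumulates
observed minus hypergeometric-expected events per distinct event time;
Cox models are fit by lifelines with Efron tie handling, hazard ratios
with Wald 95% CIs.  All tests are two-sided.

## Synthetic data

The generator mirrors the emulated study design: 48 DLBCL + 25 FL; ages
truncated-normal (DLBCL 58.1 ± 14.1, FL 53.2 ± 12.8, bounds 20-95);
gender/race/stage/LDH/cell-of-origin drawn from the reference marginal
frequencies; overall survival exponential with log-hazard linear in age
(+0.35/decade), late stage (+0.5) and DLBCL (+0.8) over a 0.004/month
baseline, censored by an independent Uniform(12, 90) months — the simplest
proportional-hazards-satisfying design, so Cox recovery is testable.
Counts are NB with mean `s_i q_g 2^{x_i·β_g}`: lognormal size factors
(CV = `libsize_cv`, default 0.3), lognormal baselines (median ≈ 40
fragments/gene — small enough that fragment files stay tractable, large
enough for stable dispersion estimates), planted subtype effects of
`±log2fc` with random sign, and small centred-normal batch/age/gender
effects (SDs 0.1, 0.05/decade, 0.05 in log2 units).  No per-gene
dispersion table exists for the real assay, so a single configurable
`alpha` (0.1 in the bundled studies) is used.  Fragments are placed
uniformly inside gene bodies, exactly `count` high-MAPQ fragments per
gene/sample, plus configurable low-MAPQ decoys and intergenic fragments;
summarization therefore recovers the generating matrix *exactly*, which is
tested.  Peak sets always contain a 199 bp-gap pair (must merge) and a
200 bp-gap pair (must not).

What the generator does not emulate: GC and mappability bias, fragment
length distributions, correlated genes or co-regulated modules, overlapping
gene models, batch-by-gene interactions, and informative censoring.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to those artefacts.

## Validation studies and problem sizes

The bundled studies (tests/test_acceptance.py, scripts/acceptance.py) run
at sizes chosen to exercise the full pipeline on one CPU in minutes:
permutation calibration at 2,000 genes, 36+36 samples, B = 1,000
(KS uniformity and the 0.05 rejection rate within 3 Monte-Carlo SEs);
stability-selection recovery with 4 genes planted at |log2fc| = 1 among
2,000 (dispersion 0.1, 48+25 samples, 50 repeats, 90% threshold, success =
all four planted and at most one false gene, over 20 replicate seeds);
oracle equivalence of merging, counting, AUC, rank-sum and log-rank
against brute-force/reference implementations on 100 random instances
each; size-factor recovery at 1,000 genes × 20 samples (max relative error
under 5%); and an end-to-end run at 800 genes × 73 samples with 8 genes
planted at |log2fc| = 1.5, B = 200 permutations, fragment round-trip on a
40-gene subset.  The recovery study's per-seed success probability sits
near 0.8 under these conditions, so its measured rate varies by a few
seeds' worth between runs.

## Known limitations

- Dispersion estimation without trend shrinkage is noisier than DESeq2's
  at very small n or very low counts.
- The pooled permutation null assumes cross-gene exchangeability of |z|;
  strongly heterogeneous designs should use `pooled=False`.
- The elastic-net path solver targets dense inputs of desk scale
  (p up to a few thousand); it is not a sparse-matrix glmnet replacement.
- `characteristics_table` reports vital status for completeness, but its
  chi-square convention for that row is not uniquely determined by the
  reference table (see the validation notes in the tests).
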