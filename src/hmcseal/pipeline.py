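"""End-to-end orchestration of the analysis on a simulated cohort.

Chains simulate -> summarize -> differential modification -> signature ->
colocalization -> clinical into one call, returning every intermediate
product.  Used by the smoke validation and the worked examples; each stage
is equally usable on its own with real inputs.
"""

from __future__ import annotations

import numpy as np

from . import clinical as clin_mod
from . import colocalization as coloc
from . import diffmod, signature, synthetic
from .features import merge_peaks, summarize_features

MARKS = ["H3K4me1", "H3K27ac", "H3K9me3", "H3K27me3"]


def run_end_to_end(
    seed: int,
    n_dlbcl: int = 48,
    n_fl: int = 25,
    n_genes: int = 800,
    n_planted: int = 8,
    log2fc: float = 1.5,
    dispersion: float = 0.1,
    libsize_cv: float = 0.3,
    permutations: int = 200,
    repeats: int = 50,
    fragment_genes: int = 40,
) -> dict:
    """Run the full pipeline on one simulated cohort.

    Fragment generation and round-trip counting are restricted to the first
    ``fragment_genes`` genes (fragment files grow with total counts; the
    count matrix itself covers all ``n_genes``).  Returns a dict with the
    cohort, counts, truth, differential table, called genes, signature
    model, train/test AUCs, per-mark element fractions for the top
    signature gene, and the round-trip check result.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731

    cohort = synthetic.generate_cohort(n_dlbcl, n_fl, seed=sub())
    annotation = synthetic.generate_annotation(
        n_genes, n_chroms=5, chrom_length=60_000_000, seed=sub())
    counts, truth = synthetic.generate_counts(
        cohort, annotation, n_planted=n_planted, log2fc=log2fc,
        dispersion=dispersion, libsize_cv=libsize_cv, seed=sub())

    # fragment round trip on a subset of genes
    sub_ann = annotation.iloc[:fragment_genes].reset_index(drop=True)
    sub_counts = counts.loc[sub_ann["gene_id"]]
    fragments = synthetic.generate_fragments(
        sub_counts, sub_ann, fragment_length=167, mapq_low_fraction=0.1,
        seed=sub())
    recounted = summarize_features(fragments, sub_ann, min_mapq=10)
    roundtrip_exact = bool(
        recounted.loc[sub_counts.index, sub_counts.columns].equals(sub_counts))

    counts_nz = diffmod.filter_nonzero_variance(counts)
    sf = diffmod.size_factors(counts_nz)
    table = diffmod.nb_wald_test(counts_nz, cohort, sf=sf)
    table["empirical_p"] = diffmod.empirical_pvalues(
        counts_nz, cohort, sf=sf, B=permutations, seed=sub(), table=table)
    called, call_summary = diffmod.call_differential(table)
    enrichment = diffmod.cytoband_enrichment(called, annotation,
                                             universe=counts_nz.index)
    concentration = diffmod.signal_concentration(table)

    train_ids, test_ids = signature.split_train_test(cohort, seed=sub())
    levels = diffmod.normalized_log2(counts_nz, sf).T  # samples x genes
    candidates = [g for g in called if g in levels.columns]
    clin_idx = cohort.set_index("sample_id")
    feats = levels[candidates].copy()
    feats["age"] = clin_idx.loc[feats.index, "age"].to_numpy(float)
    feats["gender_M"] = (clin_idx.loc[feats.index, "gender"] == "M").to_numpy(float)
    v = np.ones(feats.shape[1])
    v[-2:] = 0.0  # age and gender always in
    spec = signature.PenalizedLogisticSpec(alpha=0.5, penalty_factors=v)
    y_train = (clin_idx.loc[train_ids, "subtype"] == "FL").to_numpy(float)
    selected, freq = signature.stability_selection(
        feats.loc[train_ids], y_train, spec, repeats=repeats, threshold=0.90,
        seed=sub())
    if not selected:  # degenerate run: keep the most frequently chosen gene
        selected = [freq.drop(["age", "gender_M"]).idxmax()]
    model = signature.fit_integrated_model(
        levels.loc[train_ids, selected], selected, cohort,
        seed=seed, test_ids=test_ids)
    feat_all = levels[selected].copy()
    feat_all["age"] = clin_idx.loc[feat_all.index, "age"].to_numpy(float)
    feat_all["gender_M"] = (clin_idx.loc[feat_all.index, "gender"] == "M"
                            ).to_numpy(float)
    y_all = (clin_idx.loc[feat_all.index, "subtype"] == "FL").astype(int)
    roc_train = signature.roc_auc(model.score(feat_all.loc[train_ids]),
                                  y_all.loc[train_ids])
    roc_test = signature.roc_auc(model.score(feat_all.loc[test_ids]),
                                 y_all.loc[test_ids])

    # colocalization around the strongest planted/selected gene, using the
    # fragment subset's gene space
    peaks = synthetic.generate_peaks(sub_ann, MARKS, seed=sub())
    merged = {m: merge_peaks(p) for m, p in peaks.items()}
    gene_row = sub_ann.iloc[0]
    fractions = coloc.element_fraction(fragments, gene_row, merged)

    table1 = clin_mod.characteristics_table(cohort)
    top_gene = selected[0]
    groups = clin_mod.median_split(levels[top_gene])
    surv = cohort.dropna(subset=["os_time", "death_event"])
    g = groups.loc[surv["sample_id"]]
    curves, lr_chi2, lr_p = clin_mod.km_logrank(
        surv["os_time"], surv["death_event"], g.to_numpy())

    return {
        "cohort": cohort,
        "annotation": annotation,
        "counts": counts,
        "truth": truth,
        "size_factors": sf,
        "diffmod_table": table,
        "called_genes": list(called),
        "call_summary": call_summary,
        "cytoband_enrichment": enrichment,
        "signal_concentration": concentration,
        "selected_genes": selected,
        "selection_frequency": freq,
        "model": model,
        "roc_train": roc_train,
        "roc_test": roc_test,
        "roundtrip_exact": roundtrip_exact,
        "element_fractions": fractions,
        "characteristics": table1,
        "logrank": {"chi2": lr_chi2, "p": lr_p},
        "train_ids": train_ids,
        "test_ids": test_ids,
    }
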