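"""Simulate a DLBCL/FL cfDNA 5hmC-Seal study and write its files.

Builds a 48+25 cohort with the study-design demographics, a gene annotation
with cytobands, negative-binomial gene-body counts with 8 planted
subtype-differential genes, per-sample fragment BED files for a subset of
genes, and histone-mark narrowPeak files.  Prints a summary of what the
ground truth contains.
"""

from pathlib import Path

from hmcseal import features, synthetic

OUT = Path("scratch/example_simulation")
OUT.mkdir(parents=True, exist_ok=True)

cohort = synthetic.generate_cohort(48, 25, seed=7)
annotation = synthetic.generate_annotation(400, n_chroms=4,
                                           chrom_length=40_000_000, seed=7)
counts, truth = synthetic.generate_counts(
    cohort, annotation, n_planted=8, log2fc=1.5, dispersion=0.1,
    libsize_cv=0.3, seed=7)

sub_ann = annotation.iloc[:30].reset_index(drop=True)
fragments = synthetic.generate_fragments(
    counts.loc[sub_ann["gene_id"]], sub_ann, fragment_length=167,
    mapq_low_fraction=0.1, seed=7)
peaks = synthetic.generate_peaks(
    sub_ann, ["H3K4me1", "H3K27ac", "H3K9me3", "H3K27me3"], seed=7)

cohort.to_csv(OUT / "clinical.tsv", sep="\t", index=False)
features.write_annotation_gtf(annotation, OUT / "genes.gtf",
                              OUT / "cytobands.tsv")
features.write_counts_tsv(counts, OUT / "counts.tsv")
synthetic.write_truth_json(truth, OUT / "truth.json")
for sid in list(fragments)[:2]:
    features.write_fragments_bed(fragments[sid], OUT / f"{sid}.bed")
for mark, ps in peaks.items():
    features.write_narrowpeak(ps, OUT / f"{mark}.narrowPeak")

print(f"cohort: {len(cohort)} samples "
      f"({(cohort.subtype == 'DLBCL').sum()} DLBCL, "
      f"{(cohort.subtype == 'FL').sum()} FL)")
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples, "
      f"median per-gene count {int(counts.median(axis=1).median())}")
print(f"planted genes ({len(truth.planted_genes)}): "
      f"{sorted(truth.planted_genes)}")
print("planted log2 fold-changes (positive = higher in FL):")
for g in sorted(truth.planted_genes):
    print(f"  {g}: {truth.planted_log2fc[g]:+.2f}")
print(f"files written under {OUT}/")
# The planted set and effects are the ground truth the analysis examples
# try to recover from the counts alone.
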