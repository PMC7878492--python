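"""Co-localization of 5hmC fragments with histone-mark elements.

Builds a gene whose fragments preferentially fall inside H3K4me1/H3K27ac
(enhancer) peaks, merges nearby peaks (<200 bp), computes each mark's share
of gene-body fragments, correlates binned coverage of fragments with the
enhancer peak track, and tests element-level DLBCL-vs-FL differences by
the rank-sum test on normalized log2 levels.
"""

import numpy as np
import pandas as pd

from hmcseal import colocalization as coloc
from hmcseal import diffmod, synthetic
from hmcseal.features import PeakSet, merge_peaks

rng = np.random.default_rng(31)
gene = {"chrom": "chr1", "start": 10_000, "end": 30_000}

# enhancer peaks inside the gene; a repressive mark mostly outside
marks = {
    "H3K4me1": merge_peaks(PeakSet("H3K4me1", pd.DataFrame(
        {"chrom": "chr1", "start": [12_000, 12_950, 24_000],
         "end": [12_800, 13_800, 25_500]}))),   # first two merge (<200 bp gap)
    "H3K27ac": merge_peaks(PeakSet("H3K27ac", pd.DataFrame(
        {"chrom": "chr1", "start": [23_500], "end": [26_000]}))),
    "H3K9me3": merge_peaks(PeakSet("H3K9me3", pd.DataFrame(
        {"chrom": "chr1", "start": [40_000], "end": [45_000]}))),
}

# fragments: 70% drawn inside enhancer elements, 30% uniform on the gene
def frags_for(n_enh, n_uni, seed):
    r = np.random.default_rng(seed)
    enh = np.r_[r.integers(12_000, 13_700, size=n_enh // 2),
                r.integers(23_500, 25_800, size=n_enh - n_enh // 2)]
    uni = r.integers(10_000, 29_800, size=n_uni)
    start = np.r_[enh, uni]
    return pd.DataFrame({"chrom": "chr1", "start": start, "end": start + 167,
                         "name": "f", "mapq": 60, "strand": "."})

fragments = {f"s{i}": frags_for(140, 60, 100 + i) for i in range(6)}

frac = coloc.element_fraction(fragments, gene, marks)
print("share of gene-body fragments per mark:")
print(frac.round(3).to_string())

cov_frag = coloc.binned_coverage(pd.concat(fragments.values()), gene,
                                 bin_size=100)
cov_peak = coloc.binned_coverage(marks["H3K4me1"].intervals, gene,
                                 bin_size=100)
r, p = coloc.coverage_correlation(cov_frag, cov_peak)
print(f"fragment x H3K4me1 coverage correlation: r = {r:.2f}, p = {p:.2e}")

# element-level group difference on a small cohort
cohort = synthetic.generate_cohort(10, 10, seed=32)
elem_counts = pd.DataFrame(
    rng.poisson(np.where(cohort["subtype"] == "FL", 80, 40), size=(3, 20)),
    index=["elem_1", "elem_2", "elem_3"], columns=cohort["sample_id"])
sf = pd.Series(1.0, index=cohort["sample_id"])
diffs = coloc.element_differential(elem_counts, cohort, sf)
print("element-level DLBCL vs FL (rank-sum on log2 levels):")
print(diffs.round(4))
# Enhancer marks capture most gene-body 5hmC and the coverage tracks
# correlate strongly; element counts planted higher in FL come out with
# positive median differences and small p-values.
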