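"""Co-localization of 5hmC fragments with histone-mark elements.

For each signature gene, the share of gene-body 5hmC fragments falling in a
mark's (merged) peaks, binned coverage tracks across the gene, Pearson
correlation between coverage tracks, and element-level group comparisons
between DLBCL and FL (rank-sum by default; the groups are unpaired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, rank_sum_test
from .features import PeakSet, intersect_peaks_gene

__all__ = [
    "CoverageVector",
    "element_fraction",
    "binned_coverage",
    "coverage_correlation",
    "element_differential",
]


@dataclass
class CoverageVector:
    """Fragment coverage per fixed-width bin over one region.

    values[b] counts fragments overlapping
    [start + b*bin_size, start + (b+1)*bin_size); the last bin may be short.
    """

    chrom: str
    start: int
    end: int
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = -(-(self.end - self.start) // self.bin_size)
        if len(self.values) != expected:
            raise ValueError("coverage length does not match region/bin_size")
        if (self.values < 0).any():
            raise ValueError("coverage must be non-negative")


def _overlap_count(frag: pd.DataFrame, chrom, start, end) -> int:
    sub = frag[(frag["chrom"] == chrom) & (frag["start"] < end) & (frag["end"] > start)]
    return len(sub)


def element_fraction(
    fragments: dict[str, pd.DataFrame],
    gene,
    peaks_by_mark: dict[str, PeakSet],
    min_mapq: int = 10,
) -> pd.Series:
    """Per-mark share of gene-body fragments falling in mark elements.

    For each mark: (fragments overlapping mark-within-gene elements) /
    (fragments overlapping the gene body), pooled across samples, MAPQ
    filtered.  Marks may overlap each other so the shares need not sum to
    1.  With zero gene-body fragments the proportion is undefined (NaN).
    """
    chrom, gstart, gend = gene["chrom"], gene["start"], gene["end"]
    flt = {s: df[df["mapq"] >= min_mapq] for s, df in fragments.items()}
    denom = sum(_overlap_count(df, chrom, gstart, gend) for df in flt.values())
    out = {}
    for mark, peaks in peaks_by_mark.items():
        elements = intersect_peaks_gene(peaks, gene)
        if denom == 0:
            out[mark] = np.nan
            continue
        num = 0
        for df in flt.values():
            sub = df[(df["chrom"] == chrom) & (df["start"] < gend)
                     & (df["end"] > gstart)]
            if len(sub) == 0 or not elements:
                continue
            hit = np.zeros(len(sub), dtype=bool)
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            for es, ee in elements:
                hit |= (s < ee) & (e > es)
            num += int(hit.sum())
        out[mark] = num / denom
    return pd.Series(out, name="fraction")


def binned_coverage(intervals: pd.DataFrame, region, bin_size: int = 100) -> CoverageVector:
    """Fragment (or peak) overlap counts per bin across a region."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    chrom, start, end = region["chrom"], int(region["start"]), int(region["end"])
    n_bins = -(-(end - start) // bin_size)
    diff = np.zeros(n_bins + 1, dtype=np.int64)
    sub = intervals[(intervals["chrom"] == chrom) & (intervals["start"] < end)
                    & (intervals["end"] > start)]
    if len(sub):
        s = np.clip(sub["start"].to_numpy() - start, 0, None)
        e = np.clip(sub["end"].to_numpy() - start, None, end - start)
        b0 = s // bin_size
        b1 = (e - 1) // bin_size  # inclusive last bin touched
        np.add.at(diff, b0, 1)
        np.add.at(diff, b1 + 1, -1)
    values = np.cumsum(diff[:-1])
    return CoverageVector(chrom=chrom, start=start, end=end, bin_size=bin_size,
                          values=values)


def coverage_correlation(v1: CoverageVector, v2: CoverageVector):
    """Pearson correlation between two coverage tracks.

    Two-sided p from the t transform with n-2 df.  Constant input is an
    error (r undefined).
    """
    a = np.asarray(v1.values, float)
    b = np.asarray(v2.values, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("coverage vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant coverage vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def element_differential(
    element_counts: pd.DataFrame,
    clinical: pd.DataFrame,
    sf: pd.Series,
    test: str = "rank_sum",
) -> pd.DataFrame:
    """Per-element DLBCL-vs-FL comparison on normalized log2 levels.

    Element counts are normalized by the gene-body size factors (keeping
    element and gene-body levels on one scale) and log2(x+1) transformed.
    Groups are compared by the Wilcoxon rank-sum test with normal
    approximation and tie correction (``test="signed_rank"`` is available
    for genuinely paired designs of equal size).  Direction reports the
    sign of the FL - DLBCL median difference.  All-tied elements get p = 1
    with a warning.
    """
    clin = clinical.set_index("sample_id").loc[element_counts.columns]
    fl = clin["subtype"] == "FL"
    if fl.sum() < 2 or (~fl).sum() < 2:
        raise ValueError("need >= 2 samples per subtype")
    levels = np.log2(element_counts / sf.loc[element_counts.columns] + 1.0)
    rows = []
    for elem, vals in levels.iterrows():
        x = vals[fl.to_numpy()].to_numpy(float)      # FL
        y = vals[(~fl).to_numpy()].to_numpy(float)   # DLBCL
        if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
            warnings.warn(f"element {elem}: all values tied; p = 1", stacklevel=2)
            stat_val, p = np.nan, 1.0
        elif test == "rank_sum":
            stat_val, p = rank_sum_test(x, y, method="asymptotic")
        elif test == "signed_rank":
            if len(x) != len(y):
                raise ValueError("signed-rank requires paired samples of equal size")
            stat_val, p = stats.wilcoxon(x, y)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({
            "element": elem, "statistic": stat_val, "p": p,
            "median_diff_fl_minus_dlbcl": float(np.median(x) - np.median(y)),
        })
    out = pd.DataFrame(rows).set_index("element")
    out["fdr"] = bh_adjust(out["p"])
    return out
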