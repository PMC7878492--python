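"""Genomic feature handling: annotations, fragments, peaks, and counting.

All coordinates are 0-based half-open internally.  BED input/output is used
natively; GTF (1-based closed) is converted on read/write.  Fragment counting
is unstranded and MAPQ-filtered: a fragment is assigned to every feature it
overlaps by at least one base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "cytoband"]
FRAGMENT_COLUMNS = ["chrom", "start", "end", "name", "mapq", "strand"]

__all__ = [
    "PeakSet",
    "read_annotation",
    "read_fragments_bed",
    "read_narrowpeak",
    "write_annotation_gtf",
    "write_fragments_bed",
    "write_narrowpeak",
    "write_counts_tsv",
    "read_counts_tsv",
    "summarize_features",
    "merge_peaks",
    "intersect_peaks_gene",
]


@dataclass
class PeakSet:
    """A named set of peak intervals for one histone mark.

    ``intervals`` holds columns chrom/start/end (0-based half-open).  When
    ``merged`` is True the intervals are sorted, disjoint, and all
    same-chromosome gaps are >= ``merge_gap``.
    """

    mark: str
    intervals: pd.DataFrame
    merged: bool = False
    merge_gap: int | None = None

    def __post_init__(self) -> None:
        df = self.intervals
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"peak intervals missing columns {sorted(missing)}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("peak intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.intervals)


def _validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in annotation")
    if not (ann["start"] < ann["end"]).all():
        bad = ann.loc[ann["start"] >= ann["end"], "gene_id"].iloc[0]
        raise ValueError(f"gene {bad!r} has start >= end")
    return ann.reset_index(drop=True)


def read_annotation(path, cytoband_path=None) -> pd.DataFrame:
    """Read a gene annotation from GTF or BED, plus an optional cytoband map.

    GTF coordinates (1-based closed) are converted to 0-based half-open; only
    ``gene`` feature lines are used, with gene_id parsed from the attribute
    field.  BED files use columns chrom/start/end/name[/score/strand].  The
    cytoband file is a two-column TSV (gene_id, band); genes without an entry
    get band "NA".
    """
    path = str(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if path.endswith((".gtf", ".gff")):
                    if parts[2] != "gene":
                        continue
                    attrs = parts[8]
                    gene_id = None
                    for chunk in attrs.split(";"):
                        chunk = chunk.strip()
                        if chunk.startswith("gene_id"):
                            gene_id = chunk.split(None, 1)[1].strip().strip('"')
                            break
                    if gene_id is None:
                        raise ValueError("missing gene_id attribute")
                    records.append(
                        (gene_id, parts[0], int(parts[3]) - 1, int(parts[4]),
                         parts[6] if parts[6] in "+-" else ".")
                    )
                else:  # BED: already 0-based half-open
                    name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
                    strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
                    records.append((name, parts[0], int(parts[1]), int(parts[2]), strand))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
    ann = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    if cytoband_path is not None:
        bands = pd.read_csv(cytoband_path, sep="\t", header=None,
                            names=["gene_id", "cytoband"], dtype=str)
        ann = ann.merge(bands, on="gene_id", how="left")
        ann["cytoband"] = ann["cytoband"].fillna("NA")
    else:
        ann["cytoband"] = "NA"
    return _validate_annotation(ann)


def write_annotation_gtf(ann: pd.DataFrame, path, cytoband_path=None) -> None:
    """Write gene records as GTF (converting to 1-based closed) plus band TSV."""
    with open(path, "w") as fh:
        for row in ann.itertuples():
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\thmcseal\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )
    if cytoband_path is not None:
        ann[["gene_id", "cytoband"]].to_csv(
            cytoband_path, sep="\t", header=False, index=False
        )


def read_fragments_bed(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a BED6 fragment file; the score column carries MAPQ."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=FRAGMENT_COLUMNS, dtype={"chrom": str, "name": str, "strand": str},
    )
    if len(df) and ((df["start"] >= df["end"]).any() or (df["mapq"] < 0).any()):
        raise ValueError(f"{path}: invalid fragment coordinates or MAPQ")
    if sample_id is not None:
        df.attrs["sample_id"] = sample_id
    return df


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path, mark: str) -> PeakSet:
    """Read an ENCODE narrowPeak file (only columns 1-3 are used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"], dtype={"chrom": str})
    return PeakSet(mark=mark, intervals=df)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    df = peaks.intervals
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": [f"{peaks.mark}_{i}" for i in range(len(df))],
        "score": 0, "strand": ".", "signalValue": 0.0,
        "pValue": -1, "qValue": -1, "peak": -1,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


# ---------------------------------------------------------------------------
# counting and interval algebra
# ---------------------------------------------------------------------------

def _count_overlaps_one_chrom(starts, ends, f_start, f_end):
    """Counts per feature of fragments overlapping each of the (possibly
    overlapping) feature intervals on one chromosome.

    Disjoint sorted features admit a fully vectorized difference-array sweep;
    overlapping features fall back to an interval tree.
    """
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    counts = np.zeros(len(s), dtype=np.int64)
    disjoint = len(s) < 2 or (s[1:] >= e[:-1]).all()
    if disjoint:
        # fragment [a,b) overlaps feature [s,e) iff a < e and b > s
        lo = np.searchsorted(e, f_start, side="right")
        hi = np.searchsorted(s, f_end, side="left")
        diff = np.zeros(len(s) + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        counts = np.cumsum(diff[:-1])
    else:
        from intervaltree import IntervalTree

        tree = IntervalTree()
        for i in range(len(s)):
            tree.addi(int(s[i]), int(e[i]), i)
        for a, b in zip(f_start, f_end):
            for iv in tree.overlap(int(a), int(b)):
                counts[iv.data] += 1
    out = np.zeros_like(counts)
    out[order] = counts
    return out


def summarize_features(fragments, features, min_mapq: int = 10) -> pd.DataFrame:
    """Summarize per-sample fragments into a feature x sample count matrix.

    Parameters
    ----------
    fragments : mapping of sample_id -> fragment DataFrame (BED6 columns).
    features : gene annotation DataFrame or :class:`PeakSet`.
    min_mapq : fragments with MAPQ below this contribute nothing (the assay's
        convention is >= 10).

    A fragment is counted once for every feature it overlaps by >= 1 bp,
    unstranded.  Chromosomes present in fragments but absent from the
    features are counted as zero overlap (a warning is logged).
    """
    if isinstance(features, PeakSet):
        feat = features.intervals.copy()
        feat["feature_id"] = [f"{features.mark}_{i}" for i in range(len(feat))]
    else:
        feat = features.rename(columns={"gene_id": "feature_id"})
    if len(feat) == 0:
        raise ValueError("feature set is empty")
    feature_ids = feat["feature_id"].to_numpy()
    sample_ids = list(fragments)
    mat = np.zeros((len(feat), len(sample_ids)), dtype=np.int64)
    chrom_groups = {c: idx.to_numpy() for c, idx in feat.groupby("chrom").groups.items()}
    starts = feat["start"].to_numpy()
    ends = feat["end"].to_numpy()
    for j, sid in enumerate(sample_ids):
        fr = fragments[sid]
        fr = fr[fr["mapq"] >= min_mapq]
        for chrom, sub in fr.groupby("chrom", sort=False):
            if chrom not in chrom_groups:
                logger.warning("chromosome %s in fragments of %s absent from features",
                               chrom, sid)
                continue
            idx = chrom_groups[chrom]
            mat[idx, j] += _count_overlaps_one_chrom(
                starts[idx], ends[idx],
                sub["start"].to_numpy(), sub["end"].to_numpy(),
            )
    return pd.DataFrame(mat, index=pd.Index(feature_ids, name="feature_id"),
                        columns=sample_ids)


def merge_peaks(peaks: PeakSet, merge_gap: int = 200) -> PeakSet:
    """Union same-chromosome peaks whose gap is strictly less than merge_gap.

    The gap between [a,b) and [c,d) with c >= b is c - b; merging is
    transitive.  The result is sorted and disjoint with all remaining gaps
    >= merge_gap, and is idempotent.
    """
    df = peaks.intervals
    if len(df) == 0:
        return replace(peaks, merged=True, merge_gap=merge_gap)
    pieces = []
    for chrom, sub in df.groupby("chrom"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        e = np.maximum.accumulate(e)
        # start a new cluster where the gap to the running end is >= merge_gap
        new_cluster = np.ones(len(s), dtype=bool)
        new_cluster[1:] = s[1:] - e[:-1] >= merge_gap
        cluster = np.cumsum(new_cluster) - 1
        n_clusters = cluster[-1] + 1
        cs = np.full(n_clusters, np.iinfo(np.int64).max)
        ce = np.full(n_clusters, np.iinfo(np.int64).min)
        np.minimum.at(cs, cluster, s)
        np.maximum.at(ce, cluster, e)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": cs, "end": ce}))
    merged = pd.concat(pieces, ignore_index=True)
    merged = merged.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(mark=peaks.mark, intervals=merged, merged=True, merge_gap=merge_gap)


def intersect_peaks_gene(peaks: PeakSet, gene) -> list[tuple[int, int]]:
    """Clip merged peak intervals to a gene body.

    ``gene`` is one annotation row (anything with chrom/start/end attributes
    or mapping access).  Returns a list of (start, end) tuples, empty when no
    peak overlaps the gene.
    """
    if not peaks.merged:
        raise ValueError("intersect_peaks_gene requires a merged PeakSet")
    chrom = gene["chrom"] if isinstance(gene, (dict, pd.Series)) else gene.chrom
    gstart = gene["start"] if isinstance(gene, (dict, pd.Series)) else gene.start
    gend = gene["end"] if isinstance(gene, (dict, pd.Series)) else gene.end
    df = peaks.intervals
    sub = df[(df["chrom"] == chrom) & (df["start"] < gend) & (df["end"] > gstart)]
    return [(int(max(s, gstart)), int(min(e, gend)))
            for s, e in zip(sub["start"], sub["end"])]
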