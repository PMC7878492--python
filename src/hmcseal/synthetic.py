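"""Synthetic cohort generator for the cfDNA 5hmC-Seal pipeline.

Emulates the statistical structure the downstream analysis assumes: a
DLBCL/FL clinical table with demographic and survival covariates, a gene
annotation with cytobands, negative-binomial gene-body counts with
library-size variation, small batch/age/gender effects and a planted set of
subtype-differential genes, MAPQ-tagged fragment placements that reproduce
the counts exactly under summarization, and histone-mark narrowPeak sets
that exercise the <200 bp merge rule.  Every generator takes an explicit
integer seed; identical seed means identical output.

Default cohort parameters follow the study design being emulated:
48 DLBCL + 25 FL, DLBCL ages ~ N(58.1, 14.1), FL ages ~ N(53.2, 12.8)
truncated to [20, 95], and Table-1 marginal frequencies for gender, race,
stage, LDH, cell of origin, and vital-status missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .features import FRAGMENT_COLUMNS, PeakSet

__all__ = [
    "SyntheticTruth",
    "generate_cohort",
    "generate_annotation",
    "generate_counts",
    "generate_fragments",
    "generate_peaks",
    "write_truth_json",
    "read_truth_json",
]

#: Per-subtype marginal frequencies from the emulated cohort design.
DEFAULT_MARGINALS = {
    "DLBCL": {
        "age_mean": 58.1, "age_sd": 14.1,
        "male": 30 / 48, "ea": 39 / 48,
        "stage": {"I/II": 17 / 48, "III/IV": 20 / 48, "missing": 11 / 48},
        "ldh": {"elevated": 25 / 48, "not_elevated": 22 / 48, "missing": 1 / 48},
        "coo": {"GCB": 23 / 48, "ABC": 11 / 48, "missing": 14 / 48},
        "vital_missing": 2 / 48,
    },
    "FL": {
        "age_mean": 53.2, "age_sd": 12.8,
        "male": 15 / 25, "ea": 19 / 25,
        "stage": {"I/II": 5 / 25, "III/IV": 17 / 25, "missing": 3 / 25},
        "ldh": {"elevated": 3 / 25, "not_elevated": 21 / 25, "missing": 1 / 25},
        "coo": {"GCB": 0.0, "ABC": 0.0, "missing": 1.0},
        "vital_missing": 0.0,
    },
}

AGE_BOUNDS = (20.0, 95.0)


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a simulated count matrix.

    planted_log2fc is nonzero only for planted genes (positive = higher in
    FL); size factors are strictly positive; dispersions alpha_g satisfy
    Var = mu + alpha_g * mu^2.
    """

    planted_genes: list[str]
    planted_log2fc: dict[str, float]
    sample_size_factors: dict[str, float]
    dispersions: dict[str, float]
    covariate_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, fc in self.planted_log2fc.items():
            if fc != 0.0 and g not in self.planted_genes:
                raise ValueError(f"nonzero log2fc for non-planted gene {g!r}")
        if any(v <= 0 for v in self.sample_size_factors.values()):
            raise ValueError("size factors must be strictly positive")
        if any(v < 0 for v in self.dispersions.values()):
            raise ValueError("dispersions must be >= 0")


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(
    n_dlbcl: int,
    n_fl: int,
    seed: int,
    *,
    marginals: dict | None = None,
    n_batches: int = 2,
    baseline_hazard: float = 0.004,
    log_hr_age_per_decade: float = 0.35,
    log_hr_stage_late: float = 0.5,
    log_hr_dlbcl: float = 0.8,
    censor_range: tuple[float, float] = (12.0, 90.0),
) -> pd.DataFrame:
    """Simulate a DLBCL/FL clinical table.

    Ages come from per-subtype truncated normals; categorical covariates from
    the configurable marginal frequencies; overall survival from an
    exponential model whose log-hazard is linear in age, late stage, and
    subtype, with independent uniform censoring.  Times are in months.
    """
    if n_dlbcl < 2 or n_fl < 2:
        raise ValueError("need at least 2 samples per subtype")
    marg = marginals or DEFAULT_MARGINALS
    rng = np.random.default_rng(seed)
    rows = []
    for subtype, n in (("DLBCL", n_dlbcl), ("FL", n_fl)):
        m = marg[subtype]
        age = _truncnorm(rng, m["age_mean"], m["age_sd"], *AGE_BOUNDS, size=n)
        gender = rng.choice(["M", "F"], size=n, p=[m["male"], 1 - m["male"]])
        race = rng.choice(["EA", "non-EA"], size=n, p=[m["ea"], 1 - m["ea"]])
        stage = rng.choice(list(m["stage"]), size=n, p=list(m["stage"].values()))
        ldh = rng.choice(list(m["ldh"]), size=n, p=list(m["ldh"].values()))
        coo = rng.choice(list(m["coo"]), size=n, p=list(m["coo"].values()))
        batch = rng.integers(0, n_batches, size=n)
        late = (stage == "III/IV").astype(float)
        loghaz = (np.log(baseline_hazard)
                  + log_hr_age_per_decade * (age - 60.0) / 10.0
                  + log_hr_stage_late * late
                  + (log_hr_dlbcl if subtype == "DLBCL" else 0.0))
        t_death = rng.exponential(1.0 / np.exp(loghaz))
        t_censor = rng.uniform(*censor_range, size=n)
        os_time = np.minimum(t_death, t_censor)
        death = (t_death <= t_censor).astype(float)
        vital_missing = rng.random(n) < m["vital_missing"]
        death[vital_missing] = np.nan
        os_time[vital_missing] = np.nan
        for i in range(n):
            rows.append({
                "sample_id": f"{subtype}_{i:03d}",
                "subtype": subtype,
                "age": float(age[i]),
                "gender": gender[i],
                "race": race[i],
                "stage": stage[i],
                "ldh": ldh[i],
                "batch": f"b{batch[i]}",
                "os_time": float(os_time[i]) if np.isfinite(os_time[i]) else np.nan,
                "death_event": float(death[i]) if np.isfinite(death[i]) else np.nan,
                "cell_of_origin": coo[i],
            })
    clinical = pd.DataFrame(rows)
    ok = clinical["os_time"].isna() | (clinical["os_time"] >= 0)
    assert ok.all()
    return clinical


def generate_annotation(
    n_genes: int,
    n_chroms: int,
    chrom_length: int,
    seed: int,
    *,
    gene_length_range: tuple[int, int] = (5_000, 20_000),
    bands_per_chrom: int = 10,
) -> pd.DataFrame:
    """Place non-overlapping gene bodies on synthetic chromosomes.

    Genes are distributed round-robin over chromosomes; per chromosome, gene
    lengths are drawn uniformly from ``gene_length_range`` and the leftover
    sequence is split into random inter-gene gaps, so genes never overlap.
    Each chromosome is partitioned into ``bands_per_chrom`` contiguous
    cytobands with uneven (Dirichlet) widths; a gene's band is the band
    containing its midpoint, so band gene-counts vary and larger bands
    typically hold six or more genes when n_genes/bands is large enough.
    """
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0)
                 for c in range(n_chroms)]
    records = []
    gid = 0
    for c, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1,
                               size=n_on_chrom)
        slack = chrom_length - int(lengths.sum())
        if slack < 0:
            raise ValueError(
                f"cannot pack {n_on_chrom} genes of total length {lengths.sum()} "
                f"into chromosome of length {chrom_length}"
            )
        # random split of the slack into n+1 gaps
        gaps = rng.multinomial(slack, np.ones(n_on_chrom + 1) / (n_on_chrom + 1))
        # cytoband boundaries: uneven contiguous partition
        widths = rng.dirichlet(np.full(bands_per_chrom, 0.8)) * chrom_length
        band_edges = np.concatenate([[0], np.cumsum(widths)])
        band_edges[-1] = chrom_length
        pos = 0
        for k in range(n_on_chrom):
            pos += int(gaps[k])
            start, end = pos, pos + int(lengths[k])
            pos = end
            mid = (start + end) // 2
            band = int(np.searchsorted(band_edges, mid, side="right") - 1)
            band = min(band, bands_per_chrom - 1)
            records.append({
                "gene_id": f"G{gid:05d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": rng.choice(["+", "-"]),
                "cytoband": f"{chrom}b{band}",
            })
            gid += 1
        assert pos <= chrom_length
    return pd.DataFrame(records)


def generate_counts(
    clinical: pd.DataFrame,
    annotation: pd.DataFrame,
    n_planted: int,
    log2fc: float,
    dispersion: float,
    libsize_cv: float,
    seed: int,
    *,
    baseline_log_mean: float = np.log(40.0),
    baseline_log_sd: float = 1.0,
    batch_sd_log2: float = 0.1,
    age_sd_log2_per_decade: float = 0.05,
    gender_sd_log2: float = 0.05,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a negative-binomial gene x sample count matrix with ground truth.

    Counts are NB with mean ``s_i * q_g * 2**(x_i . beta_g)`` where the s_i
    are lognormal size factors with coefficient of variation ``libsize_cv``,
    q_g are lognormal baselines, and beta_g holds the subtype effect
    (+-log2fc with random sign for the ``n_planted`` planted genes, positive
    meaning higher in FL) plus small per-gene batch/age/gender effects drawn
    from centred normals.  ``dispersion`` is the NB alpha (Var = mu +
    alpha mu^2); 0 gives the Poisson limit.
    """
    genes = annotation["gene_id"].to_numpy()
    if n_planted >= len(genes):
        raise ValueError("n_planted must be smaller than the number of genes")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    samples = clinical["sample_id"].to_numpy()
    n, g = len(samples), len(genes)

    if libsize_cv > 0:
        sigma2 = np.log1p(libsize_cv**2)
        s = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)
    else:
        s = np.ones(n)
    q = rng.lognormal(baseline_log_mean, baseline_log_sd, size=g)

    planted = rng.choice(genes, size=n_planted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    beta_subtype = np.zeros(g)
    planted_idx = {gene: i for i, gene in enumerate(genes)}
    for gene, sign in zip(planted, signs):
        beta_subtype[planted_idx[gene]] = sign * log2fc

    beta_batch = rng.normal(0.0, batch_sd_log2, size=g)
    beta_age = rng.normal(0.0, age_sd_log2_per_decade, size=g)
    beta_gender = rng.normal(0.0, gender_sd_log2, size=g)

    is_fl = (clinical["subtype"] == "FL").to_numpy(dtype=float)
    batch_codes = pd.Categorical(clinical["batch"]).codes.astype(float)
    batch_centered = batch_codes - batch_codes.mean()
    age_decades = (clinical["age"].to_numpy() - 60.0) / 10.0
    is_male = (clinical["gender"] == "M").to_numpy(dtype=float) - 0.5

    log2_effect = (np.outer(beta_subtype, is_fl)
                   + np.outer(beta_batch, batch_centered)
                   + np.outer(beta_age, age_decades)
                   + np.outer(beta_gender, is_male))
    mu = q[:, None] * s[None, :] * np.exp2(log2_effect)

    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        counts = rng.poisson(rng.gamma(shape, mu / shape))
    counts_df = pd.DataFrame(counts.astype(np.int64),
                             index=pd.Index(genes, name="feature_id"),
                             columns=samples)
    truth = SyntheticTruth(
        planted_genes=[str(x) for x in planted],
        planted_log2fc={str(gene): float(sign * log2fc)
                        for gene, sign in zip(planted, signs)},
        sample_size_factors={str(sid): float(v) for sid, v in zip(samples, s)},
        dispersions={str(gene): float(dispersion) for gene in genes},
        covariate_effects={
            "batch_sd_log2": batch_sd_log2,
            "age_sd_log2_per_decade": age_sd_log2_per_decade,
            "gender_sd_log2": gender_sd_log2,
        },
    )
    return counts_df, truth


def generate_fragments(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    fragment_length: int,
    mapq_low_fraction: float,
    seed: int,
    *,
    intergenic_fraction: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Place fragments consistent with a count matrix, per sample.

    For every gene/sample cell with count c, exactly c fragments of length
    ``fragment_length`` with MAPQ >= 10 are placed fully inside the gene
    body, so MAPQ-filtered summarization against non-overlapping genes
    recovers the counts exactly.  Decoy fragments with MAPQ < 10 (a
    ``mapq_low_fraction`` share of all emitted fragments) are scattered
    anywhere, and a share of high-MAPQ intergenic fragments is placed in
    gaps between genes when gaps of sufficient length exist.
    """
    gene_len = annotation["end"] - annotation["start"]
    if (fragment_length >= gene_len).any():
        raise ValueError("fragment_length must be shorter than every gene body")
    if not 0 <= mapq_low_fraction < 1:
        raise ValueError("mapq_low_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("gene_id").loc[counts.index]
    gstart = ann["start"].to_numpy()
    gend = ann["end"].to_numpy()
    gchrom = ann["chrom"].to_numpy()
    chrom_max = {c: int(e) for c, e in ann.groupby("chrom")["end"].max().items()}

    # candidate intergenic windows per chromosome (gaps long enough)
    gaps: list[tuple[str, int, int]] = []
    for chrom, sub in ann.sort_values("start").groupby("chrom"):
        prev = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s - prev >= fragment_length:
                gaps.append((chrom, prev, int(s)))
            prev = int(e)

    out = {}
    for sid in counts.columns:
        c = counts[sid].to_numpy()
        n_true = int(c.sum())
        reps = np.repeat(np.arange(len(c)), c)
        starts = (gstart[reps]
                  + rng.integers(0, gend[reps] - gstart[reps] - fragment_length + 1))
        frames = [pd.DataFrame({
            "chrom": gchrom[reps],
            "start": starts,
            "end": starts + fragment_length,
            "mapq": rng.integers(10, 61, size=n_true),
        })]
        n_inter = int(round(intergenic_fraction * n_true)) if gaps else 0
        if n_inter:
            pick = rng.integers(0, len(gaps), size=n_inter)
            ic = [gaps[i][0] for i in pick]
            istart = np.array([rng.integers(gaps[i][1], gaps[i][2] - fragment_length + 1)
                               for i in pick])
            frames.append(pd.DataFrame({
                "chrom": ic, "start": istart, "end": istart + fragment_length,
                "mapq": rng.integers(10, 61, size=n_inter),
            }))
        n_high = n_true + n_inter
        n_low = int(round(mapq_low_fraction / (1 - mapq_low_fraction) * n_high))
        if n_low:
            chroms = list(chrom_max)
            pick = rng.integers(0, len(chroms), size=n_low)
            lc = [chroms[i] for i in pick]
            lstart = np.array([rng.integers(0, chrom_max[chroms[i]] - fragment_length + 1)
                               for i in pick])
            frames.append(pd.DataFrame({
                "chrom": lc, "start": lstart, "end": lstart + fragment_length,
                "mapq": rng.integers(0, 10, size=n_low),
            }))
        df = pd.concat(frames, ignore_index=True)
        df["name"] = [f"{sid}_f{i}" for i in range(len(df))]
        df["strand"] = rng.choice(["+", "-"], size=len(df))
        out[sid] = df[FRAGMENT_COLUMNS]
    return out


def generate_peaks(
    annotation: pd.DataFrame,
    marks: list[str],
    seed: int,
    *,
    peaks_per_mark: int | None = None,
    genic_fraction: float = 0.7,
    peak_length_range: tuple[int, int] = (200, 1000),
) -> dict[str, PeakSet]:
    """Emit narrowPeak-style interval sets, one per histone mark.

    A ``genic_fraction`` share of peaks is placed overlapping randomly chosen
    gene bodies, the rest anywhere on the chromosomes.  Every mark's set is
    guaranteed to contain one same-chromosome pair of peaks separated by a
    gap of 199 bp (which the <200 bp rule merges) and one pair separated by
    exactly 200 bp (which it must not merge).
    """
    if not marks:
        raise ValueError("marks must be non-empty")
    rng = np.random.default_rng(seed)
    n_peaks = peaks_per_mark or max(20, len(annotation) // 2)
    chrom_len = {c: int(e) for c, e in annotation.groupby("chrom")["end"].max().items()}
    chroms = list(chrom_len)
    out = {}
    for mark in marks:
        rows = []
        for _ in range(n_peaks):
            length = int(rng.integers(*peak_length_range))
            if rng.random() < genic_fraction:
                g = annotation.iloc[int(rng.integers(0, len(annotation)))]
                lo = max(0, int(g["start"]) - length + 1)
                hi = int(g["end"]) - 1
                start = int(rng.integers(lo, hi + 1))
            else:
                chrom_pick = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, chrom_len[chrom_pick] - length))
                rows.append({"chrom": chrom_pick, "start": start, "end": start + length})
                continue
            rows.append({"chrom": g["chrom"], "start": start, "end": start + length})
        # guaranteed merge-rule probes on the first chromosome, past the genes
        probe_chrom = chroms[0]
        base = chrom_len[probe_chrom] + 10_000
        rows.append({"chrom": probe_chrom, "start": base, "end": base + 300})
        rows.append({"chrom": probe_chrom, "start": base + 499, "end": base + 799})
        base2 = base + 5_000
        rows.append({"chrom": probe_chrom, "start": base2, "end": base2 + 300})
        rows.append({"chrom": probe_chrom, "start": base2 + 500, "end": base2 + 800})
        df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        out[mark] = PeakSet(mark=mark, intervals=df)
    return out


def write_truth_json(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)


def read_truth_json(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth(**json.load(fh))
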