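"""Self-validation suites: the checks that qualify the pipeline end to end.

Each function runs one validation study from scratch — rebuilding its
inputs, running the relevant pipeline stages, and measuring the result —
and returns a plain dict of numbers.  They back both the validation tests
and the reproduction script.

The reference cohort table (study-design category counts: 48 DLBCL / 25 FL
with the published sex, race, stage, LDH and vital-status breakdowns) is an
input to the characteristics check; ages in that table are synthetic
placeholders, so the age t-test is not part of the check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import clinical as clin_mod
from . import diffmod, signature, synthetic
from ._stats import logrank_statistic, rank_sum_test
from .features import PeakSet, merge_peaks, summarize_features
from .pipeline import run_end_to_end

#: study-design category counts per subtype:
#: (n, males, EA, (stage I/II, III/IV, missing), (LDH elev, not, missing),
#:  (alive, dead, missing))
REFERENCE_COUNTS = {
    "DLBCL": (48, 30, 39, (17, 20, 11), (25, 22, 1), (34, 12, 2)),
    "FL": (25, 15, 19, (5, 17, 3), (3, 21, 1), (23, 2, 0)),
}


def build_reference_cohort() -> pd.DataFrame:
    """Clinical table realizing the reference category counts exactly."""
    rows = []
    for subtype, (n, males, ea, stage, ldh, vital) in REFERENCE_COUNTS.items():
        gender = ["M"] * males + ["F"] * (n - males)
        race = ["EA"] * ea + ["non-EA"] * (n - ea)
        stages = (["I/II"] * stage[0] + ["III/IV"] * stage[1]
                  + ["missing"] * stage[2])
        ldhs = (["elevated"] * ldh[0] + ["not_elevated"] * ldh[1]
                + ["missing"] * ldh[2])
        vitals = [0.0] * vital[0] + [1.0] * vital[1] + [np.nan] * vital[2]
        for i in range(n):
            rows.append({
                "sample_id": f"{subtype}_{i:03d}", "subtype": subtype,
                "age": 55.0 + i % 9, "gender": gender[i], "race": race[i],
                "stage": stages[i], "ldh": ldhs[i], "batch": "b0",
                "os_time": 24.0, "death_event": vitals[i],
                "cell_of_origin": "missing",
            })
    return pd.DataFrame(rows)


def characteristics_pvalues() -> dict[str, float]:
    """Chi-square p-values of the reference cohort characteristics."""
    rep = clin_mod.characteristics_table(build_reference_cohort())

    def p_of(var):
        return float(rep.loc[rep["variable"] == var, "p"].dropna().iloc[0])

    return {
        "sex_p": p_of("gender"),
        "race_p": p_of("race"),
        "stage_p": p_of("stage"),
        "ldh_p": p_of("ldh"),
    }


def permutation_calibration(seed: int, n_genes: int = 2000,
                            n_per_group: int = 36, B: int = 1000) -> dict:
    """Null-data empirical p-value calibration study.

    Simulates a cohort with no planted effects, runs the NB Wald +
    permutation machinery, and summarizes uniformity of the empirical
    p-values (KS test) and the rejection rate at 0.05 with its Monte-Carlo
    standard error.
    """
    rng = np.random.default_rng(seed)
    s = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    cohort = synthetic.generate_cohort(n_per_group, n_per_group, seed=s())
    ann = synthetic.generate_annotation(n_genes, 5, 60_000_000, seed=s())
    counts, _ = synthetic.generate_counts(cohort, ann, 0, 0.0, 0.1, 0.3,
                                          seed=s())
    counts = diffmod.filter_nonzero_variance(counts)
    sf = diffmod.size_factors(counts)
    table = diffmod.nb_wald_test(counts, cohort, sf=sf)
    emp = diffmod.empirical_pvalues(counts, cohort, sf=sf, B=B, seed=s(),
                                    table=table)
    e = emp.dropna().to_numpy()
    frac = float((e < 0.05).mean())
    mc_se = float(np.sqrt(0.05 * 0.95 / len(e)))
    return {
        "ks_p": float(stats.kstest(e, "uniform").pvalue),
        "frac_below_005": frac,
        "mc_se": mc_se,
        "n_genes": int(len(e)),
    }


def planted_recovery(seed: int, n_seeds: int = 20, n_genes: int = 2000,
                     n_dlbcl: int = 48, n_fl: int = 25, n_planted: int = 4,
                     log2fc: float = 1.0, dispersion: float = 0.1,
                     repeats: int = 50, threshold: float = 0.90) -> dict:
    """Stability-selection parameter-recovery study.

    For each replicate seed: simulate the cohort with planted
    subtype-differential genes, run stability selection over the full gene
    matrix (age and gender forced in), and score a success when all planted
    genes and at most one false gene are retained.
    """
    rng = np.random.default_rng(seed)
    successes = 0
    tps, fps = [], []
    for _ in range(n_seeds):
        s = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
        cohort = synthetic.generate_cohort(n_dlbcl, n_fl, seed=s())
        ann = synthetic.generate_annotation(n_genes, 5, 60_000_000, seed=s())
        counts, truth = synthetic.generate_counts(
            cohort, ann, n_planted, log2fc, dispersion, 0.3, seed=s())
        counts = diffmod.filter_nonzero_variance(counts)
        sf = diffmod.size_factors(counts)
        levels = diffmod.normalized_log2(counts, sf).T
        clin = cohort.set_index("sample_id")
        feats = levels.copy()
        feats["age"] = clin.loc[feats.index, "age"].to_numpy(float)
        feats["gender_M"] = (clin.loc[feats.index, "gender"] == "M"
                             ).to_numpy(float)
        v = np.ones(feats.shape[1])
        v[-2:] = 0.0
        spec = signature.PenalizedLogisticSpec(alpha=0.5, penalty_factors=v)
        y = (clin.loc[feats.index, "subtype"] == "FL").to_numpy(float)
        selected, _ = signature.stability_selection(
            feats, y, spec, repeats=repeats, threshold=threshold, seed=s())
        tp = sum(g in truth.planted_genes for g in selected)
        fp = len(selected) - tp
        tps.append(tp)
        fps.append(fp)
        successes += (tp == n_planted) and (fp <= 1)
    return {
        "success_rate": successes / n_seeds,
        "mean_true_positives": float(np.mean(tps)),
        "mean_false_positives": float(np.mean(fps)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# brute-force oracles for the equivalence study
# ---------------------------------------------------------------------------

def _brute_merge(df: pd.DataFrame, gap: int):
    rows = sorted(df.itertuples(index=False), key=lambda r: (r.chrom, r.start))
    out = []
    for r in rows:
        if out and out[-1][0] == r.chrom and r.start - out[-1][2] < gap:
            out[-1][2] = max(out[-1][2], r.end)
        else:
            out.append([r.chrom, r.start, r.end])
    return [(c, s, e) for c, s, e in out]


def _brute_counts(frag: pd.DataFrame, feat: pd.DataFrame, min_mapq=10):
    out = np.zeros(len(feat), dtype=int)
    for fr in frag.itertuples(index=False):
        if fr.mapq < min_mapq:
            continue
        for k, fe in enumerate(feat.itertuples(index=False)):
            if (fr.chrom == fe.chrom and fr.start < fe.end
                    and fr.end > fe.start):
                out[k] += 1
    return out


def _brute_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return conc / (len(pos) * len(neg))


def oracle_agreement(seed: int, n_instances: int = 100) -> dict:
    """Agreement rates between the package's interval/rank/survival
    statistics and independent brute-force or reference implementations on
    random small instances (1.0 = full agreement)."""
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(seed)
    agree = {k: 0 for k in ("merge", "summarize", "auc", "rank_sum",
                            "logrank")}
    for _ in range(n_instances):
        # peak merging
        n = int(rng.integers(2, 60))
        s = rng.integers(0, 20_000, size=n)
        df = pd.DataFrame({"chrom": rng.choice(["c1", "c2"], size=n),
                           "start": s, "end": s + rng.integers(1, 600, size=n)})
        gap = int(rng.integers(1, 400))
        got = list(merge_peaks(PeakSet("m", df), gap)
                   .intervals.itertuples(index=False, name=None))
        agree["merge"] += got == _brute_merge(df, gap)

        # fragment counting
        nf, ng = int(rng.integers(5, 60)), int(rng.integers(2, 12))
        gs = rng.integers(0, 30_000, size=ng)
        feat = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(ng)],
            "chrom": rng.choice(["c1", "c2"], size=ng),
            "start": gs, "end": gs + rng.integers(200, 3000, size=ng),
            "strand": "+", "cytoband": "NA"})
        fs = rng.integers(0, 32_000, size=nf)
        frag = pd.DataFrame({
            "chrom": rng.choice(["c1", "c2", "c3"], size=nf),
            "start": fs, "end": fs + rng.integers(1, 300, size=nf),
            "name": "f", "mapq": rng.integers(0, 61, size=nf), "strand": "."})
        got = summarize_features({"s": frag}, feat)["s"].to_numpy()
        agree["summarize"] += bool((got == _brute_counts(frag, feat)).all())

        # AUC
        m = int(rng.integers(6, 30))
        scores = rng.integers(0, 10, size=m).astype(float)
        labels = rng.integers(0, 2, size=m)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc = signature.roc_auc(scores, labels).auc
        agree["auc"] += bool(np.isclose(auc, _brute_auc(scores, labels)))

        # rank-sum: brute-force U plus reference asymptotic p
        n1, n2 = int(rng.integers(3, 10)), int(rng.integers(3, 10))
        x = rng.integers(0, 10, size=n1).astype(float)
        yv = rng.integers(0, 10, size=n2).astype(float)
        u, p = rank_sum_test(x, yv)
        u_brute = sum((a > b) + 0.5 * (a == b) for a in x for b in yv)
        if np.ptp(np.concatenate([x, yv])) == 0:
            ref_ok = p == 1.0
        else:
            ref = stats.mannwhitneyu(x, yv, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=False)
            ref_ok = np.isclose(p, ref.pvalue)
        agree["rank_sum"] += bool(np.isclose(u, u_brute) and ref_ok)

        # log-rank vs lifelines
        ns = int(rng.integers(8, 30))
        time = rng.exponential(10, size=ns).round(1) + 0.1
        event = rng.integers(0, 2, size=ns)
        group = np.r_[np.zeros(ns // 2), np.ones(ns - ns // 2)]
        if event.sum() == 0:
            event[0] = 1
        chi2, p = logrank_statistic(time, event, group)
        ref = logrank_test(time[group == 0], time[group == 1],
                           event[group == 0], event[group == 1])
        agree["logrank"] += bool(np.isclose(chi2, ref.test_statistic)
                                 and np.isclose(p, ref.p_value))
    return {f"{k}_agreement": v / n_instances for k, v in agree.items()}


def size_factor_recovery(seed: int, n_genes: int = 1000,
                         n_samples: int = 20) -> dict:
    """Median-of-ratios recovery of true library-size factors (max relative
    error after removing the global scale)."""
    rng = np.random.default_rng(seed)
    s = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    cohort = synthetic.generate_cohort(n_samples // 2,
                                       n_samples - n_samples // 2, seed=s())
    ann = synthetic.generate_annotation(n_genes, 2, 60_000_000, seed=s())
    counts, truth = synthetic.generate_counts(cohort, ann, 0, 0.0, 0.1, 0.4,
                                              seed=s())
    sf = diffmod.size_factors(diffmod.filter_nonzero_variance(counts))
    true = np.array([truth.sample_size_factors[c] for c in sf.index])
    ratio = sf.to_numpy() / true
    return {"max_relative_error": float(np.abs(ratio / ratio.mean() - 1).max()),
            "n_genes": n_genes, "n_samples": n_samples}


def end_to_end_smoke(seed: int) -> dict:
    """Full-pipeline run on the 73-sample cohort with strong planted signal."""
    res = run_end_to_end(seed)
    return {
        "roundtrip_exact": float(res["roundtrip_exact"]),
        "n_called": res["call_summary"]["n_called"],
        "n_selected": len(res["selected_genes"]),
        "train_auc": res["roc_train"].auc,
        "test_auc": res["roc_test"].auc,
        "test_auc_ci_low": res["roc_test"].ci_low,
        "logrank_p": res["logrank"]["p"],
    }
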