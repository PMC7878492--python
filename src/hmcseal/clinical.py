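"""Cohort characteristics and survival analysis.

Characteristics follow the published-table conventions for this design:
age by pooled-variance Student's t-test; complete two-level variables (sex,
race) by Pearson chi-square with Yates continuity correction; variables
with a Missing level (stage, LDH, vital status) by Pearson chi-square over
all levels including Missing as its own category, without continuity
correction.  Survival: median-split groups, product-limit (Kaplan-Meier)
curves with a two-group log-rank test, and covariate-adjusted Cox
proportional hazards (Efron ties, via lifelines).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import logrank_statistic

__all__ = [
    "characteristics_table",
    "median_split",
    "km_curves",
    "km_logrank",
    "cox_ph",
    "plot_km",
]

_MISSING_TOKENS = {"missing", "na", "nan", ""}


def _norm_missing(series: pd.Series) -> pd.Series:
    s = series.astype(object).where(series.notna(), "Missing")
    return s.map(lambda v: "Missing" if str(v).strip().lower() in _MISSING_TOKENS else v)


def _crosstab(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    return pd.crosstab(values, groups)


def characteristics_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-variable group summaries and tests between DLBCL and FL.

    Returns one row per variable/level with per-group counts (or mean/SD and
    median/min/max for age) plus the test name and p-value on the variable's
    first row.  Raises when a contingency table has an expected count of 0,
    naming the cell.
    """
    if clinical["subtype"].isna().any():
        raise ValueError("every sample needs a subtype")
    groups = clinical["subtype"]
    rows = []

    age = clinical["age"]
    a1 = age[groups == "DLBCL"]
    a2 = age[groups == "FL"]
    _, p_age = stats.ttest_ind(a1, a2, equal_var=True)
    rows.append({
        "variable": "age", "level": "mean (SD)",
        "DLBCL": f"{a1.mean():.1f} ({a1.std(ddof=1):.1f})",
        "FL": f"{a2.mean():.1f} ({a2.std(ddof=1):.1f})",
        "test": "Student t (pooled)", "p": float(p_age),
    })
    rows.append({
        "variable": "age", "level": "median (min, max)",
        "DLBCL": f"{a1.median():.1f} ({a1.min():.0f}, {a1.max():.0f})",
        "FL": f"{a2.median():.1f} ({a2.min():.0f}, {a2.max():.0f})",
        "test": "", "p": np.nan,
    })

    specs = [
        ("gender", False), ("race", False),
        ("stage", True), ("ldh", True),
    ]
    if "death_event" in clinical:
        vital = _norm_missing(clinical["death_event"]).map(
            {0.0: "Alive", 1.0: "Dead"}).fillna("Missing")
        clinical = clinical.assign(vital_status=vital)
        specs.append(("vital_status", True))
    for var, has_missing in specs:
        if var not in clinical:
            continue
        vals = _norm_missing(clinical[var]) if has_missing else clinical[var]
        tab = _crosstab(vals, groups)
        if has_missing and "Missing" in tab.index and (tab.loc["Missing"] == 0).all():
            tab = tab.drop(index="Missing")
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.to_numpy().sum()
        if (expected == 0).any():
            i, j = np.argwhere(expected == 0)[0]
            raise ValueError(
                f"{var}: expected count 0 in cell ({tab.index[i]}, {tab.columns[j]})"
            )
        correction = tab.shape == (2, 2) and not has_missing
        chi2, p, dof, _ = stats.chi2_contingency(tab, correction=correction)
        name = "chi-square (Yates)" if correction else "chi-square"
        for k, level in enumerate(tab.index):
            rows.append({
                "variable": var, "level": str(level),
                "DLBCL": int(tab.loc[level].get("DLBCL", 0)),
                "FL": int(tab.loc[level].get("FL", 0)),
                "test": name if k == 0 else "",
                "p": float(p) if k == 0 else np.nan,
            })
    return pd.DataFrame(rows)


def median_split(levels: pd.Series, clinical: pd.DataFrame | None = None) -> pd.Series:
    """Split samples at the median of a gene's normalized 5hmC level.

    Values strictly above the median are "high", the rest "low"; an odd-n
    unique median sample therefore lands in "low".  All-equal values are a
    degenerate split and raise.
    """
    vals = levels.astype(float)
    if vals.nunique() == 1:
        raise ValueError("all values equal; median split is degenerate")
    med = vals.median()
    return pd.Series(np.where(vals > med, "high", "low"), index=vals.index,
                     name="group")


def km_curves(time, event, groups) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns, per group label, a DataFrame of event times, numbers at risk,
    events, and the Kaplan-Meier survival estimate.  With no censoring the
    estimate equals the empirical survival function.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    out = {}
    for lab in np.unique(groups):
        t = time[groups == lab]
        e = event[groups == lab]
        if len(t) == 0:
            raise ValueError(f"group {lab!r} has no subjects")
        order = np.argsort(t)
        t, e = t[order], e[order]
        surv = 1.0
        recs = [{"time": 0.0, "n_risk": len(t), "n_events": 0, "survival": 1.0}]
        for tt in np.unique(t[e == 1]):
            n_risk = int((t >= tt).sum())
            d = int(((t == tt) & (e == 1)).sum())
            surv *= 1.0 - d / n_risk
            recs.append({"time": float(tt), "n_risk": n_risk, "n_events": d,
                         "survival": surv})
        out[str(lab)] = pd.DataFrame(recs)
    return out


def km_logrank(time, event, groups):
    """Kaplan-Meier curves plus the two-group log-rank test.

    Returns (curves dict, chi2, p).  The chi-square has 1 df and is built
    from observed and hypergeometric-expected events at each distinct event
    time; it is invariant under relabeling of the two groups.
    """
    curves = km_curves(time, event, groups)
    chi2, p = logrank_statistic(time, event, groups)
    return curves, chi2, p


def cox_ph(clinical: pd.DataFrame, covariates=("age", "gender"),
           group: pd.Series | None = None) -> pd.DataFrame:
    """Covariate-adjusted Cox proportional hazards model of overall survival.

    Fits os_time/death_event on the requested covariates (gender coded
    M = 1, stage coded late = 1 with missing-stage rows dropped) plus an
    optional median-split group (high = 1).  Efron tie handling.  Returns a
    table of hazard ratios with Wald 95% CIs; warns when events are fewer
    than covariates.  Monotone-likelihood failures surface as an error
    suggesting penalization.
    """
    import warnings as _w

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = clinical.dropna(subset=["os_time", "death_event"]).copy()
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = df["age"].astype(float)
        elif cov == "gender":
            cols["gender_M"] = (df["gender"] == "M").astype(float)
        elif cov == "stage":
            stage = _norm_missing(df["stage"])
            keep = stage != "Missing"
            df = df[keep]
            for key in cols:
                cols[key] = cols[key][keep]
            cols["stage_late"] = (stage[keep] == "III/IV").astype(float)
        else:
            cols[cov] = df[cov].astype(float)
    model_df = pd.DataFrame(cols, index=df.index)
    if group is not None:
        g = group.reindex(df["sample_id"]).to_numpy()
        model_df["group_high"] = (g == "high").astype(float)
    model_df["os_time"] = df["os_time"].astype(float)
    model_df["death_event"] = df["death_event"].astype(float)
    n_events = int(model_df["death_event"].sum())
    n_covs = model_df.shape[1] - 2
    if n_events < n_covs:
        _w.warn(f"only {n_events} events for {n_covs} covariates; estimates "
                "are unstable", stacklevel=2)
    cph = CoxPHFitter()
    try:
        cph.fit(model_df, duration_col="os_time", event_col="death_event")
    except ConvergenceError as exc:
        raise RuntimeError(
            "Cox model did not converge (possibly monotone likelihood); "
            "consider a penalized fit (CoxPHFitter(penalizer=...))"
        ) from exc
    out = cph.summary[["coef", "exp(coef)", "exp(coef) lower 95%",
                       "exp(coef) upper 95%", "p"]].copy()
    out.columns = ["coef", "hr", "hr_ci_low", "hr_ci_high", "p"]
    out.attrs["n_events"] = n_events
    out.attrs["n_samples"] = len(model_df)
    return out


def plot_km(curves: dict[str, pd.DataFrame], path, title: str = "") -> None:
    """Step-plot Kaplan-Meier curves to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, df in curves.items():
        ax.step(df["time"], df["survival"], where="post", label=lab)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
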