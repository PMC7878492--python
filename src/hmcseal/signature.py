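"""Subtype signature: elastic-net stability selection and the integrated
classifier.

The feature-selection input is the differential gene set's normalized 5hmC
levels (log2(count/size-factor + 1)); age and gender ride along as
always-in covariates with penalty factor 0.  Selection repeats a
10-fold-CV elastic-net fit (alpha = 0.5 by default — the paper-style
lasso/ridge blend midpoint) with fresh fold randomization, and genes with
nonzero coefficients in at least a 90% share of repeats form the signature.
The integrated model is an unpenalized logistic refit of subtype on the
signature genes plus age and gender, evaluated by ROC AUC with DeLong (or
stratified-bootstrap) confidence intervals.  The positive class is FL.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ._elasticnet import enet_logistic_path, lambda_grid

__all__ = [
    "PenalizedLogisticSpec",
    "SignatureModel",
    "ROCResult",
    "split_train_test",
    "fit_penalized_logistic",
    "cv_select_lambda",
    "stability_selection",
    "fit_integrated_model",
    "roc_auc",
]


@dataclass
class PenalizedLogisticSpec:
    """Configuration of the penalized logistic fit.

    alpha blends lasso (1) and ridge (0); lambda_grid is decreasing (None =
    computed from the data); penalty_factors v_j >= 0 per feature (0 forces
    a feature in, e.g. age and gender); n_folds for cross-validation.
    """

    alpha: float = 0.5
    lambda_grid: np.ndarray | None = None
    penalty_factors: np.ndarray | None = None
    n_folds: int = 10
    n_lambda: int = 100
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lambda_grid is not None and (np.asarray(self.lambda_grid) <= 0).any():
            raise ValueError("lambdas must be positive")
        if self.penalty_factors is not None and (
            np.asarray(self.penalty_factors) < 0
        ).any():
            raise ValueError("penalty factors must be >= 0")


@dataclass
class SignatureModel:
    """Fitted integrated classifier: intercept + coefficients on the
    original feature scale (selected genes' 5hmC levels, age, gender M=1).

    ``score`` returns the linear predictor (logit of P(FL)); scoring is
    deterministic given inputs.
    """

    features: list[str]
    intercept: float
    coefficients: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    seed: int | None = None
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coefficients):
            raise ValueError("feature list and coefficient vector length differ")

    def score(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.features].to_numpy(float) @ self.coefficients

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(self.score(X), -30, 30)))

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "feature_means": list(map(float, self.feature_means)),
            "feature_sds": list(map(float, self.feature_sds)),
            "seed": self.seed,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "degenerate": self.degenerate,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            d = json.load(fh)
        d["coefficients"] = np.asarray(d["coefficients"])
        d["feature_means"] = np.asarray(d["feature_means"])
        d["feature_sds"] = np.asarray(d["feature_sds"])
        return cls(**d)


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError("CI must satisfy 0 <= low <= auc <= high <= 1")


def split_train_test(clinical: pd.DataFrame, seed: int):
    """Near-equal train/test split within subtype, balanced on gender/age.

    Within each subtype, samples are ordered by gender then age and split
    into adjacent pairs; one member of each pair goes to train at random,
    the other to test, so gender and age distributions stay balanced.  An
    odd leftover sample joins the training set, making the training side
    ceil(n/2) per subtype (48+25 gives the 24+13 / 24+12 arrangement).
    Strata with fewer than two samples simply pair across strata (the
    adjacency ordering degrades gracefully).
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, sub in clinical.groupby("subtype"):
        ordered = sub.sort_values(["gender", "age"], kind="mergesort")
        ids = ordered["sample_id"].tolist()
        for k in range(0, len(ids) - 1, 2):
            a, b = ids[k], ids[k + 1]
            if rng.random() < 0.5:
                a, b = b, a
            train.append(a)
            test.append(b)
        if len(ids) % 2:
            train.append(ids[-1])
    return train, test


def fit_penalized_logistic(X, y, spec: PenalizedLogisticSpec):
    """Elastic-net logistic coefficient path (see ``_elasticnet``).

    X is samples x features (array or DataFrame); y binary.  Returns the
    path dict with lambdas, intercepts and original-scale coefficients.
    """
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    return enet_logistic_path(
        Xa, np.asarray(y), alpha=spec.alpha, lambdas=spec.lambda_grid,
        penalty_factors=spec.penalty_factors, standardize=spec.standardize,
        n_lambda=spec.n_lambda,
    )


def _binomial_deviance(y, p):
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return -2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))


def cv_select_lambda(X, y, spec: PenalizedLogisticSpec, seed: int):
    """Choose lambda by stratified k-fold CV at minimum mean binomial
    deviance.

    The fold count is capped at the smaller class size so every fold keeps
    both classes.  Returns (lambda, lambda grid, mean deviance per lambda).
    """
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < spec.n_folds:
        raise ValueError("fewer samples than folds")
    v = (np.ones(Xa.shape[1]) if spec.penalty_factors is None
         else np.asarray(spec.penalty_factors, float))
    if spec.lambda_grid is None:
        sd = Xa.std(axis=0)
        kept = sd > 0
        Xs = (Xa[:, kept] - Xa[:, kept].mean(axis=0)) / sd[kept]
        grid = lambda_grid(Xs, y, spec.alpha, v[kept], n_lambda=spec.n_lambda)
    else:
        grid = np.asarray(spec.lambda_grid, float)
    n_min_class = int(min((y == c).sum() for c in np.unique(y)))
    n_splits = max(2, min(spec.n_folds, n_min_class))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(seed))
    dev = np.zeros((n_splits, len(grid)))
    for f, (tr, va) in enumerate(skf.split(Xa, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a CV fold lost one class; use fewer folds")
        path = enet_logistic_path(
            Xa[tr], y[tr], alpha=spec.alpha, lambdas=grid,
            penalty_factors=v, standardize=spec.standardize,
        )
        eta = path["intercepts"][:, None] + path["coefs"] @ Xa[va].T
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        dev[f] = [_binomial_deviance(y[va], pk) for pk in p]
    mean_dev = dev.mean(axis=0)
    return float(grid[np.argmin(mean_dev)]), grid, mean_dev


def stability_selection(
    X: pd.DataFrame,
    y,
    spec: PenalizedLogisticSpec,
    repeats: int = 200,
    threshold: float = 0.90,
    seed: int = 0,
    subsample_fraction: float | None = 2 / 3,
):
    """Repeat CV-tuned elastic-net fits and retain consistently selected
    genes.

    Each repeat draws a class-stratified subsample of the rows (a
    ``subsample_fraction`` share without replacement; ``None`` uses all
    rows), re-randomizes the CV folds on it, picks lambda at minimum mean
    deviance, refits at that lambda, and records which penalized features
    have nonzero coefficients.  Features selected in at least ``threshold``
    of repeats (>= 180/200 at defaults) are retained.  The row resampling
    is what makes the frequencies informative: with fixed rows, the same
    chance-correlated features would enter every repeat.  Unpenalized
    (v_j = 0) features are excluded from the frequency table.

    Returns (selected feature names, frequency Series).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    Xa = X.to_numpy(float)
    names = list(X.columns)
    y = np.asarray(y, float)
    v = (np.ones(Xa.shape[1]) if spec.penalty_factors is None
         else np.asarray(spec.penalty_factors, float))
    rng = np.random.default_rng(seed)
    hits = np.zeros(Xa.shape[1])
    pos = np.where(y == y.max())[0]
    neg = np.where(y != y.max())[0]
    for _ in range(repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if subsample_fraction is not None:
            pi = rng.choice(pos, size=int(round(len(pos) * subsample_fraction)),
                            replace=False)
            ni = rng.choice(neg, size=int(round(len(neg) * subsample_fraction)),
                            replace=False)
            idx = np.sort(np.concatenate([pi, ni]))
        else:
            idx = np.arange(len(y))
        Xs, ys = X.iloc[idx], y[idx]
        lam, grid, _ = cv_select_lambda(Xs, ys, spec, seed=rep_seed)
        path = enet_logistic_path(
            Xs.to_numpy(float), ys, alpha=spec.alpha, lambdas=grid[grid >= lam],
            penalty_factors=v, standardize=spec.standardize,
        )
        hits += path["coefs"][-1] != 0
    freq = pd.Series(hits / repeats, index=names, name="selection_frequency")
    penalized = v > 0
    selected = [nm for nm, f, pen in zip(names, freq, penalized)
                if pen and f >= threshold]
    return selected, freq


def fit_integrated_model(
    train_levels: pd.DataFrame,
    selected_genes: list[str],
    clinical: pd.DataFrame,
    seed: int | None = None,
    test_ids: list[str] | None = None,
) -> SignatureModel:
    """Unpenalized logistic refit of subtype on the signature.

    ``train_levels`` is samples x genes normalized 5hmC levels for the
    training samples; age (years, standardized internally) and gender
    (M = 1) are appended.  Under perfect separation the fit falls back to a
    small ridge penalty (lambda = 1e-6) with a warning.  Coefficients are
    reported on the original feature scale.
    """
    if not selected_genes:
        raise ValueError("selected gene list is empty")
    clin = clinical.set_index("sample_id").loc[train_levels.index]
    X = train_levels[selected_genes].copy()
    X["age"] = clin["age"].to_numpy(float)
    X["gender_M"] = (clin["gender"] == "M").to_numpy(float)
    y = (clin["subtype"] == "FL").to_numpy(float)
    Xa = X.to_numpy(float)
    path = enet_logistic_path(Xa, y, alpha=0.0, lambdas=np.array([1e-10]),
                              standardize=True)
    coef = path["coefs"][-1]
    b0 = path["intercepts"][-1]
    if np.abs(coef).max() > 1e3 or not np.isfinite(coef).all():
        warnings.warn("perfect separation; refitting with ridge lambda=1e-6",
                      stacklevel=2)
        path = enet_logistic_path(Xa, y, alpha=0.0, lambdas=np.array([1e-6]),
                                  standardize=True)
        coef = path["coefs"][-1]
        b0 = path["intercepts"][-1]
    degenerate = bool(np.allclose(coef, 0.0))
    if degenerate:
        warnings.warn("all coefficients zero; scores are constant and AUC "
                      "is undefined", stacklevel=2)
    return SignatureModel(
        features=list(X.columns),
        intercept=float(b0),
        coefficients=coef,
        feature_means=Xa.mean(axis=0),
        feature_sds=Xa.std(axis=0),
        seed=seed,
        train_ids=list(train_levels.index),
        test_ids=list(test_ids or []),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _auc_mann_whitney(scores, labels):
    """AUC via the Mann-Whitney identity with midrank tie correction."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def _delong_ci(scores, labels, level=0.95):
    """DeLong variance of the AUC via placement values."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    auc = _auc_mann_whitney(scores, labels)
    # placement of each positive among negatives, and vice versa
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = np.sqrt(max(var, 0.0))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return auc, max(0.0, auc - zq * se), min(1.0, auc + zq * se)


def roc_auc(scores, labels, ci_method: str = "delong", n_boot: int = 2000,
            seed: int = 0, level: float = 0.95) -> ROCResult:
    """AUC with a confidence interval.

    AUC is the Mann-Whitney statistic (probability a random positive scores
    above a random negative, ties counted half), invariant under strictly
    monotone transforms of the scores.  The CI is DeLong (default) or a
    stratified bootstrap percentile interval.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain both classes")
    labels = (labels == np.max(labels)).astype(int)
    if ci_method == "delong":
        auc, lo, hi = _delong_ci(scores, labels, level)
    elif ci_method == "bootstrap":
        scores = np.asarray(scores, float)
        rng = np.random.default_rng(seed)
        pos_idx = np.where(labels == 1)[0]
        neg_idx = np.where(labels == 0)[0]
        auc = _auc_mann_whitney(scores, labels)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
            ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
            idx = np.concatenate([pi, ni])
            reps[b] = _auc_mann_whitney(scores[idx], labels[idx])
        alpha = (1 - level) / 2
        lo, hi = np.quantile(reps, [alpha, 1 - alpha])
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCResult(auc=float(auc), ci_low=float(lo), ci_high=float(hi),
                     method=ci_method)
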