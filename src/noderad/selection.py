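"""Feature normalization and the three-step selection chain.

All statistics here are computed on the primary cohort only; the
validation cohort is transformed with frozen parameters and never
influences which features survive.

Step 1 screens each feature with a two-sided Wilcoxon rank-sum test
between the LNM+ and LNM- groups, keeping p <= 0.1.  Step 2 prunes
redundant survivors: whenever two features have |Spearman rho| > 0.9 the
one with the larger screening p-value is dropped (pairs processed in
descending |rho|, ties broken lexicographically, so the survivor set is
deterministic).  Step 3 fits an L1-penalized logistic path and keeps the
features with nonzero coefficients at the one-standard-error lambda of
a 10-fold stratified cross-validation of binomial deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold


@dataclass
class NormalizationParams:
    """Per-feature min/max learned on the primary cohort (unit-range scaling)."""

    min_: pd.Series
    max_: pd.Series

    def __post_init__(self):
        if (self.max_ < self.min_).any():
            raise ValueError("max must be >= min for every feature")


@dataclass
class SelectionResult:
    stage1_kept: List[str]
    stage1_pvalues: Dict[str, float]
    stage2_kept: List[str]
    stage3_kept: List[str]
    lambda_grid: np.ndarray
    cv_mean_deviance: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "stage1_kept": self.stage1_kept,
            "stage1_pvalues": self.stage1_pvalues,
            "stage2_kept": self.stage2_kept,
            "stage3_kept": self.stage3_kept,
            "lambda_grid": list(map(float, self.lambda_grid)),
            "cv_mean_deviance": list(map(float, self.cv_mean_deviance)),
            "cv_se": list(map(float, self.cv_se)),
            "lambda_min": float(self.lambda_min),
            "lambda_1se": float(self.lambda_1se),
            "seed": int(self.seed),
        }


def fit_normalizer(primary_table: pd.DataFrame) -> NormalizationParams:
    """Learn per-feature min and max from the primary cohort."""
    if len(primary_table) < 2:
        raise ValueError("need >= 2 patients to fit the normalizer")
    return NormalizationParams(min_=primary_table.min(axis=0), max_=primary_table.max(axis=0))


def apply_normalizer(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Map each feature through (x - min) / (max - min).

    Values outside the primary-cohort range map outside [0, 1] (no
    clipping).  A feature constant in the primary cohort maps to 0
    everywhere, with a warning.
    """
    unknown = set(table.columns) - set(params.min_.index)
    if unknown:
        raise KeyError(f"unknown feature name(s): {sorted(unknown)[:5]}")
    mn = params.min_[table.columns]
    mx = params.max_[table.columns]
    span = mx - mn
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) constant in primary cohort; normalized to 0",
            UserWarning,
        )
    safe = span.copy()
    safe[degenerate] = 1.0
    out = (table - mn) / safe
    out.loc[:, degenerate[degenerate].index] = 0.0
    return out


def wilcoxon_screen(
    table: pd.DataFrame, labels: Sequence[int], alpha: float = 0.1
) -> Tuple[List[str], Dict[str, float]]:
    """Two-sided Wilcoxon rank-sum test per feature; keep p <= alpha.

    Uses exact enumeration when both groups have <= 25 members and the
    feature has no cross-group ties, otherwise the midrank normal
    approximation with tie correction.
    """
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs >= 2 members")
    xs = table.to_numpy(dtype=float)
    g1, g0 = xs[y == 1], xs[y == 0]
    small = min(len(g1), len(g0)) <= 25 and max(len(g1), len(g0)) <= 25
    pvals: Dict[str, float] = {}
    if small:
        for j, name in enumerate(table.columns):
            a, b = g1[:, j], g0[:, j]
            has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
            method = "exact" if not has_ties else "asymptotic"
            p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
            pvals[name] = float(p)
    else:
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method="asymptotic", axis=0)
        pvals = {name: float(p) for name, p in zip(table.columns, np.atleast_1d(res.pvalue))}
    kept = [n for n in table.columns if pvals[n] <= alpha]
    return kept, pvals


def spearman_prune(
    table: pd.DataFrame, pvalues: Dict[str, float], r_threshold: float = 0.9
) -> List[str]:
    """Drop the larger-p member of every feature pair with |rho| > threshold.

    Pairs are processed in descending |rho| (ties broken by the sorted
    name pair); a pair is skipped if one member was already dropped.
    Within a pair, a p-value tie drops the lexicographically later name.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    ranks = np.apply_along_axis(stats.rankdata, 0, table.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.nan_to_num(rho, nan=0.0)
    iu, ju = np.triu_indices(len(cols), k=1)
    strong = np.abs(rho[iu, ju]) > r_threshold
    pairs = sorted(
        zip(np.abs(rho[iu, ju])[strong], iu[strong], ju[strong]),
        key=lambda t: (-t[0], cols[t[1]], cols[t[2]]),
    )
    dropped: set = set()
    for _, a, b in pairs:
        na, nb = cols[a], cols[b]
        if na in dropped or nb in dropped:
            continue
        pa, pb = pvalues[na], pvalues[nb]
        if pa > pb or (pa == pb and na > nb):
            dropped.add(na)
        else:
            dropped.add(nb)
    return [c for c in cols if c not in dropped]


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-4) -> LogisticRegression:
    # liblinear minimizes C * sum(loglik losses) + |w|_1; glmnet-scale lambda = 1/(n*C)
    # CV path fits use a loose tolerance (deviance estimates only); the final
    # fit at the chosen lambda is run tighter.
    clf = LogisticRegression(
        penalty="l1",
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        tol=tol,
        max_iter=500,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def lasso_select(
    table: pd.DataFrame,
    labels: Sequence[int],
    n_folds: int = 10,
    rule: str = "1se",
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
) -> Tuple[List[str], dict]:
    """L1-penalized logistic path with cross-validated lambda selection.

    ``lambda_1se`` is the largest lambda whose mean CV binomial deviance
    lies within one standard error of the minimum.  Fold assignment is
    stratified by label and fixed by ``seed``.  Returns the selected
    names and the path metadata.
    """
    if table.shape[1] == 0:
        raise ValueError("empty candidate set")
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    # glmnet-style grid from the smallest lambda that zeroes every coefficient
    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max() / n
    lam_max = max(lam_max, 1e-6)
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    # walk the path from the strongest penalty down, stopping once the CV
    # deviance has clearly passed its minimum (the 1-SE lambda can only lie
    # at or above lambda_min, so the far tail of the path is never needed)
    dev_rows = []
    worse_streak = 0
    for g, lam in enumerate(grid):
        row = np.empty(n_folds)
        for f, (tr, te) in enumerate(folds):
            clf = _l1_fit(X[tr], y[tr], lam)
            row[f] = _binomial_deviance(y[te], clf.predict_proba(X[te])[:, 1])
        dev_rows.append(row)
        means = np.array([r.mean() for r in dev_rows])
        g_best = int(np.argmin(means))
        se_best = dev_rows[g_best].std(ddof=1) / np.sqrt(n_folds)
        if means[g] > means[g_best] + 3 * se_best:
            worse_streak += 1
            if worse_streak >= 5:
                break
        else:
            worse_streak = 0
    dev = np.vstack(dev_rows)
    grid = grid[: dev.shape[0]]
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    g_min = int(np.argmin(cv_mean))
    lam_min = float(grid[g_min])
    threshold = cv_mean[g_min] + cv_se[g_min]
    ok = np.flatnonzero(cv_mean <= threshold)
    g_1se = int(ok[0])  # grid is descending in lambda
    lam_1se = float(grid[g_1se])
    lam_use = lam_1se if rule == "1se" else lam_min
    final = _l1_fit(X, y, lam_use, tol=1e-7)
    nz = np.flatnonzero(np.abs(final.coef_.ravel()) > 1e-10)
    selected = [table.columns[k] for k in nz]
    meta = {
        "lambda_grid": grid,
        "cv_mean_deviance": cv_mean,
        "cv_se": cv_se,
        "lambda_min": lam_min,
        "lambda_1se": lam_1se,
        "seed": seed,
    }
    return selected, meta


def select_features(
    primary_table: pd.DataFrame,
    labels: Sequence[int],
    alpha: float = 0.1,
    r_threshold: float = 0.9,
    n_folds: int = 10,
    rule: str = "1se",
    seed: int = 0,
) -> SelectionResult:
    """Run the full three-step chain on the (normalized) primary table."""
    stage1, pvals = wilcoxon_screen(primary_table, labels, alpha)
    if not stage1:
        raise ValueError("empty candidate set: no feature passed the rank-sum screen")
    stage2 = spearman_prune(primary_table[stage1], {k: pvals[k] for k in stage1}, r_threshold)
    stage3, meta = lasso_select(primary_table[stage2], labels, n_folds, rule, seed)
    return SelectionResult(
        stage1_kept=stage1,
        stage1_pvalues=pvals,
        stage2_kept=stage2,
        stage3_kept=stage3,
        lambda_grid=meta["lambda_grid"],
        cv_mean_deviance=meta["cv_mean_deviance"],
        cv_se=meta["cv_se"],
        lambda_min=meta["lambda_min"],
        lambda_1se=meta["lambda_1se"],
        seed=seed,
    )
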