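"""Model-evaluation statistics for binary node-status predictors.

Covers the full comparison suite: ROC/AUC with DeLong variance and the
correlated-AUC test, Youden cutoffs, confusion-matrix metrics with
Clopper-Pearson intervals, McNemar's test, the category-free net
reclassification improvement (NRI), the Hosmer-Lemeshow goodness-of-fit
test with calibration curves, decision-curve analysis, Cohen's kappa,
and per-ymrT-subgroup reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, predicted: Sequence[int], labels: Sequence[int]) -> "ConfusionMatrix2x2":
        p = np.asarray(predicted, dtype=int)
        y = np.asarray(labels, dtype=int)
        return cls(
            tp=int(((p == 1) & (y == 1)).sum()),
            fp=int(((p == 1) & (y == 0)).sum()),
            fn=int(((p == 0) & (y == 1)).sum()),
            tn=int(((p == 0) & (y == 0)).sum()),
        )


def _rate(num: int, den: int, level: float = 0.95):
    """(estimate, lo, hi) with Clopper-Pearson CI; None when undefined."""
    if den == 0:
        return None
    lo, hi = proportion_confint(num, den, alpha=1 - level, method="beta")
    return (num / den, float(lo), float(hi))


def confusion_metrics(cm: ConfusionMatrix2x2, level: float = 0.95) -> Dict[str, Optional[Tuple[float, float, float]]]:
    """Sensitivity, specificity, PPV, NPV, accuracy — each with an exact binomial CI."""
    return {
        "sensitivity": _rate(cm.tp, cm.tp + cm.fn, level),
        "specificity": _rate(cm.tn, cm.tn + cm.fp, level),
        "ppv": _rate(cm.tp, cm.tp + cm.fp, level),
        "npv": _rate(cm.tn, cm.tn + cm.fn, level),
        "accuracy": _rate(cm.tp + cm.tn, cm.total, level),
    }


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney pair statistic (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    r = stats.rankdata(s)
    n1 = int((y == 1).sum())
    n0 = y.size - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC and its structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r, neg_r = all_r[:m], all_r[m:]
    v10 = (pos_r - stats.rankdata(pos)) / n
    v01 = 1.0 - (neg_r - stats.rankdata(neg)) / m
    auc = v10.mean()
    return float(auc), v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> Tuple[float, float, float]:
    """AUC with a DeLong-variance normal confidence interval (clipped to [0, 1])."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    auc, v10, v01 = _delong_components(s, y)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(scores_a, scores_b, labels) -> Tuple[float, float]:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Returns ``(delta_auc, p)``; degenerate variance reports p = 1 with
    a warning.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired scores on identical patients required")
    _check_two_classes(y)
    auc_a, va10, va01 = _delong_components(sa, y)
    auc_b, vb10, vb01 = _delong_components(sb, y)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]))
    s01 = np.cov(np.vstack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0:
        warnings.warn("degenerate DeLong variance; p reported as 1", UserWarning)
        return float(delta), 1.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * stats.norm.sf(abs(z)))


def youden_cutoff(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 over score midpoints.

    Scores >= threshold are called positive.  Ties in Youden's J are
    broken toward higher specificity (the larger threshold).  If every
    score is identical, J = 0 everywhere; that value is returned with a
    warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    uniq = np.unique(s)
    if uniq.size == 1:
        warnings.warn("all scores identical; Youden J = 0 at every threshold", UserWarning)
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    best_j, best_t = -np.inf, cands[0]
    for t in cands:
        pred = s >= t
        j = ((pred & (y == 1)).sum() / n1) + ((~pred & (y == 0)).sum() / n0) - 1
        if j > best_j - 1e-12 and (j > best_j + 1e-12 or t > best_t):
            best_j, best_t = max(best_j, j), t
    return float(best_t)


# ---------------------------------------------------------------------------
# paired comparison tests


def mcnemar_test(correct_a: Sequence[int], correct_b: Sequence[int]) -> float:
    """McNemar's test on paired correctness indicators.

    Exact binomial when there are fewer than 25 discordant pairs,
    chi-square with continuity correction otherwise; no discordant
    pairs gives p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired vectors required")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    if n01 + n10 == 0:
        return 1.0
    table = [[int((a & b).sum()), n10], [n01, int((~a & ~b).sum())]]
    exact = (n01 + n10) < 25
    res = _sm_mcnemar(np.asarray(table), exact=exact, correction=True)
    return float(min(1.0, res.pvalue))


def nri(probs_old, probs_new, labels) -> Dict[str, float]:
    """Category-free (continuous) net reclassification improvement.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)]
    with the usual asymptotic z-test.
    """
    po = np.asarray(probs_old, dtype=float)
    pn = np.asarray(probs_new, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (po.shape == pn.shape == y.shape):
        raise ValueError("paired probabilities required")
    ev, ne = y == 1, y == 0
    if not ev.any() or not ne.any():
        raise ValueError("need events and nonevents")
    up, down = pn > po, pn < po
    p_up_e, p_dn_e = up[ev].mean(), down[ev].mean()
    p_up_n, p_dn_n = up[ne].mean(), down[ne].mean()
    nri_e = p_up_e - p_dn_e
    nri_n = p_dn_n - p_up_n
    total = nri_e + nri_n
    var = (p_up_e + p_dn_e - nri_e**2) / ev.sum() + (p_up_n + p_dn_n - nri_n**2) / ne.sum()
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = total / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {
        "nri": float(total),
        "nri_events": float(nri_e),
        "nri_nonevents": float(nri_n),
        "z": float(z),
        "p": p,
    }


# ---------------------------------------------------------------------------
# calibration


def hosmer_lemeshow(
    probs, labels, n_groups: int = 10, dof: Optional[int] = None
) -> Dict[str, object]:
    """Hosmer-Lemeshow decile-of-risk test plus calibration-curve points.

    chi2 = sum (O_g - E_g)^2 / (E_g (1 - E_g/n_g)); by default
    dof = groups - 2 (probabilities fitted on these data).  For
    externally specified probabilities the large-sample reference is
    chi2(groups); pass ``dof=n_groups`` in that case.  Groups are
    equal-size in predicted-probability order; a warning is emitted when
    ties leave fewer distinct probabilities than groups.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = p.size
    if n < 2 * n_groups:
        raise ValueError("need n >= 2 * n_groups")
    # deciles of risk: equal-size groups in predicted-probability order
    if np.unique(p).size < n_groups:
        warnings.warn("fewer distinct probabilities than risk groups", UserWarning)
    order = np.argsort(p, kind="stable")
    gidx = np.empty(n, dtype=int)
    gidx[order] = (np.arange(n) * n_groups) // n
    chi2 = 0.0
    curve = []
    n_used = 0
    for g in range(n_groups):
        sel = gidx == g
        ng = int(sel.sum())
        if ng == 0:
            continue
        n_used += 1
        obs = float(y[sel].sum())
        exp = float(p[sel].sum())
        pbar = exp / ng
        denom = exp * (1 - pbar)
        if denom > 0:
            chi2 += (obs - exp) ** 2 / denom
        curve.append({"mean_predicted": pbar, "observed_rate": obs / ng, "n": ng})
    if dof is None:
        dof = max(1, n_used - 2)
    return {
        "chi2": float(chi2),
        "dof": int(dof),
        "p": float(stats.chi2.sf(chi2, dof)),
        "calibration_curve": curve,
    }


def decision_curve(probs, labels, thresholds: Sequence[float]) -> pd.DataFrame:
    """Net benefit of acting on the model at each threshold probability.

    NB(pt) = TP/n - (FP/n) * pt/(1-pt); the treat-all and treat-none
    reference policies are included as columns.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    t = np.asarray(thresholds, dtype=float)
    if np.any(t >= 1) or np.any(t <= 0):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = p.size
    prev = y.mean()
    rows = []
    for pt in t:
        pred = p >= pt
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        w = pt / (1 - pt)
        rows.append(
            dict(
                threshold=pt,
                net_benefit=tp / n - (fp / n) * w,
                treat_all=prev - (1 - prev) * w,
                treat_none=0.0,
            )
        )
    return pd.DataFrame(rows)


def cohen_kappa(ratings1, ratings2) -> float:
    """Unweighted Cohen's kappa; chance agreement of 1 is undefined (NaN)."""
    r1 = np.asarray(ratings1)
    r2 = np.asarray(ratings2)
    if r1.shape != r2.shape:
        raise ValueError("rating vectors must have equal length")
    cats, c1 = np.unique(r1, return_counts=True)
    cats2, c2 = np.unique(r2, return_counts=True)
    # chance agreement
    all_cats = np.union1d(cats, cats2)
    p1 = np.array([np.mean(r1 == c) for c in all_cats])
    p2 = np.array([np.mean(r2 == c) for c in all_cats])
    pe = float(np.sum(p1 * p2))
    if pe >= 1.0:
        return float("nan")
    return float(cohen_kappa_score(r1, r2))


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvaluationReport:
    subgroup: str
    n: int
    prevalence: float
    auc: Optional[float]
    auc_ci: Optional[Tuple[float, float]]
    cutoff: Optional[float]
    metrics: Dict[str, Optional[Tuple[float, float, float]]]
    hosmer_lemeshow: Optional[Dict[str, object]] = None
    decision_curve: Optional[pd.DataFrame] = None
    notes: str = ""

    def to_dict(self) -> dict:
        d = {
            "subgroup": self.subgroup,
            "n": self.n,
            "prevalence": self.prevalence,
            "auc": self.auc,
            "auc_ci": self.auc_ci,
            "cutoff": self.cutoff,
            "metrics": self.metrics,
            "notes": self.notes,
        }
        if self.hosmer_lemeshow is not None:
            d["hosmer_lemeshow"] = {
                k: v for k, v in self.hosmer_lemeshow.items() if k != "calibration_curve"
            }
        return d


def evaluate_predictions(
    probs, labels, cutoff: Optional[float] = None, subgroup: str = "all", calibration: bool = True
) -> EvaluationReport:
    """Full metric set for one cohort (or subgroup) of predicted probabilities.

    If ``cutoff`` is None it is derived from these data by the Youden
    rule; pass a frozen primary-cohort cutoff to evaluate a validation
    cohort.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = p.size
    prev = float(y.mean()) if n else float("nan")
    if n == 0 or y.min() == y.max():
        return EvaluationReport(
            subgroup=subgroup,
            n=n,
            prevalence=prev,
            auc=None,
            auc_ci=None,
            cutoff=cutoff,
            metrics=_single_class_metrics(p, y, cutoff),
            notes="single-class subgroup: AUC and class-conditional metrics unavailable",
        )
    auc, lo, hi = delong_ci(p, y)
    if cutoff is None:
        cutoff = youden_cutoff(p, y)
    cm = ConfusionMatrix2x2.from_predictions((p >= cutoff).astype(int), y)
    hl = None
    if calibration and n >= 20:
        hl = hosmer_lemeshow(p, y)
    dc = decision_curve(p, y, np.linspace(0.05, 0.95, 19)) if calibration else None
    return EvaluationReport(
        subgroup=subgroup,
        n=n,
        prevalence=prev,
        auc=auc,
        auc_ci=(lo, hi),
        cutoff=float(cutoff),
        metrics=confusion_metrics(cm),
        hosmer_lemeshow=hl,
        decision_curve=dc,
    )


def _single_class_metrics(p, y, cutoff):
    if cutoff is None or p.size == 0:
        return {k: None for k in ("sensitivity", "specificity", "ppv", "npv", "accuracy")}
    cm = ConfusionMatrix2x2.from_predictions((p >= cutoff).astype(int), y)
    return confusion_metrics(cm)


def stratified_report(
    predictions: pd.DataFrame,
    prob_col: str = "probability",
    label_col: str = "label",
    ymrt_col: str = "ymrT",
    split_col: str = "split",
) -> Dict[str, Dict[str, EvaluationReport]]:
    """Per-subgroup (ymrT1-2 / ymrT3-4) evaluation in each cohort.

    The cutoff for each subgroup is derived in the primary-cohort
    subgroup and applied unchanged to the matching validation subgroup.
    """
    out: Dict[str, Dict[str, EvaluationReport]] = {}
    groups = {
        "ymrT1-2": predictions[ymrt_col] <= 2,
        "ymrT3-4": predictions[ymrt_col] >= 3,
    }
    for gname, gsel in groups.items():
        out[gname] = {}
        prim = predictions[gsel & (predictions[split_col] == "primary")]
        val = predictions[gsel & (predictions[split_col] == "validation")]
        cutoff = None
        if len(prim) >= 10 and prim[label_col].nunique() == 2:
            cutoff = youden_cutoff(prim[prob_col], prim[label_col])
        for cohort, df in (("primary", prim), ("validation", val)):
            out[gname][cohort] = evaluate_predictions(
                df[prob_col].to_numpy(),
                df[label_col].to_numpy(),
                cutoff=cutoff,
                subgroup=f"{gname}/{cohort}",
                calibration=False,
            )
    return out
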