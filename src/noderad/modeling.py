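"""Logistic models: radiomic signature, univariate screen, combined model, nomogram.

The radiomic signature is the linear predictor of a multivariate
logistic fit over the selected (normalized) features,

    signature(x) = sum_i C_i * x_i + b,
    P(LNM+ | x)  = 1 / (1 + exp(-signature(x))),

and the combined model is a second logistic fit over the signature and
the radiologist restaging covariates (ymrT, ymrN entered as numeric
ordinal scores).  All fits are maximum likelihood via statsmodels; a
perfectly separated fit raises with advice to use the documented small-
ridge fallback.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class LogisticModel:
    feature_names: List[str]
    coefficients: np.ndarray
    intercept: float
    fitted_on: str = "primary"
    # Wald inference per coefficient (None for penalized fallback fits)
    stderr: Optional[np.ndarray] = None
    pvalues: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_names) != self.coefficients.size:
            raise ValueError("one coefficient per feature required")
        if not np.all(np.isfinite(self.coefficients)) or not np.isfinite(self.intercept):
            raise ValueError("parameters must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "fitted_on": self.fitted_on,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.asarray(d["coefficients"]),
            intercept=float(d["intercept"]),
            fitted_on=d.get("fitted_on", "primary"),
        )


@dataclass
class UnivariateResult:
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coefficient: float

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must contain the OR point estimate")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist; refit with ridge=1e-6."""


def _mle_fit(X: pd.DataFrame, y: np.ndarray, ridge: float = 0.0) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (params, bse, pvalues) for [const, features]."""
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if ridge > 0:
        # small L2 penalty: penalized IRLS via sklearn-equivalent closed loop
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(penalty="l2", C=1.0 / (len(y) * ridge), solver="lbfgs", max_iter=2000)
        clf.fit(X.to_numpy(dtype=float), y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        return params, np.full_like(params, np.nan), np.full_like(params, np.nan)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, method="newton", tol=1e-10)
    except Exception as exc:  # singular Hessian / perfect separation
        raise SeparationError(
            "perfect separation: refit with a small ridge penalty (ridge=1e-6)"
        ) from exc
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params) > 1e3):
        raise SeparationError(
            "perfect separation: refit with a small ridge penalty (ridge=1e-6)"
        )
    return res.params, res.bse, res.pvalues


def fit_signature_model(
    selected_table: pd.DataFrame, labels: Sequence[int], ridge: float = 0.0
) -> LogisticModel:
    """Maximum-likelihood logistic fit over the selected normalized features."""
    y = np.asarray(labels, dtype=int)
    params, bse, pvals = _mle_fit(selected_table, y, ridge)
    return LogisticModel(
        feature_names=list(selected_table.columns),
        coefficients=params[1:],
        intercept=float(params[0]),
        stderr=bse[1:] if bse is not None else None,
        pvalues=pvals[1:] if pvals is not None else None,
    )


def compute_signature(model: LogisticModel, x) -> np.ndarray:
    """Linear predictor sum_i C_i x_i + b for one row or a table of rows."""
    if isinstance(x, pd.DataFrame):
        missing = set(model.feature_names) - set(x.columns)
        if missing:
            raise KeyError(f"missing feature(s): {sorted(missing)}")
        xv = x[model.feature_names].to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        if xv.shape[-1] != len(model.feature_names):
            raise ValueError("feature count mismatch")
    return xv @ model.coefficients + model.intercept


def predict_probability(model: LogisticModel, x) -> np.ndarray:
    """Logistic link of the signature: 1 / (1 + exp(-signature))."""
    from scipy.special import expit

    return expit(compute_signature(model, x))


def univariate_screen(
    table: pd.DataFrame, labels: Sequence[int], variables: Optional[Sequence[str]] = None
) -> List[UnivariateResult]:
    """One single-covariate logistic fit per candidate variable.

    Ordinal stage variables enter as numeric scores (per-unit odds
    ratio); constant variables are flagged and skipped.
    """
    y = np.asarray(labels, dtype=int)
    if variables is None:
        variables = list(table.columns)
    out: List[UnivariateResult] = []
    for v in variables:
        col = table[[v]].astype(float)
        if col[v].nunique() < 2:
            warnings.warn(f"variable {v} is constant; skipped", UserWarning)
            continue
        try:
            params, bse, pvals = _mle_fit(col, y)
            beta, se = params[1], bse[1]
            lo = float(np.exp(beta - 1.959963984540054 * se))
            hi = float(np.exp(beta + 1.959963984540054 * se))
            p = float(pvals[1])
        except SeparationError:
            # separated single covariate: ridge point estimate, likelihood-ratio p
            warnings.warn(f"variable {v} separates the classes; ridge fallback", UserWarning)
            params, _, _ = _mle_fit(col, y, ridge=1e-6)
            beta = params[1]
            from scipy.special import expit
            from scipy.stats import chi2 as _chi2

            eta = params[0] + col[v].to_numpy() * beta
            pr = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            ll1 = float(np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr)))
            pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            ll0 = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
            p = float(_chi2.sf(2 * (ll1 - ll0), 1))
            lo = hi = float(np.exp(beta))
        out.append(
            UnivariateResult(
                variable=v,
                odds_ratio=float(np.exp(beta)),
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                coefficient=float(beta),
            )
        )
    return out


def fit_combined_model(
    table: pd.DataFrame,
    labels: Sequence[int],
    variables: Sequence[str] = ("signature", "ymrT", "ymrN"),
    ridge: float = 0.0,
) -> Tuple[LogisticModel, pd.DataFrame]:
    """Joint logistic fit of the signature and the significant clinical stages.

    Returns the model and a per-term summary (coefficient, OR, Wald 95%
    CI, p).  Duplicated/collinear covariates raise; a perfectly
    separated fit raises unless a small ``ridge`` penalty is given
    (penalized fits carry no Wald inference).
    """
    X = table[list(variables)].astype(float)
    if np.linalg.matrix_rank(np.corrcoef(X.to_numpy(), rowvar=False)) < X.shape[1]:
        raise ValueError("aliased covariates: design matrix is rank deficient")
    y = np.asarray(labels, dtype=int)
    params, bse, pvals = _mle_fit(X, y, ridge)
    z = 1.959963984540054
    rows = []
    for name, b, se, p in zip(["intercept"] + list(variables), params, bse, pvals):
        rows.append(
            dict(
                term=name,
                coefficient=float(b),
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * se)),
                ci_high=float(np.exp(b + z * se)),
                p_value=float(p),
            )
        )
    model = LogisticModel(
        feature_names=list(variables),
        coefficients=params[1:],
        intercept=float(params[0]),
        stderr=bse[1:],
        pvalues=pvals[1:],
    )
    return model, pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# nomogram


@dataclass
class NomogramSpec:
    """Points-scale representation of a fitted logistic model.

    For each variable v with coefficient beta_v over range
    [lo_v, hi_v], the reference x_ref is the value minimizing
    beta_v * x (the low-risk end), and

        points_v(x) = 100 * beta_v * (x - x_ref) / M,

    with M = max_v |beta_v| * (hi_v - lo_v), so the widest-impact
    variable spans exactly 0..100 points and all points are
    nonnegative.  Total points map back to probability through the
    inverse linear predictor.
    """

    variables: List[str]
    coefficients: Dict[str, float]
    ranges: Dict[str, Tuple[float, float]]
    refs: Dict[str, float]
    scale: float  # M: linear-predictor units per 100 points
    intercept: float

    def points(self, variable: str, value) -> np.ndarray:
        beta = self.coefficients[variable]
        return 100.0 * beta * (np.asarray(value, dtype=float) - self.refs[variable]) / self.scale

    def total_points(self, row: Dict[str, float]) -> float:
        return float(sum(self.points(v, row[v]) for v in self.variables))

    def probability(self, total_points) -> np.ndarray:
        from scipy.special import expit

        eta0 = self.intercept + sum(self.coefficients[v] * self.refs[v] for v in self.variables)
        return expit(eta0 + np.asarray(total_points, dtype=float) * self.scale / 100.0)


def export_nomogram(model: LogisticModel, ranges: Dict[str, Tuple[float, float]]) -> NomogramSpec:
    """Convert a fitted logistic model into a nomogram points table.

    Variables whose range has zero width are excluded with a warning.
    """
    variables, coefs, rng, refs = [], {}, {}, {}
    impacts = []
    for v, beta in zip(model.feature_names, model.coefficients):
        lo, hi = ranges[v]
        if hi <= lo:
            warnings.warn(f"variable {v} has zero range; excluded from nomogram", UserWarning)
            continue
        variables.append(v)
        coefs[v] = float(beta)
        rng[v] = (float(lo), float(hi))
        refs[v] = float(lo) if beta >= 0 else float(hi)
        impacts.append(abs(beta) * (hi - lo))
    if not variables:
        raise ValueError("no variable with positive range")
    return NomogramSpec(
        variables=variables,
        coefficients=coefs,
        ranges=rng,
        refs=refs,
        scale=float(max(impacts)),
        intercept=float(model.intercept),
    )


def render_nomogram(spec: NomogramSpec, path) -> None:
    """Simple matplotlib rendering of the points scales."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 1.2 + len(spec.variables)))
    yrow = len(spec.variables) + 1
    ax.plot([0, 100], [yrow, yrow], "k-")
    for t in range(0, 101, 10):
        ax.plot([t, t], [yrow - 0.07, yrow + 0.07], "k-")
        ax.text(t, yrow + 0.15, str(t), ha="center", fontsize=8)
    ax.text(-5, yrow, "Points", ha="right", va="center")
    for r, v in enumerate(spec.variables):
        y = yrow - 1 - r
        lo, hi = spec.ranges[v]
        grid = np.linspace(lo, hi, 6)
        pts = spec.points(v, grid)
        ax.plot([pts.min(), pts.max()], [y, y], "k-")
        for g, p in zip(grid, pts):
            ax.plot([p, p], [y - 0.07, y + 0.07], "k-")
            ax.text(p, y - 0.25, f"{g:g}", ha="center", fontsize=7)
        ax.text(-5, y, v, ha="right", va="center")
    ax.set_xlim(-30, 110)
    ax.set_ylim(-0.8, yrow + 0.8)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
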