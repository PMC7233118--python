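"""End-to-end orchestration: simulate → extract → select → fit → evaluate.

A run is deterministic given its configuration and master seed.  The
primary/validation split is frozen in the cohort table at creation time;
every fitted parameter (normalization bounds, screening p-values,
lambda, model coefficients, Youden cutoffs) is learned on the primary
cohort only and applied unchanged to the validation cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import modeling as mdl
from .features import ExtractionConfig, extract_table
from .selection import (
    SelectionResult,
    apply_normalizer,
    fit_normalizer,
    select_features,
)
from .synthetic import SEQUENCES, CohortConfig, MRISample, cohort_table, generate_cohort

log = logging.getLogger("noderad")

CLINICAL_SCREEN_VARS = ("sex", "age", "cea", "radiation", "ymrT", "ymrN", "signature")


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    alpha: float = 0.1
    r_threshold: float = 0.9
    n_folds: int = 10
    rule: str = "1se"
    univariate_alpha: float = 0.05
    seed: int = 0
    output_dir: Optional[Path] = None

    def __post_init__(self):
        for name, v in (("alpha", self.alpha), ("r_threshold", self.r_threshold)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class PipelineResult:
    config: RunConfig
    selection: SelectionResult
    signature_model: mdl.LogisticModel
    combined_model: mdl.LogisticModel
    combined_summary: pd.DataFrame
    clinical_model: mdl.LogisticModel
    univariate: List[mdl.UnivariateResult]
    predictions: pd.DataFrame  # patient_id, split, label, ymrT, ymrN, signature, probability, ...
    reports: Dict[str, ev.EvaluationReport]
    subgroup_reports: Dict[str, Dict[str, ev.EvaluationReport]]
    comparisons: Dict[str, object]
    nomogram: mdl.NomogramSpec
    excluded: List[Tuple[str, str]] = field(default_factory=list)


def validate_inputs(samples: Sequence[MRISample]) -> Tuple[List[MRISample], List[Tuple[str, str]]]:
    """Apply the four exclusion-criteria analogues, report-only.

    A patient is excluded when a sequence is missing, a mask is
    empty/too small, a clinical field is absent, or the node label is
    missing.  Returns (retained, [(patient_id, reason), ...]).
    """
    keep, excluded = [], []
    for s in samples:
        reason = None
        missing = [q for q in SEQUENCES if q not in s.images or s.images[q] is None]
        if missing:
            reason = f"missing sequence {missing[0]}"
        elif any(
            q not in s.masks or s.masks[q] is None or int(np.asarray(s.masks[q]).sum()) < 16
            for q in SEQUENCES
        ):
            reason = "insufficient ROI"
        elif s.clinical is None:
            reason = "missing clinical record"
        elif s.label is None:
            reason = "missing node label"
        if reason is None:
            keep.append(s)
        else:
            excluded.append((s.patient_id, reason))
            log.info("excluded %s: %s", s.patient_id, reason)
    return keep, excluded


def run_pipeline(
    config: RunConfig,
    samples: Optional[Sequence[MRISample]] = None,
    split: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Execute the whole analysis; generates a synthetic cohort unless one is given."""
    if samples is None:
        samples, split = generate_cohort(config.cohort)
    assert split is not None
    split_map = {s.patient_id: sp for s, sp in zip(samples, split)}
    samples, excluded = validate_inputs(samples)
    clin = cohort_table(samples, [split_map[s.patient_id] for s in samples])
    clin = clin.set_index("patient_id")

    feats = extract_table(samples, config.extraction)
    is_primary = clin["split"] == "primary"
    primary_ids = clin.index[is_primary]
    valid_ids = clin.index[~is_primary]
    y_primary = clin.loc[primary_ids, "label"].to_numpy()

    norm = fit_normalizer(feats.loc[primary_ids])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        normed = apply_normalizer(feats, norm)

    selection = select_features(
        normed.loc[primary_ids],
        y_primary,
        alpha=config.alpha,
        r_threshold=config.r_threshold,
        n_folds=config.n_folds,
        rule=config.rule,
        seed=config.seed,
    )
    selected = selection.stage3_kept
    if selected:
        try:
            sig_model = mdl.fit_signature_model(normed.loc[primary_ids, selected], y_primary)
        except mdl.SeparationError:
            log.warning("signature fit perfectly separated; using ridge fallback")
            sig_model = mdl.fit_signature_model(
                normed.loc[primary_ids, selected], y_primary, ridge=1e-6
            )
    else:
        # no detectable radiomic signal: intercept-only signature (constant score)
        log.warning("LASSO selected no feature; signature degenerates to the intercept")
        prev = float(np.clip(y_primary.mean(), 1e-6, 1 - 1e-6))
        sig_model = mdl.LogisticModel(
            feature_names=[], coefficients=np.empty(0), intercept=float(np.log(prev / (1 - prev)))
        )
    signature = mdl.compute_signature(sig_model, normed[selected])

    table = clin.copy()
    table["signature"] = signature
    screen_df = pd.DataFrame(
        {
            "sex": (table["sex"] == "male").astype(int),
            "age": table["age"],
            "cea": table["cea"],
            "radiation": table["radiation"],
            "ymrT": table["ymrT"],
            "ymrN": table["ymrN"],
            "signature": table["signature"],
        },
        index=table.index,
    )
    univariate = mdl.univariate_screen(
        screen_df.loc[primary_ids], y_primary, variables=list(CLINICAL_SCREEN_VARS)
    )
    significant = [
        u.variable for u in univariate if u.p_value < config.univariate_alpha and u.variable != "signature"
    ]
    combined_vars = (["signature"] if selected else []) + significant
    if not combined_vars:
        combined_vars = ["ymrT", "ymrN"]
    def _fit(vars_):
        try:
            return mdl.fit_combined_model(screen_df.loc[primary_ids], y_primary, variables=vars_)
        except mdl.SeparationError:
            log.warning("fit over %s perfectly separated; using ridge fallback", vars_)
            return mdl.fit_combined_model(
                screen_df.loc[primary_ids], y_primary, variables=vars_, ridge=1e-6
            )

    combined_model, combined_summary = _fit(combined_vars)
    clinical_vars = significant if significant else ["ymrT", "ymrN"]
    clinical_model, _ = _fit(clinical_vars)

    preds = table[["split", "label", "ymrT", "ymrN", "signature"]].copy()
    preds["probability"] = mdl.predict_probability(combined_model, screen_df[combined_vars])
    preds["prob_signature"] = mdl.predict_probability(sig_model, normed[selected])
    preds["prob_clinical"] = mdl.predict_probability(clinical_model, screen_df[clinical_vars])
    preds = preds.reset_index().rename(columns={"index": "patient_id"})

    reports: Dict[str, ev.EvaluationReport] = {}
    prim = preds[preds["split"] == "primary"]
    val = preds[preds["split"] == "validation"]
    cutoffs: Dict[str, float] = {}
    for model_name, col in (
        ("signature", "prob_signature"),
        ("clinical", "prob_clinical"),
        ("combined", "probability"),
    ):
        cut = ev.youden_cutoff(prim[col], prim["label"])
        cutoffs[model_name] = cut
        reports[f"{model_name}/primary"] = ev.evaluate_predictions(
            prim[col].to_numpy(), prim["label"].to_numpy(), cutoff=cut, subgroup=f"{model_name}/primary"
        )
        reports[f"{model_name}/validation"] = ev.evaluate_predictions(
            val[col].to_numpy(), val["label"].to_numpy(), cutoff=cut, subgroup=f"{model_name}/validation"
        )

    # model comparisons in the validation cohort
    yv = val["label"].to_numpy()
    comparisons: Dict[str, object] = {}
    if len(val) and val["label"].nunique() == 2:
        d_cs, p_cs = ev.delong_test(val["probability"], val["prob_clinical"], yv)
        comparisons["delong_combined_vs_clinical"] = {"delta_auc": d_cs, "p": p_cs}
        d_ss, p_ss = ev.delong_test(val["probability"], val["prob_signature"], yv)
        comparisons["delong_combined_vs_signature"] = {"delta_auc": d_ss, "p": p_ss}
        radiologist = (val["ymrN"] >= 1).astype(int).to_numpy()
        sig_call = (val["prob_signature"] >= cutoffs["signature"]).astype(int).to_numpy()
        comparisons["mcnemar_signature_vs_radiologist"] = ev.mcnemar_test(
            sig_call == yv, radiologist == yv
        )
        comparisons["nri_combined_vs_clinical"] = ev.nri(
            val["prob_clinical"].to_numpy(), val["probability"].to_numpy(), yv
        )
    else:
        comparisons["note"] = "validation cohort empty or single-class; comparisons skipped"

    subgroups = ev.stratified_report(preds)

    ranges = {
        v: (float(screen_df.loc[primary_ids, v].min()), float(screen_df.loc[primary_ids, v].max()))
        for v in combined_vars
    }
    nomogram = mdl.export_nomogram(combined_model, ranges)

    result = PipelineResult(
        config=config,
        selection=selection,
        signature_model=sig_model,
        combined_model=combined_model,
        combined_summary=combined_summary,
        clinical_model=clinical_model,
        univariate=univariate,
        predictions=preds,
        reports=reports,
        subgroup_reports=subgroups,
        comparisons=comparisons,
        nomogram=nomogram,
        excluded=excluded,
    )
    if config.output_dir is not None:
        write_run(result, Path(config.output_dir))
    return result


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def write_run(result: PipelineResult, out: Path) -> Path:
    """Deterministic run directory: tables and models as CSV/JSON plus a manifest."""
    out.mkdir(parents=True, exist_ok=True)
    result.predictions.to_csv(out / "predictions.csv", index=False)
    (out / "selection.json").write_text(json.dumps(result.selection.to_dict(), indent=2))
    (out / "signature_model.json").write_text(result.signature_model.to_json())
    (out / "combined_model.json").write_text(result.combined_model.to_json())
    result.combined_summary.to_csv(out / "combined_summary.csv")
    uni = pd.DataFrame([vars(u) for u in result.univariate])
    uni.to_csv(out / "univariate.csv", index=False)
    reports = {k: r.to_dict() for k, r in result.reports.items()}
    for g, d in result.subgroup_reports.items():
        for cohort, r in d.items():
            reports[f"subgroup:{g}/{cohort}"] = r.to_dict()
    (out / "reports.json").write_text(json.dumps(reports, indent=2, default=_json_default))
    (out / "comparisons.json").write_text(
        json.dumps(result.comparisons, indent=2, default=_json_default)
    )
    nomo = {
        "variables": result.nomogram.variables,
        "coefficients": result.nomogram.coefficients,
        "ranges": result.nomogram.ranges,
        "refs": result.nomogram.refs,
        "scale": result.nomogram.scale,
        "intercept": result.nomogram.intercept,
    }
    (out / "nomogram.json").write_text(json.dumps(nomo, indent=2))
    dc = result.reports["combined/validation"].decision_curve
    if dc is not None:
        dc.to_csv(out / "decision_curve_validation.csv", index=False)
    manifest = {
        "seed": result.config.seed,
        "cohort_seed": result.config.cohort.seed,
        "n_patients": result.config.cohort.n_patients,
        "alpha": result.config.alpha,
        "r_threshold": result.config.r_threshold,
        "n_folds": result.config.n_folds,
        "rule": result.config.rule,
        "n_selected_features": len(result.selection.stage3_kept),
        "excluded": result.excluded,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "cohort": {
                        k: (v if not isinstance(v, dict) else dict(sorted(v.items())))
                        for k, v in asdict(result.config.cohort).items()
                    },
                    "alpha": result.config.alpha,
                    "r": result.config.r_threshold,
                    "seed": result.config.seed,
                },
                sort_keys=True,
                default=_json_default,
            ).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    try:
        mdl.render_nomogram(result.nomogram, out / "nomogram.png")
    except Exception:  # rendering is best-effort; tables are the contract
        log.warning("nomogram rendering failed", exc_info=True)
    return out
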