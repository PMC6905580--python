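"""Validation-set construction, LOOCV prediction, cutoff classification and
the predictive-performance report, plus prediction-surface export.

The validation set comprises the thermal-survey-derived records of high
confidence (weight >= 0.90) — the records most likely to reflect the true
state on the ground.  Predicted probabilities are classified as presence
when p >= 0.4: a deliberately permissive cutoff, because in a conservation
setting missing a presence costs more than a false alarm.  Performance is
summarized by classification accuracy, sensitivity (true positive rate),
specificity (true negative rate) and the root mean-square prediction error
computed on the raw probabilities.

Model recipes follow the study design: the ground-only (G) and fused G_E
models never see the validation records, so they are fit once and predict
directly; the GT and GT_E recipes train on all records, so each validation
site is predicted by leave-one-out refitting of the survey parent (the
expert model's data contain no validation observations and is fit once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    ReferenceScaling,
    compute_reference_scaling,
    standardize,
    validate_elicitations,
    validate_observations,
    validate_site_covariates,
)
from .expert_model import fit_weighted_beta
from .fusion import CombinedModel, combine_estimates, predict_combined
from .survey_model import (
    FittedModel,
    SeparationError,
    fit_weighted_logistic,
    predict_probability,
)

__all__ = [
    "EvaluationReport",
    "StudyResult",
    "build_validation_set",
    "classify",
    "confusion_metrics",
    "rmspe",
    "evaluate_predictions",
    "loocv_predictions",
    "run_study",
]

MODEL_IDS = ("G", "GT", "G_E", "GT_E")


@dataclass
class EvaluationReport:
    """Confusion counts and summary metrics of one model at a stated cutoff.

    ``sensitivity``/``specificity`` are ``None`` when the validation set has
    no positives/negatives respectively.
    """

    model_id: str
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    rmspe: float
    n_validation: int

    def as_row(self) -> dict:
        return {
            "model": self.model_id,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "rmspe": self.rmspe,
        }


def build_validation_set(obs: pd.DataFrame) -> pd.DataFrame:
    """Thermal-survey-derived records with confidence weight >= 0.90."""
    sel = (obs["source"] == "thermal") & (obs["weight"] >= 0.90)
    out = obs[sel].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("validation set is empty", stacklevel=2)
    return out


def classify(p: np.ndarray | float, cutoff: float = 0.4) -> np.ndarray | int:
    """1 (presence) iff p >= cutoff, else 0; ties classify as presence."""
    if np.isscalar(p):
        return int(p >= cutoff)
    return (np.asarray(p) >= cutoff).astype(int)


def confusion_metrics(obs: np.ndarray, pred: np.ndarray) -> dict:
    """Confusion counts plus accuracy/sensitivity/specificity.

    Rates with an empty denominator are reported as ``None`` with a warning.
    """
    obs = np.asarray(obs, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if len(obs) != len(pred) or len(obs) == 0:
        raise ValueError("obs and pred must have equal, non-zero length")
    tp = int(np.sum((obs == 1) & (pred == 1)))
    fp = int(np.sum((obs == 0) & (pred == 1)))
    tn = int(np.sum((obs == 0) & (pred == 0)))
    fn = int(np.sum((obs == 1) & (pred == 0)))
    sens = spec = None
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        warnings.warn("no positives: sensitivity undefined", stacklevel=2)
    if tn + fp > 0:
        spec = tn / (tn + fp)
    else:
        warnings.warn("no negatives: specificity undefined", stacklevel=2)
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": (tp + tn) / len(obs),
        "sensitivity": sens,
        "specificity": spec,
    }


def rmspe(obs: np.ndarray, p: np.ndarray) -> float:
    """Root mean-square prediction error on the raw probabilities:
    sqrt(mean((obs - p)^2))."""
    obs = np.asarray(obs, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(obs) != len(p):
        raise ValueError("obs and p must have equal length")
    if len(obs) == 0:
        raise ValueError("cannot compute RMSPE on empty input")
    return float(np.sqrt(np.mean((obs - p) ** 2)))


def evaluate_predictions(
    model_id: str, y: np.ndarray, p: np.ndarray, cutoff: float = 0.4
) -> EvaluationReport:
    """Assemble the full report for one model's validation predictions."""
    cm = confusion_metrics(y, classify(p, cutoff))
    return EvaluationReport(
        model_id=model_id,
        cutoff=cutoff,
        rmspe=rmspe(y, p),
        n_validation=len(np.asarray(y)),
        **cm,
    )


def _standardized(cov: pd.DataFrame, site_ids, scaling: ReferenceScaling) -> pd.DataFrame:
    sub = cov.set_index("site_id").loc[list(site_ids)]
    return standardize(sub.reset_index(), scaling)


def loocv_predictions(
    recipe: str,
    obs: pd.DataFrame,
    cov: pd.DataFrame,
    scaling: ReferenceScaling,
    validation_ids,
    expert: FittedModel | None = None,
    alpha: float = 0.05,
) -> pd.Series:
    """Validation-site probabilities under one model recipe.

    ``"G"``/``"G_E"``: fit once on the ground-source records and predict
    directly (optionally fused with ``expert``).  ``"GT"``/``"GT_E"``: for
    each validation site, drop its record, refit the survey model on the
    rest (re-fusing with the fixed ``expert`` model for GT_E) and predict at
    the dropped site.  Folds whose refit fails are reported as NaN with a
    warning.  Output is indexed by site_id and invariant to the order of
    ``validation_ids``.
    """
    validation_ids = list(validation_ids)
    if recipe not in MODEL_IDS:
        raise ValueError(f"unknown recipe {recipe!r}; expected one of {MODEL_IDS}")
    if recipe.endswith("_E") and expert is None:
        raise ValueError(f"recipe {recipe} needs a fitted expert model")
    if len(validation_ids) == 0:
        return pd.Series(dtype=float, name="p")

    z_val = _standardized(cov, validation_ids, scaling)

    if recipe in ("G", "G_E"):
        sub = obs[obs["source"] == "ground"]
        m = fit_weighted_logistic(
            _standardized(cov, sub["site_id"], scaling), sub["y"], sub["weight"]
        )
        if recipe == "G":
            p = predict_probability(m, z_val)
        else:
            p = predict_combined(combine_estimates(m, expert, alpha=alpha), z_val)
        return pd.Series(p, index=pd.Index(validation_ids, name="site_id"), name="p")

    preds = {}
    for sid, (_, zrow) in zip(validation_ids, z_val.iterrows()):
        train = obs[obs["site_id"] != sid]
        zrow = zrow.to_frame().T
        try:
            m = fit_weighted_logistic(
                _standardized(cov, train["site_id"], scaling),
                train["y"],
                train["weight"],
            )
            if recipe == "GT":
                preds[sid] = float(predict_probability(m, zrow)[0])
            else:
                cm = combine_estimates(m, expert, alpha=alpha)
                preds[sid] = float(predict_combined(cm, zrow)[0])
        except SeparationError as exc:
            warnings.warn(f"LOOCV fold for site {sid} failed: {exc}", stacklevel=2)
            preds[sid] = np.nan
    out = pd.Series(preds, name="p")
    out.index.name = "site_id"
    return out


@dataclass
class StudyResult:
    """Everything the full pipeline produces: the three fitted parents, the
    two fused models, one evaluation report per recipe, and the prediction
    surfaces on the grid."""

    models: dict[str, FittedModel]
    combined: dict[str, CombinedModel]
    reports: dict[str, EvaluationReport]
    predictions: pd.DataFrame | None
    validation: pd.DataFrame
    scaling: ReferenceScaling

    def report_table(self) -> pd.DataFrame:
        return pd.DataFrame([self.reports[m].as_row() for m in MODEL_IDS])


def run_study(
    obs: pd.DataFrame,
    cov: pd.DataFrame,
    elic: pd.DataFrame,
    grid: pd.DataFrame | None = None,
    cutoff: float = 0.4,
    alpha: float = 0.05,
    df_method: str = "edf",
) -> StudyResult:
    """Run the full multi-source pipeline on validated input tables.

    Fits the ground-only (G) and ground+thermal (GT) weighted logistic
    models and the expert (E) weighted Beta mixed model, all on covariates
    standardized by the base G data; fuses G_E and GT_E by inverse-variance
    pooling; evaluates all four recipes on the high-confidence thermal
    validation set at the given cutoff; and predicts all four over the
    optional grid.
    """
    obs = validate_observations(obs)
    cov = validate_site_covariates(cov)
    elic = validate_elicitations(elic)

    ground = obs[obs["source"] == "ground"]
    base_cov = cov.set_index("site_id").loc[ground["site_id"]].reset_index()
    scaling = compute_reference_scaling(base_cov)

    m_g = fit_weighted_logistic(
        _standardized(cov, ground["site_id"], scaling), ground["y"], ground["weight"]
    )
    m_gt = fit_weighted_logistic(
        _standardized(cov, obs["site_id"], scaling), obs["y"], obs["weight"]
    )
    m_e = fit_weighted_beta(
        _standardized(cov, elic["site_id"], scaling),
        elic["p_suitability"],
        elic["weight"],
        elic["expert_id"],
        df_method=df_method,
    )

    g_e = combine_estimates(m_g, m_e, alpha=alpha, provenance=("G", "E"))
    gt_e = combine_estimates(m_gt, m_e, alpha=alpha, provenance=("GT", "E"))

    validation = build_validation_set(obs)
    val_ids = list(validation["site_id"])
    y_val = validation["y"].to_numpy()
    reports = {}
    for recipe in MODEL_IDS:
        p = loocv_predictions(
            recipe, obs, cov, scaling, val_ids,
            expert=m_e if recipe.endswith("_E") else None, alpha=alpha,
        )
        reports[recipe] = evaluate_predictions(recipe, y_val, p.loc[val_ids].to_numpy(), cutoff)

    predictions = None
    if grid is not None:
        grid = validate_site_covariates(grid)
        z_grid = standardize(grid, scaling)
        predictions = grid[["site_id", "longitude", "latitude"]].copy()
        predictions["p_G"] = predict_probability(m_g, z_grid)
        predictions["p_GT"] = predict_probability(m_gt, z_grid)
        predictions["p_G_E"] = predict_combined(g_e, z_grid)
        predictions["p_GT_E"] = predict_combined(gt_e, z_grid)

    return StudyResult(
        models={"G": m_g, "GT": m_gt, "E": m_e},
        combined={"G_E": g_e, "GT_E": gt_e},
        reports=reports,
        predictions=predictions,
        validation=validation,
        scaling=scaling,
    )
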