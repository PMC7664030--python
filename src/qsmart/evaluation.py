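"""Model scoring, classification evaluation, and explanation utilities.

Regression accuracy is reported as R^2 = 1 - RSS/TSS and RMSE. For
sensitive/non-sensitive classification, multiple log-IC50 thresholds
(-4, -3, -2, -1, 0 by default) each define a labelling (sensitive iff
actual < threshold); predicted log-IC50 is negated to score sensitivity,
an ROC/AUC is computed per threshold, and the AUCs are averaged to avoid
overestimating performance from a single favourable cut.

Explanation artifacts mirror the model's unit-perturbation reading: the
effect of a feature is the change in mean prediction when its value is
raised by one unit with everything else held fixed (exactly the
coefficient in the linear view), the statistical interaction of a drug
substructure with a residue perturbation is assessed by the nested-model
F-test along with the four cell means for interaction plots, and every
PPI term's expression-unit impact on predicted log-IC50 is tabulated with
a strong/weak sign class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .interactions import ftest_term
from .model import QsmartModelSpec

log = logging.getLogger("qsmart")

DEFAULT_THRESHOLDS = (-4.0, -3.0, -2.0, -1.0, 0.0)


@dataclass
class EvaluationReport:
    r2: float
    rmse: float
    auc_by_threshold: dict[float, float] = field(default_factory=dict)
    mean_auc: float = np.nan
    per_group: dict[str, dict] = field(default_factory=dict)
    comparison_p: float | None = None
    metadata: dict = field(default_factory=dict)


@dataclass
class EffectAttribution:
    feature: str
    baseline_mean: float
    perturbed_mean: float
    delta: float


def score(predictions: np.ndarray, actuals: np.ndarray) -> tuple[float, float]:
    """(R^2, RMSE) of predictions against actual log-IC50 values.

    R^2 = 1 - RSS/TSS; raises when the actuals have zero variance (R^2
    undefined).
    """
    pred = np.asarray(predictions, float)
    act = np.asarray(actuals, float)
    if pred.shape != act.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    if not (np.isfinite(pred).all() and np.isfinite(act).all()):
        raise ValueError("non-finite values in scoring input")
    tss = float(np.sum((act - act.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    rss = float(np.sum((act - pred) ** 2))
    return 1.0 - rss / tss, float(np.sqrt(np.mean((act - pred) ** 2)))


def multithreshold_roc(
    predicted: np.ndarray, actual: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> tuple[dict[float, float], float, list[float]]:
    """Average AUC over several sensitivity thresholds.

    Per threshold t the positive class is actual < t (sensitive: lower
    IC50 kills at lower dose) and the score is the negated prediction.
    Thresholds yielding a single class are skipped and reported. Returns
    (AUC per usable threshold, mean AUC, skipped thresholds).
    """
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    aucs: dict[float, float] = {}
    skipped: list[float] = []
    for t in thresholds:
        labels = (actual < t).astype(int)
        if labels.min() == labels.max():
            skipped.append(t)
            log.info("threshold %g yields a single class; skipped", t)
            continue
        aucs[float(t)] = float(roc_auc_score(labels, -predicted))
    mean_auc = float(np.mean(list(aucs.values()))) if aucs else np.nan
    return aucs, mean_auc, skipped


def roc_points(predicted: np.ndarray, actual: np.ndarray,
               threshold: float, grid: np.ndarray | None = None
               ) -> pd.DataFrame:
    """ROC curve (FPR, TPR) for one threshold, for plotting exports.

    With ``grid`` given, the TPR is linearly interpolated onto a common
    false-positive-rate grid so curves can be averaged across models.
    """
    from sklearn.metrics import roc_curve
    labels = (np.asarray(actual, float) < threshold).astype(int)
    fpr, tpr, _ = roc_curve(labels, -np.asarray(predicted, float))
    if grid is not None:
        tpr = np.interp(grid, fpr, tpr)
        fpr = grid
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def perturb_effect(model: QsmartModelSpec, feature: str,
                   dataset: pd.DataFrame, delta: float = 1.0,
                   view: str | None = None) -> EffectAttribution:
    """Unit-perturbation attribution of one feature.

    Raise the feature by ``delta`` for every row with all other features
    held constant; the effect is the change in mean prediction. On the
    linear view this equals coefficient * delta exactly.
    """
    if feature not in model.feature_names:
        raise ValueError(f"feature {feature!r} not in model")
    if view is None:
        view = "linear" if model.has_linear else "network"
    base = model.predict(dataset, view=view)
    bumped = dataset.copy()
    bumped[feature] = bumped[feature] + delta
    pert = model.predict(bumped, view=view)
    return EffectAttribution(
        feature=feature, baseline_mean=float(np.mean(base)),
        perturbed_mean=float(np.mean(pert)),
        delta=float(np.mean(pert) - np.mean(base)))


def interaction_analysis(
    responses: np.ndarray, fingerprint: np.ndarray, residue: np.ndarray,
) -> tuple[float, float, pd.DataFrame]:
    """Statistical interaction of a drug substructure with a residue feature.

    Runs the same nested-model F-test used for term screening and returns
    the group-mean response in the four cells (fingerprint bit in {0,1} x
    residue-feature sign) for interaction plots; non-parallel cell means
    indicate interaction. Degenerate (empty) cells are flagged with NaN.
    """
    y = np.asarray(responses, float)
    fp = np.asarray(fingerprint, float)
    res = np.asarray(residue, float)
    f, p = ftest_term(y, fp * res, fp, res)
    rows = []
    for bit in (0, 1):
        for sign, mask_r in (("<=0", res <= 0), (">0", res > 0)):
            mask = (fp == bit) & mask_r
            mean = float(y[mask].mean()) if mask.any() else np.nan
            if not mask.any():
                log.info("degenerate cell: bit=%d residue%s", bit, sign)
            rows.append({"fingerprint_bit": bit, "residue_sign": sign,
                         "n": int(mask.sum()), "mean_response": mean})
    return f, p, pd.DataFrame(rows)


def ppi_edge_impacts(model: QsmartModelSpec, dataset: pd.DataFrame,
                     ppi_terms: list[str] | None = None,
                     strong_cut: float = 0.05,
                     view: str | None = None) -> pd.DataFrame:
    """Per-PPI-term unit impact on predicted log-IC50 with sign classes.

    ``ppi_terms`` defaults to every model feature named
    ``EXP_<A>_X_EXP_<B>``. Class is positive / weak positive / weak
    negative / negative with |delta| >= ``strong_cut`` as the strong cut.
    """
    if ppi_terms is None:
        ppi_terms = [c for c in model.feature_names
                     if c.startswith("EXP_") and "_X_EXP_" in c]
    if not ppi_terms:
        raise ValueError("model contains no PPI terms")
    rows = []
    for term in ppi_terms:
        body = term[len("EXP_"):]
        gene_a, gene_b = body.split("_X_EXP_")
        eff = perturb_effect(model, term, dataset, view=view)
        d = eff.delta
        sign = "positive" if d > 0 else "negative"
        strength = "" if abs(d) >= strong_cut else "weak "
        rows.append({"gene_a": gene_a, "gene_b": gene_b,
                     "delta": d, "sign_class": f"{strength}{sign}"})
    return pd.DataFrame(rows)


def compare_models(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-group scores."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or len(a) < 6:
        raise ValueError("need >= 6 paired group scores")
    diff = a - b
    if np.all(diff == 0):
        log.info("identical score vectors; p = 1 by convention")
        return 1.0
    return float(stats.wilcoxon(a, b, zero_method="wilcox",
                                alternative="two-sided").pvalue)


def evaluate(predictions: np.ndarray, actuals: np.ndarray,
             thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
             groups: np.ndarray | None = None,
             metadata: dict | None = None) -> EvaluationReport:
    """Full report: R^2, RMSE, multi-threshold AUC, optional group breakdown.

    With group labels both poolings are reported per group: R^2 on the
    group's own residuals and its contribution to the pooled fit.
    """
    r2, rmse = score(predictions, actuals)
    aucs, mean_auc, _ = multithreshold_roc(predictions, actuals, thresholds)
    per_group: dict[str, dict] = {}
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            mask = groups == g
            if mask.sum() < 2:
                continue
            try:
                g_r2, g_rmse = score(predictions[mask], actuals[mask])
            except ValueError:
                continue
            per_group[str(g)] = {"r2": g_r2, "rmse": g_rmse,
                                 "n": int(mask.sum())}
    return EvaluationReport(r2=r2, rmse=rmse, auc_by_threshold=aucs,
                            mean_auc=mean_auc, per_group=per_group,
                            metadata=metadata or {})
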