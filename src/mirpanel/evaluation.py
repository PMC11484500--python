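"""Panel scoring and ROC analysis of cohort contrasts.

A selected miRNA panel is scored per sample with the linear predictor of
a penalized logistic model refit on the panel features alone (or with
user-supplied weights; a raw single-marker mode covers per-miRNA ROCs).
ROC curves sweep the unique score thresholds with ties grouped; the AUC
is the Mann-Whitney pair statistic with ties counted 1/2, which equals
the trapezoidal area under the (FPR, TPR) polyline.  An AUC below 0.5
simply means the score ranks the reference side higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidDesignError, LabelError
from .ensemble import pairwise_comparisons
from .penalized import (
    BinaryContrast,
    ExpressionMatrix,
    FitResult,
    LambdaPath,
    PenaltySpec,
    fit_penalized_logistic,
    loocv_tune,
)


@dataclass
class PanelScore:
    sample_id: str
    contrast: str
    score: float


@dataclass
class ROCCurve:
    """Threshold sweep (descending) with cumulative TPR/FPR and the AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    contrast: str = ""


def fit_panel_model(X: ExpressionMatrix, contrast: BinaryContrast,
                    panel: Sequence[str], penalty: str = "lasso",
                    cv_rule: str = "min", n_lambda: int = 100,
                    ) -> FitResult:
    """Refit a penalized logistic model restricted to the panel features."""
    sub = X.subset_features(panel)
    mask, y = contrast.code_response(sub.group_labels)
    Xp = sub.log_values()[mask]
    cv = loocv_tune(Xp, y, penalty, path=LambdaPath.from_data(Xp, y, n_lambda))
    lam = cv.lambda_min if cv_rule == "min" else cv.lambda_1se
    return fit_penalized_logistic(Xp, y, PenaltySpec(penalty, lam),
                                  feature_ids=list(panel))


def score_panel(panel: Sequence[str], fit: FitResult | Mapping[str, float],
                X: ExpressionMatrix, contrast_name: str = "",
                intercept: float | None = None) -> list[PanelScore]:
    """Linear-predictor scores b0 + sum_panel b_j x_j for every sample.

    ``fit`` is either a FitResult (its intercept is used) or a plain
    feature -> weight mapping (intercept defaults to 0).
    """
    missing = set(panel) - set(X.feature_ids)
    if missing:
        raise InvalidDesignError(f"panel features absent from matrix: "
                                 f"{sorted(missing)}")
    if isinstance(fit, FitResult):
        weights = fit.coefficients
        b0 = fit.intercept if intercept is None else intercept
    else:
        weights = dict(fit)
        b0 = 0.0 if intercept is None else intercept
    vals = X.log_values()
    col = {f: j for j, f in enumerate(X.feature_ids)}
    eta = np.full(X.n_samples, float(b0))
    for f, w in weights.items():
        if f in set(panel) and f in col:
            eta += w * vals[:, col[f]]
    return [PanelScore(s, contrast_name, float(e))
            for s, e in zip(X.sample_ids, eta)]


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie) over all pos/neg pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # rank-based computation: O(n log n), ties averaged
    allv = np.concatenate([neg, pos])
    order = np.argsort(allv, kind="mergesort")
    ranks = np.empty(len(allv))
    sorted_v = allv[order]
    i = 0
    while i < len(allv):
        j = i
        while j + 1 < len(allv) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[len(neg):].sum()
    n1, n0 = len(pos), len(neg)
    u = r_pos - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scores: Sequence[float], labels: Sequence[int],
              contrast: str = "") -> ROCCurve:
    """ROC over the unique score thresholds (ties grouped), highest first.

    The returned AUC is the Mann-Whitney statistic; it agrees with the
    trapezoidal area under the curve to machine precision.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidDesignError("scores and labels must be 1-D and aligned")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise LabelError("labels must be 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise LabelError("both classes must be present for a ROC curve")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # group tied scores so each unique threshold contributes one point
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[idx]
    fps = (idx + 1) - tps
    thresholds = s_sorted[idx]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    auc = auc_mann_whitney(s, y)
    return ROCCurve(thresholds=np.r_[np.inf, thresholds], fpr=fpr, tpr=tpr,
                    auc=auc, contrast=contrast)


def trapezoid_auc(curve: ROCCurve) -> float:
    """Independent area computation for cross-checking the pair statistic."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def one_vs_rest_contrasts(group_labels: Sequence[str]) -> list[BinaryContrast]:
    """Each group vs the union of the others, in label order."""
    labels = list(dict.fromkeys(group_labels))
    out = []
    for g in labels:
        rest = [h for h in labels if h != g]
        out.append(BinaryContrast(name=f"{g} vs rest",
                                  reference_groups=frozenset(rest),
                                  target_groups=frozenset([g])))
    return out


def evaluate_panel(X: ExpressionMatrix, panel: Sequence[str],
                   penalty: str = "lasso", cv_rule: str = "min",
                   include_pairwise: bool = True,
                   ) -> dict[str, ROCCurve]:
    """ROC curves of the refit panel model for every one-vs-rest contrast
    (plus all pairwise contrasts by default)."""
    groups = list(dict.fromkeys(X.group_labels))
    contrasts = one_vs_rest_contrasts(groups)
    if include_pairwise:
        contrasts += pairwise_comparisons(groups)
    out = {}
    for contrast in contrasts:
        fit = fit_panel_model(X, contrast, panel, penalty=penalty,
                              cv_rule=cv_rule)
        mask, y = contrast.code_response(X.group_labels)
        scores = score_panel(panel, fit, X, contrast_name=contrast.name)
        eta = np.array([ps.score for ps in scores])[mask]
        out[contrast.name] = roc_curve(eta, y, contrast=contrast.name)
    return out
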