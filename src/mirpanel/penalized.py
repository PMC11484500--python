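"""Penalized logistic regression with LASSO and SCAD penalties.

Built for the small-n / large-p biomarker screening regime (n = 24
samples, p = 809 miRNAs): the negative log-likelihood of a binary group
indicator, an L1 (LASSO) or smoothly-clipped-absolute-deviation (SCAD)
penalty on the slopes, a warm-started coordinate-descent solver over a
decreasing lambda path, and leave-one-out cross-validation to tune the
penalty strength.

Conventions
-----------
* Columns are standardized internally (zero mean, unit population SD);
  reported coefficients are back-transformed to the original scale.
* The solver objective is ``(1/n) * NLL + lambda * P(beta)`` in the
  standardized parameterization; the intercept is never penalized.
* ``lambda_max = max_j |x_j' (y - ybar)| / n`` on standardized columns is
  the smallest lambda with an all-zero solution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from . import _solver
from .errors import (
    DimensionMismatchError,
    FoldDegeneracyError,
    InvalidDesignError,
    LabelError,
)

logger = logging.getLogger(__name__)

PROB_CLIP = 1e-12
DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 10_000
DEFAULT_SCAD_A = 3.7

_PEN_CODE = {"lasso": 0, "scad": 1}


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Samples x features expression matrix with cohort labels.

    ``scale`` records whether ``values`` are raw (linear) intensities or
    already log2; model fitting always consumes the log2 representation
    (``log2(v + 1)`` is applied to linear-scale input).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    group_labels: list[str]
    scale: Literal["log2", "linear"] = "log2"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n < 2 or p < 1:
            raise InvalidDesignError("need at least 2 samples and 1 feature")
        if len(self.sample_ids) != n or len(self.group_labels) != n:
            raise DimensionMismatchError("sample ids/labels do not match rows")
        if len(self.feature_ids) != p:
            raise DimensionMismatchError("feature ids do not match columns")
        if len(set(self.feature_ids)) != p:
            raise InvalidDesignError("feature ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise InvalidDesignError("expression values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def log_values(self) -> np.ndarray:
        """Expression on the log2 scale used for modeling."""
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + 1.0)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise InvalidDesignError(f"unknown features: {missing[:5]}")
        cols = [idx[f] for f in feature_ids]
        return ExpressionMatrix(
            self.values[:, cols],
            list(self.sample_ids),
            list(feature_ids),
            list(self.group_labels),
            scale=self.scale,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class BinaryContrast:
    """A binary cohort contrast; the reference side is coded y = 0.

    A positive fitted coefficient then means higher expression raises the
    odds of belonging to the target side.
    """

    name: str
    reference_groups: frozenset
    target_groups: frozenset

    def __post_init__(self) -> None:
        if not self.reference_groups or not self.target_groups:
            raise InvalidDesignError("both contrast sides must be nonempty")
        if self.reference_groups & self.target_groups:
            raise InvalidDesignError("contrast sides must be disjoint")

    def code_response(self, group_labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (row mask, y) for samples belonging to either side."""
        labels = np.asarray(group_labels, dtype=object)
        in_ref = np.isin(labels, sorted(self.reference_groups))
        in_tgt = np.isin(labels, sorted(self.target_groups))
        mask = in_ref | in_tgt
        y = in_tgt[mask].astype(float)
        return mask, y


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty definition: kind, strength lambda, and the SCAD shape a."""

    kind: Literal["lasso", "scad"]
    lam: float
    scad_a: float = DEFAULT_SCAD_A

    def __post_init__(self) -> None:
        if self.kind not in _PEN_CODE:
            raise InvalidDesignError(f"unknown penalty kind {self.kind!r}")
        if not math.isfinite(self.lam) or self.lam < 0:
            raise InvalidDesignError("lambda must be finite and >= 0")
        if self.kind == "scad" and self.scad_a <= 2:
            raise InvalidDesignError("SCAD shape parameter a must exceed 2")


@dataclass
class FitResult:
    """A fitted sparse logistic model.

    ``coefficients`` maps feature id -> original-scale coefficient and
    contains only nonzeros; ``coefficients_std`` carries the standardized
    scale on which the penalty acted.  ``objective`` is the penalized
    mean negative log-likelihood at the solution (standardized scale).
    """

    intercept: float
    coefficients: dict
    lam: float
    converged: bool
    n_iterations: int
    objective: float
    coefficients_std: dict = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return len(self.coefficients)

    def predict_proba(self, X: np.ndarray, feature_ids: Sequence[str]) -> np.ndarray:
        eta = np.full(X.shape[0], self.intercept)
        idx = {f: j for j, f in enumerate(feature_ids)}
        for f, b in self.coefficients.items():
            eta += b * X[:, idx[f]]
        return np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)


@dataclass
class LambdaPath:
    """Strictly decreasing log-spaced lambda grid from lambda_max down to
    lambda_max * min_ratio."""

    values: np.ndarray
    n_lambda: int = 100
    min_ratio: float = 0.01

    @classmethod
    def from_data(cls, X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                  min_ratio: float = 0.01) -> "LambdaPath":
        if not 0 < min_ratio < 1:
            raise InvalidDesignError("min_ratio must lie in (0, 1)")
        Xs, _, _ = standardize_columns(np.asarray(X, dtype=float))
        lmax = lambda_max(Xs, y)
        vals = np.geomspace(lmax, lmax * min_ratio, n_lambda)
        return cls(values=vals, n_lambda=n_lambda, min_ratio=min_ratio)


@dataclass
class CVResult:
    """Per-lambda LOOCV error summary with the two standard lambda rules."""

    lambdas: np.ndarray
    mean_error: np.ndarray
    se_error: np.ndarray
    lambda_min: float
    lambda_1se: float
    error_metric: Literal["deviance", "misclassification"] = "deviance"
    n_folds: int = 0


# ---------------------------------------------------------------------------
# elementary operations


def logistic_probability(intercept: float, coefficients: np.ndarray,
                         x: np.ndarray) -> float:
    """P(y=1 | x) under the logistic model, clipped away from {0, 1}."""
    coefficients = np.asarray(coefficients, dtype=float)
    x = np.asarray(x, dtype=float)
    if coefficients.shape != x.shape:
        raise DimensionMismatchError(
            f"coefficient shape {coefficients.shape} != x shape {x.shape}")
    p = expit(intercept + float(coefficients @ x))
    return float(np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP))


def negative_log_likelihood(intercept: float, coefficients: np.ndarray,
                            X: np.ndarray, y: np.ndarray) -> float:
    """-sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)] (natural log)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise LabelError("labels must be 0/1")
    eta = intercept + X @ np.asarray(coefficients, dtype=float)
    p = np.clip(expit(eta), PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def penalty_value(spec: PenaltySpec, coefficients: np.ndarray) -> float:
    """lambda * P(beta): L1 for LASSO, the piecewise SCAD sum for SCAD."""
    b = np.asarray(coefficients, dtype=float)
    if spec.kind == "lasso":
        return float(spec.lam * np.sum(np.abs(b)))
    return float(sum(_solver._scad_pen_1d(float(v), float(spec.lam),
                                          float(spec.scad_a)) for v in b))


def soft_threshold(z: float, t: float) -> float:
    """sign(z) * max(|z| - t, 0)."""
    if t < 0:
        raise InvalidDesignError("threshold must be >= 0")
    return float(_solver._soft(float(z), float(t)))


def scad_threshold(z: float, lam: float, a: float = DEFAULT_SCAD_A) -> float:
    """Exact minimizer of 0.5*(b - z)^2 + SCAD(b; lam, a).

    Soft-thresholding for |z| <= 2*lam, the linearly relaxed solution on
    (2*lam, a*lam], and the identity (no shrinkage) beyond a*lam — the
    unbiasedness region that distinguishes SCAD from LASSO.
    """
    if a <= 2:
        raise InvalidDesignError("SCAD shape parameter a must exceed 2")
    if lam < 0:
        raise InvalidDesignError("lambda must be >= 0")
    return float(_solver._scad_prox(float(z), 1.0, float(lam), float(a)))


def standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale columns to unit population SD.

    Zero-variance columns get scale 1 (their coefficient stays exactly 0
    because the centered column is identically zero) and a logged warning.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero_var = sd == 0.0
    if np.any(zero_var):
        logger.warning("%d zero-variance feature column(s); coefficients "
                       "fixed at 0", int(zero_var.sum()))
    scale = np.where(zero_var, 1.0, sd)
    return (X - mean) / scale, mean, scale


def lambda_max(X_standardized: np.ndarray, y: np.ndarray) -> float:
    """max_j |x_j' (y - ybar)| / n; fits at lambda >= this are all-zero."""
    y = np.asarray(y, dtype=float)
    if np.all(y == y[0]):
        raise LabelError("response is constant; both classes are required")
    n = len(y)
    return float(np.max(np.abs(X_standardized.T @ (y - y.mean()))) / n)


# ---------------------------------------------------------------------------
# fitting


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise DimensionMismatchError("X rows must match len(y)")
    if not np.all(np.isfinite(X)):
        raise InvalidDesignError("X contains non-finite values")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise LabelError("labels must be 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise LabelError("both classes must be present")
    return X, y


def _to_original_scale(b0: float, beta_std: np.ndarray, mean: np.ndarray,
                       scale: np.ndarray) -> tuple[float, np.ndarray]:
    beta = beta_std / scale
    intercept = b0 - float(np.sum(beta * mean))
    return intercept, beta


def _make_result(feature_ids: Sequence[str] | None, b0: float,
                 beta_std: np.ndarray, mean: np.ndarray, scale: np.ndarray,
                 lam: float, it: int, conv: bool, obj: float) -> FitResult:
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(len(beta_std))]
    intercept, beta = _to_original_scale(b0, beta_std, mean, scale)
    nz = np.nonzero(beta_std)[0]
    return FitResult(
        intercept=intercept,
        coefficients={feature_ids[j]: float(beta[j]) for j in nz},
        lam=float(lam),
        converged=bool(conv),
        n_iterations=int(it),
        objective=float(obj),
        coefficients_std={feature_ids[j]: float(beta_std[j]) for j in nz},
    )


def fit_penalized_logistic(X: np.ndarray, y: np.ndarray, spec: PenaltySpec,
                           tol: float = DEFAULT_TOL,
                           max_iter: int = DEFAULT_MAX_ITER,
                           warm_start: FitResult | None = None,
                           feature_ids: Sequence[str] | None = None,
                           track_objective: bool = False,
                           ) -> FitResult | tuple[FitResult, np.ndarray]:
    """Fit one penalized logistic regression at a fixed lambda.

    Standardization happens internally; returned coefficients are on the
    original feature scale.  For SCAD without a warm start, the non-convex
    descent is run from two deterministic initializers — the LASSO solution
    at the same lambda and a denser LASSO solution at lambda/10 — and the
    stationary point with the lower penalized objective is returned.
    """
    X, y = _check_Xy(X, y)
    Xs, mean, scale = standardize_columns(X)
    p = X.shape[1]
    ybar = float(y.mean())
    b0 = math.log(ybar / (1.0 - ybar))
    beta0 = np.zeros(p)
    if warm_start is not None:
        ids = (list(feature_ids) if feature_ids is not None
               else [f"x{j}" for j in range(p)])
        idx = {f: j for j, f in enumerate(ids)}
        for f, b in warm_start.coefficients_std.items():
            if f in idx:
                beta0[idx[f]] = b
        # shift the original-scale intercept onto the standardized scale
        b0 = warm_start.intercept + float(np.sum((beta0 / scale) * mean))
    if spec.kind == "scad" and warm_start is None:
        # deterministic two-start scheme for the non-convex objective:
        # the LASSO solution at the same lambda (local-linear-approximation
        # initializer) and a denser start from LASSO at lambda/10, keeping
        # the stationary point with the lower objective
        b0_l, beta_l, _, _, _ = _solver.cd_solve(
            Xs, y, spec.lam, 0, spec.scad_a, tol, max_iter, b0, beta0, False)
        b0_d, beta_d, _, _, _ = _solver.cd_solve(
            Xs, y, 0.1 * spec.lam, 0, spec.scad_a, tol, max_iter,
            b0_l, beta_l, False)
        b0f, beta, it, conv = _solver.scad_multistart(
            Xs, y, spec.lam, spec.scad_a, tol, max_iter,
            b0_l, beta_l, b0_d, beta_d)
        hist = np.array([_solver._objective(
            y, b0f + Xs @ beta, beta, spec.lam, 1, spec.scad_a)])
        if track_objective:
            start_is_lla = np.array_equal(
                beta, _solver.cd_solve(Xs, y, spec.lam, 1, spec.scad_a, tol,
                                       max_iter, b0_l, beta_l, False)[1])
            s0, sb = (b0_l, beta_l) if start_is_lla else (b0_d, beta_d)
            b0f, beta, it, conv, hist = _solver.cd_solve(
                Xs, y, spec.lam, 1, spec.scad_a, tol, max_iter, s0, sb, True)
    else:
        code = _PEN_CODE[spec.kind]
        b0f, beta, it, conv, hist = _solver.cd_solve(
            Xs, y, spec.lam, code, spec.scad_a, tol, max_iter, b0, beta0,
            track_objective)
    if not conv:
        logger.warning("coordinate descent did not converge at lambda=%g "
                       "within %d sweeps", spec.lam, max_iter)
    res = _make_result(feature_ids, b0f, beta, mean, scale, spec.lam, it,
                       conv, hist[-1])
    if track_objective:
        return res, np.asarray(hist)
    return res


def fit_lambda_path(X: np.ndarray, y: np.ndarray, kind: str,
                    path: LambdaPath, scad_a: float = DEFAULT_SCAD_A,
                    tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                    feature_ids: Sequence[str] | None = None,
                    dev_max: float = 0.999) -> list[FitResult]:
    """Warm-started fits over a decreasing lambda path (sparsest first).

    The path is truncated (last solution carried forward) once the fit
    explains more than ``dev_max`` of the null deviance — the saturated
    regime where small-n logistic fits are separable.
    """
    if kind not in _PEN_CODE:
        raise InvalidDesignError(f"unknown penalty kind {kind!r}")
    X, y = _check_Xy(X, y)
    Xs, mean, scale = standardize_columns(X)
    lambdas = np.asarray(path.values, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise InvalidDesignError("lambda path must be strictly decreasing")
    b0s, B, iters, conv = _solver.cd_path(
        Xs, y, lambdas, _PEN_CODE[kind], scad_a, tol, max_iter, dev_max)
    out = []
    for k, lam in enumerate(lambdas):
        obj = _solver._objective(
            y, b0s[k] + Xs @ B[k], B[k], lam, _PEN_CODE[kind], scad_a)
        out.append(_make_result(feature_ids, b0s[k], B[k], mean, scale, lam,
                                iters[k], bool(conv[k]), obj))
    return out


def _heldout_error(fit_b0: float, fit_beta_std: np.ndarray,
                   x_std: np.ndarray, y_i: float, metric: str) -> float:
    p = float(np.clip(expit(fit_b0 + float(fit_beta_std @ x_std)),
                      PROB_CLIP, 1.0 - PROB_CLIP))
    if metric == "misclassification":
        return float((p > 0.5) != bool(y_i))
    return -2.0 * (y_i * math.log(p) + (1.0 - y_i) * math.log(1.0 - p))


def loocv_tune(X: np.ndarray, y: np.ndarray, kind: str,
               path: LambdaPath | None = None,
               scad_a: float = DEFAULT_SCAD_A,
               error_metric: str = "deviance",
               tol: float = DEFAULT_TOL,
               max_iter: int = DEFAULT_MAX_ITER,
               dev_max: float = 0.999) -> CVResult:
    """Leave-one-out cross-validation over the lambda path.

    Each of the n folds refits the whole path on n-1 samples (fold-local
    standardization) and scores the held-out sample; chosen for the n = 24
    cohort sizes where k-fold splits would be unstable.
    """
    X, y = _check_Xy(X, y)
    n = len(y)
    if n < 3:
        raise InvalidDesignError("LOOCV needs at least 3 samples")
    if error_metric not in ("deviance", "misclassification"):
        raise InvalidDesignError(f"unknown error metric {error_metric!r}")
    if path is None:
        path = LambdaPath.from_data(X, y)
    lambdas = np.asarray(path.values, dtype=float)
    errors = np.empty((n, len(lambdas)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
            raise FoldDegeneracyError(
                f"LOOCV fold {i} (sample index {i}) leaves a single-class "
                f"training set")
        X_tr = X[mask]
        Xs, mean, scale = standardize_columns(X_tr)
        b0s, B, _, _ = _solver.cd_path(
            np.ascontiguousarray(Xs), y_tr, lambdas, _PEN_CODE[kind], scad_a,
            tol, max_iter, dev_max)
        x_held = (X[i] - mean) / scale
        for k in range(len(lambdas)):
            errors[i, k] = _heldout_error(b0s[k], B[k], x_held, y[i],
                                          error_metric)
    mean_err = errors.mean(axis=0)
    se_err = errors.std(axis=0, ddof=1) / math.sqrt(n)
    k_min = int(np.argmin(mean_err))  # ties -> largest lambda (first index)
    thresh = mean_err[k_min] + se_err[k_min]
    k_1se = int(np.nonzero(mean_err <= thresh)[0][0])
    return CVResult(
        lambdas=lambdas,
        mean_error=mean_err,
        se_error=se_err,
        lambda_min=float(lambdas[k_min]),
        lambda_1se=float(lambdas[k_1se]),
        error_metric=error_metric,  # type: ignore[arg-type]
        n_folds=n,
    )
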