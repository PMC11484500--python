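"""Delimited-text and JSON input/output.

CSV dialect: UTF-8, comma separator, header row, '.' decimal point.
Expression tables are rows = samples with columns
(sample_id, group, <feature ids...>); write/read round-trips are lossless
on the canonical form.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .ensemble import FrequencyTable, SelectionRecord
from .errors import (
    DuplicateFeatureError,
    MalformedFileError,
    NonNumericDataError,
)
from .penalized import CVResult, ExpressionMatrix, FitResult
from .synthetic import AnnotationScheme


def write_expression_csv(matrix: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, columns=matrix.feature_ids)
    df.insert(0, "group", matrix.group_labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False)


def read_expression_csv(path, scale: str = "linear") -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        raw_header = fh.readline().strip().split(",")
    if raw_header[:2] != ["sample_id", "group"]:
        raise MalformedFileError(
            f"{path}: first two columns must be sample_id, group "
            f"(got {raw_header[:2]})")
    features = raw_header[2:]
    if not features:
        raise MalformedFileError(f"{path}: no feature columns")
    if len(set(features)) != len(features):
        dups = sorted({f for f in features if features.count(f) > 1})
        raise DuplicateFeatureError(f"{path}: duplicated feature ids {dups}")
    try:
        df = pd.read_csv(path)
    except Exception as err:  # pragma: no cover - pandas message passthrough
        raise MalformedFileError(f"cannot parse {path}: {err}") from err
    df.columns = raw_header
    values = df[features].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = [f for f in features
               if not np.issubdtype(df[f].dtype, np.number)]
        raise NonNumericDataError(f"{path}: non-numeric cells in columns "
                                  f"{bad[:5]}")
    return ExpressionMatrix(values.astype(float),
                            df["sample_id"].astype(str).tolist(),
                            features,
                            df["group"].astype(str).tolist(),
                            scale=scale)  # type: ignore[arg-type]


def write_annotations_csv(annotations: AnnotationScheme, path) -> None:
    annotations.to_frame().to_csv(path, index=False)


def read_annotations_csv(path, subset_sizes: Sequence[int] | None = None,
                         ) -> AnnotationScheme:
    df = pd.read_csv(path)
    if list(df.columns) != ["feature_id", "category"]:
        raise MalformedFileError(
            f"{path}: expected columns feature_id, category")
    cats = df["category"].tolist()
    if subset_sizes is None:
        from .synthetic import CATEGORIES
        c = [cats.count(k) for k in CATEGORIES]
        subset_sizes = (c[0], c[0] + c[1], c[0] + c[1] + c[2])
    return AnnotationScheme(df["feature_id"].astype(str).tolist(), cats,
                            tuple(subset_sizes))  # type: ignore[arg-type]


def write_calibration_points_csv(points_by_analyte: Mapping[str, list], path) -> None:
    rows = [{"analyte": a, "concentration_pM": c, "voltage_V": v}
            for a, pts in points_by_analyte.items() for c, v in pts]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibration_points_csv(path) -> dict[str, list]:
    df = pd.read_csv(path)
    need = {"analyte", "concentration_pM", "voltage_V"}
    if need - set(df.columns):
        raise MalformedFileError(f"{path}: expected columns {sorted(need)}")
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        out.setdefault(row["analyte"], []).append(
            (float(row["concentration_pM"]), float(row["voltage_V"])))
    return out


def curves_to_json(curves: Mapping[str, CalibrationCurve], path) -> None:
    payload = {a: {"A": c.A, "Cr": c.Cr, "residual_sd": c.residual_sd,
                   "n_points": c.n_points, "lod": c.lod,
                   "log_base": c.log_base}
               for a, c in curves.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def curves_from_json(path) -> dict[str, CalibrationCurve]:
    payload = json.loads(Path(path).read_text())
    return {a: CalibrationCurve(analyte=a, **v) for a, v in payload.items()}


def records_to_json(records: Sequence[SelectionRecord], path) -> None:
    payload = [{"model_id": r.model_id,
                "comparison": r.config.comparison.name,
                "penalty": r.config.penalty,
                "subset": r.config.subset,
                "lambda": r.lam,
                "coefficients": r.coefficients} for r in records]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def frequency_to_csv(freq: FrequencyTable, path) -> None:
    rows = sorted(freq.counts.items(), key=lambda fc: (-fc[1], fc[0]))
    pd.DataFrame(rows, columns=["feature_id", "count"]).to_csv(path,
                                                               index=False)


def presence_to_csv(freq: FrequencyTable, path) -> None:
    freq.presence.rename_axis("model_id").to_csv(path)


def fit_to_json(fit: FitResult) -> dict:
    return {"intercept": fit.intercept, "lambda": fit.lam,
            "converged": fit.converged, "n_iterations": fit.n_iterations,
            "objective": fit.objective,
            "coefficients": fit.coefficients,
            "coefficients_standardized": fit.coefficients_std}


def cv_to_json(cv: CVResult) -> dict:
    return {"lambdas": cv.lambdas.tolist(),
            "mean_error": cv.mean_error.tolist(),
            "se_error": cv.se_error.tolist(),
            "lambda_min": cv.lambda_min, "lambda_1se": cv.lambda_1se,
            "error_metric": cv.error_metric, "n_folds": cv.n_folds}
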