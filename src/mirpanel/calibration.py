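"""Ion-exchange-membrane sensor quantification model.

In the linear region of the Langmuir isotherm the voltage shift of the
membrane's current-voltage characteristic varies with the logarithm of the
analyte concentration:

    dV = A * (R*T/F) * log10(C / C_r)

where ``A`` is a dimensionless slope coefficient close to the theoretical
2*ln(10) of an ideal over-limiting response and ``C_r`` is the per-analyte
reference concentration at which the shift crosses zero.  This module fits
calibration curves from (concentration, voltage) points, inverts voltages
to concentrations, derives a limit of detection (LOD), and summarizes
quantified cohorts as radar-style group profiles.

Units: volts for dV, pM for concentrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    BUILTIN_ISOTHERM_CONSTANTS,
    DEFAULT_CONSTANTS,
    PANEL_9,
    PhysicalConstants,
    THEORETICAL_SLOPE,
)
from .errors import (
    DegenerateCalibrationError,
    DomainError,
    MissingCalibrationError,
)

#: Slope plausibility band, as multiples of the theoretical 2 ln(10).
SLOPE_BAND = (0.5, 2.0)
#: Fallback minimum resolvable shift when no residual SD is available.
FALLBACK_MIN_SHIFT_V = 0.01
#: LOD rule: minimum resolvable shift = this multiple of the residual SD.
LOD_SD_MULTIPLIER = 3.0


class SlopePlausibilityWarning(UserWarning):
    """Fitted slope coefficient far from the theoretical 2 ln(10)."""


@dataclass
class CalibrationCurve:
    """Per-analyte isotherm constants and fit diagnostics."""

    analyte: str
    A: float
    Cr: float
    residual_sd: float = 0.0
    n_points: int = 0
    lod: float | None = None
    log_base: str = "10"  # "10" (default) or "e" isotherm variant

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise DomainError("slope coefficient A must be > 0")
        if self.Cr <= 0:
            raise DomainError("reference concentration must be > 0")
        if self.lod is not None and self.lod < 0:
            raise DomainError("LOD must be >= 0")
        if self.log_base not in ("10", "e"):
            raise DomainError("log_base must be '10' or 'e'")

    @property
    def _log(self):
        return math.log10 if self.log_base == "10" else math.log

    @property
    def _exp_base(self) -> float:
        return 10.0 if self.log_base == "10" else math.e


def builtin_curve(name: str, constants: PhysicalConstants = DEFAULT_CONSTANTS,
                  ) -> CalibrationCurve:
    """Load one of the nine built-in panel curves by analyte name, with its
    LOD computed under the fallback minimum-shift rule."""
    if name not in BUILTIN_ISOTHERM_CONSTANTS:
        raise MissingCalibrationError(
            f"no built-in curve named {name!r}; available: {list(PANEL_9)}")
    A, Cr = BUILTIN_ISOTHERM_CONSTANTS[name]
    curve = CalibrationCurve(analyte=name, A=A, Cr=Cr)
    return lod_from_curve(curve, constants)


def builtin_curves(constants: PhysicalConstants = DEFAULT_CONSTANTS,
                   ) -> dict[str, CalibrationCurve]:
    """All nine built-in panel curves, in panel order."""
    return {name: builtin_curve(name, constants) for name in PANEL_9}


def voltage_from_concentration(curve: CalibrationCurve, C: float,
                               constants: PhysicalConstants = DEFAULT_CONSTANTS,
                               ) -> float:
    """Forward isotherm dV = A * (RT/F) * log(C / C_r); increasing in C."""
    if C <= 0:
        raise DomainError(f"concentration must be > 0 pM, got {C}")
    return curve.A * constants.thermal_voltage * curve._log(C / curve.Cr)


def concentration_from_voltage(curve: CalibrationCurve, dV: float,
                               constants: PhysicalConstants = DEFAULT_CONSTANTS,
                               ) -> float:
    """Exact inverse of the forward isotherm: C = C_r * base^(dV*F/(A*R*T))."""
    if not math.isfinite(dV):
        raise DomainError("voltage shift must be finite")
    return curve.Cr * curve._exp_base ** (dV / (curve.A * constants.thermal_voltage))


def fit_calibration(points: Sequence[tuple[float, float]],
                    constants: PhysicalConstants = DEFAULT_CONSTANTS,
                    analyte: str = "", log_base: str = "10",
                    ) -> CalibrationCurve:
    """Least-squares isotherm fit: regress dV on log(C).

    slope = A * RT/F  and  intercept = -A * (RT/F) * log(C_r), so
    A = slope * F / (R*T) and C_r = base^(-intercept/slope).  The residual
    SD uses n-2 degrees of freedom; the LOD is attached via the default
    rule (3 x residual SD, falling back to 0.01 V for exact fits).
    """
    pts = [(float(c), float(v)) for c, v in points]
    if any(c <= 0 for c, _ in pts):
        raise DomainError("all calibration concentrations must be > 0 pM")
    if len({c for c, _ in pts}) < 2:
        raise DegenerateCalibrationError(
            "need at least 2 distinct concentrations to fit a curve")
    logf = math.log10 if log_base == "10" else math.log
    x = np.array([logf(c) for c, _ in pts])
    v = np.array([dv for _, dv in pts])
    slope, intercept = np.polyfit(x, v, 1)
    if slope <= 0:
        raise DegenerateCalibrationError(
            "fitted slope is non-positive; voltages do not increase with "
            "concentration")
    resid = v - (slope * x + intercept)
    dof = len(pts) - 2
    residual_sd = float(np.sqrt(np.sum(resid ** 2) / dof)) if dof > 0 else 0.0
    A = float(slope / constants.thermal_voltage)
    base = 10.0 if log_base == "10" else math.e
    Cr = float(base ** (-intercept / slope))
    lo, hi = SLOPE_BAND
    if not lo * THEORETICAL_SLOPE <= A <= hi * THEORETICAL_SLOPE:
        warnings.warn(
            f"fitted slope coefficient A={A:.4g} is outside "
            f"[{lo}, {hi}] x 2 ln(10) = "
            f"[{lo * THEORETICAL_SLOPE:.3f}, {hi * THEORETICAL_SLOPE:.3f}]",
            SlopePlausibilityWarning, stacklevel=2)
    curve = CalibrationCurve(analyte=analyte, A=A, Cr=Cr,
                             residual_sd=residual_sd, n_points=len(pts),
                             log_base=log_base)
    return lod_from_curve(curve, constants)


def lod_from_curve(curve: CalibrationCurve,
                   constants: PhysicalConstants = DEFAULT_CONSTANTS,
                   min_resolvable_shift: float | None = None,
                   ) -> CalibrationCurve:
    """Attach the limit of detection: the concentration whose predicted
    shift equals the minimum resolvable shift (default 3 x residual SD,
    falling back to 0.01 V when no residual SD is available)."""
    if min_resolvable_shift is None:
        min_resolvable_shift = (LOD_SD_MULTIPLIER * curve.residual_sd
                                if curve.residual_sd > 0
                                else FALLBACK_MIN_SHIFT_V)
    if min_resolvable_shift <= 0:
        raise DomainError("minimum resolvable shift must be > 0 V")
    lod = concentration_from_voltage(curve, min_resolvable_shift, constants)
    return replace(curve, lod=lod)


def quantify_samples(measurements: pd.DataFrame,
                     curves: Mapping[str, CalibrationCurve],
                     constants: PhysicalConstants = DEFAULT_CONSTANTS,
                     ) -> pd.DataFrame:
    """Convert per-sample voltage shifts to concentrations with below-LOD
    flags (values are flagged, never censored).

    ``measurements`` needs columns sample_id, group, analyte, voltage_V;
    the result adds concentration_pM and below_lod.  A reading exactly at
    the LOD is not flagged (>= comparison).
    """
    required = {"sample_id", "group", "analyte", "voltage_V"}
    missing_cols = required - set(measurements.columns)
    if missing_cols:
        raise MissingCalibrationError(
            f"measurement table lacks columns {sorted(missing_cols)}")
    missing = sorted(set(measurements["analyte"]) - set(curves))
    if missing:
        raise MissingCalibrationError(f"no calibration curve for {missing}")
    out = measurements.copy()
    conc = np.empty(len(out))
    below = np.zeros(len(out), dtype=bool)
    for k, (_, row) in enumerate(out.iterrows()):
        curve = curves[row["analyte"]]
        c = concentration_from_voltage(curve, float(row["voltage_V"]),
                                       constants)
        conc[k] = c
        if curve.lod is not None:
            below[k] = c < curve.lod
    out["concentration_pM"] = conc
    out["below_lod"] = below
    return out


def summarize_group_profiles(quantified: pd.DataFrame,
                             analyte_order: Sequence[str] | None = None,
                             ) -> pd.DataFrame:
    """Radar-map substrate: per (group, analyte) mean and max concentration
    and the fraction of readings below the LOD."""
    required = {"group", "analyte", "concentration_pM", "below_lod"}
    if required - set(quantified.columns):
        raise MissingCalibrationError(
            f"quantified table lacks columns "
            f"{sorted(required - set(quantified.columns))}")
    if quantified.empty:
        raise DomainError("quantified table is empty")
    g = quantified.groupby(["group", "analyte"], sort=True)
    prof = g.agg(mean_concentration_pM=("concentration_pM", "mean"),
                 max_concentration_pM=("concentration_pM", "max"),
                 fraction_below_lod=("below_lod", "mean"),
                 n=("concentration_pM", "size")).reset_index()
    if analyte_order is None and set(prof["analyte"]) <= set(PANEL_9):
        analyte_order = [a for a in PANEL_9 if a in set(prof["analyte"])]
    if analyte_order is not None:
        prof["analyte"] = pd.Categorical(prof["analyte"],
                                         categories=list(analyte_order),
                                         ordered=True)
        prof = prof.sort_values(["group", "analyte"]).reset_index(drop=True)
    return prof
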