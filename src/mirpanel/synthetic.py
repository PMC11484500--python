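"""Synthetic cohort, annotation and sensor-measurement generators.

Emulates the statistical structure the analysis pipeline assumes: a
Nanostring-like expression matrix for four cohorts (NCAD, CAD, STEMI-pre,
STEMI-PCI; 6 samples each over 809 miRNAs), a nested feature-annotation
scheme (cardiac 450 / +vasculature 565 / +cerebral-or-rare 576 / full 809),
noisy sensor calibration points under the membrane isotherm, and per-sample
voltage measurements.  Everything is a pure function of its seed.

The expression model is log-normal: log2 intensities are Gaussian around a
baseline with per-(feature, group) mean shifts expressed in noise-SD units
("planted markers"), optionally exponentiated to linear pseudo-counts.
The planted structure is recorded in the matrix metadata so recovery tests
are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, voltage_from_concentration
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import DomainError, InvalidDesignError, MissingCalibrationError
from .penalized import ExpressionMatrix

DEFAULT_GROUPS = ("NCAD", "CAD", "STEMI-pre", "STEMI-PCI")
DEFAULT_SUBSET_SIZES = (450, 565, 576)
CATEGORIES = ("cardiac", "vasculature", "cerebral_vasculature_or_rare", "other")

#: Group-shift patterns (in noise-SD units, unit scale) of the default
#: planted markers, mirroring the stage structure of cardiac miRNA panels:
#: chronic-disease markers elevated in CAD, an acute marker unique to
#: STEMI-pre that normalizes after intervention, reperfusion markers that
#: rise only post-PCI, and injury markers sustained through both STEMI
#: stages.
DEFAULT_PLANT_PATTERNS = (
    {"STEMI-pre": 1.0, "STEMI-PCI": 1.0},   # sustained injury marker
    {"STEMI-pre": 1.0},                      # acute-phase, drops after PCI
    {"STEMI-pre": 1.0, "STEMI-PCI": 1.0},   # sustained injury marker
    {"CAD": 1.0},                            # chronic-disease marker
    {"CAD": 1.0, "STEMI-pre": 1.0},         # chronic marker carried into MI
    {"STEMI-PCI": 1.0},                      # reperfusion-response marker
    {"STEMI-PCI": 1.0},                      # reperfusion-response marker
    {"STEMI-pre": 1.0, "STEMI-PCI": 1.0},   # sustained injury marker
    {"STEMI-PCI": 1.0},                      # reperfusion-response marker
)
DEFAULT_N_PLANTED = 9


@dataclass
class AnnotationScheme:
    """Per-feature category labels with the nested subset sizes they induce."""

    feature_ids: list[str]
    categories: list[str]
    subset_sizes: tuple[int, int, int]

    def __post_init__(self) -> None:
        s1, s2, s3 = self.subset_sizes
        n = len(self.feature_ids)
        if not 0 < s1 < s2 < s3 < n:
            raise InvalidDesignError(
                f"subset sizes must be strictly increasing and < {n}")
        if len(self.categories) != n:
            raise InvalidDesignError("one category per feature required")
        counts = {c: self.categories.count(c) for c in CATEGORIES}
        expect = (s1, s2 - s1, s3 - s2, n - s3)
        if tuple(counts[c] for c in CATEGORIES) != expect:
            raise InvalidDesignError(
                f"category counts {counts} inconsistent with sizes "
                f"{self.subset_sizes} of {n}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def ids_in_category(self, category: str) -> list[str]:
        return [f for f, c in zip(self.feature_ids, self.categories)
                if c == category]

    def subsets(self) -> dict[str, list[str]]:
        """Nested feature subsets: cardiac c cardiac+vasc c +rare c full."""
        order = []
        for cat in CATEGORIES:
            order.append(self.ids_in_category(cat))
        cardiac = order[0]
        vasc = cardiac + order[1]
        ext = vasc + order[2]
        full = ext + order[3]
        return {"cardiac": cardiac, "cardiac+vasc": vasc,
                "cardiac+vasc+rare": ext, "full": full}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids,
                             "category": self.categories})


@dataclass
class CohortDesign:
    """Parameters of a synthetic four-cohort expression experiment.

    ``planted_markers`` maps feature id -> {group: mean shift in noise-SD
    units on the log2 scale}; unlisted groups sit at the baseline.
    """

    group_names: tuple = DEFAULT_GROUPS
    n_per_group: int = 6
    n_features: int = 809
    planted_markers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_log_mean: float = 7.0
    noise_sd: float = 1.0
    equicorrelation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_features < 1:
            raise InvalidDesignError("n_per_group and n_features must be >= 1")
        if self.noise_sd <= 0:
            raise InvalidDesignError("noise_sd must be > 0")
        if not 0.0 <= self.equicorrelation < 1.0:
            raise InvalidDesignError("equicorrelation must lie in [0, 1)")
        for f, shifts in self.planted_markers.items():
            bad = set(shifts) - set(self.group_names)
            if bad:
                raise InvalidDesignError(
                    f"planted marker {f!r} references unknown groups {bad}")

    @property
    def n_samples(self) -> int:
        return self.n_per_group * len(self.group_names)


def generate_annotations(n_features: int,
                         sizes: Sequence[int] = DEFAULT_SUBSET_SIZES,
                         seed: int = 0) -> AnnotationScheme:
    """Randomly assign features to the four categories with exact counts
    matching the nested subset sizes."""
    s1, s2, s3 = (int(s) for s in sizes)
    if not 0 < s1 < s2 < s3 < n_features:
        raise InvalidDesignError(
            f"sizes {sizes} must be strictly increasing and < {n_features}")
    width = max(4, len(str(n_features)))
    ids = [f"miR-n{i:0{width}d}" for i in range(n_features)]
    counts = (s1, s2 - s1, s3 - s2, n_features - s3)
    pool = np.repeat(np.arange(4), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    cats = [CATEGORIES[k] for k in pool]
    return AnnotationScheme(feature_ids=ids, categories=cats,
                            subset_sizes=(s1, s2, s3))


def default_planted_markers(annotations: AnnotationScheme,
                            n_planted: int = DEFAULT_N_PLANTED,
                            shift_sd: float = 3.0,
                            patterns: Sequence[Mapping[str, float]] | None = None,
                            ) -> dict[str, dict[str, float]]:
    """Choose planted markers inside the cardiac subset so that every
    nested feature subset can detect them.

    Marker i takes the i-th group-shift pattern (cycled), scaled by
    ``shift_sd``; the defaults reproduce the mixed chronic/acute/
    post-intervention stage structure described in the module docstring.
    """
    cardiac = annotations.ids_in_category("cardiac")
    if n_planted > len(cardiac):
        raise InvalidDesignError("more planted markers than cardiac features")
    if patterns is None:
        patterns = DEFAULT_PLANT_PATTERNS
    chosen = cardiac[:n_planted]
    return {f: {g: shift_sd * w for g, w in patterns[i % len(patterns)].items()}
            for i, f in enumerate(chosen)}


def generate_expression(design: CohortDesign, annotations: AnnotationScheme,
                        scale: str = "linear") -> ExpressionMatrix:
    """Draw an expression matrix under the cohort design.

    ``scale="linear"`` exponentiates the Gaussian log2 intensities to
    pseudo-counts (the pipeline re-logs them); ``scale="log2"`` returns the
    log intensities directly.
    """
    if annotations.n_features != design.n_features:
        raise InvalidDesignError("annotation scheme does not match design")
    unknown = set(design.planted_markers) - set(annotations.feature_ids)
    if unknown:
        raise InvalidDesignError(f"planted markers not in feature ids: "
                                 f"{sorted(unknown)[:5]}")
    rng = np.random.default_rng(design.seed)
    groups = list(design.group_names)
    n, p = design.n_samples, design.n_features
    labels = [g for g in groups for _ in range(design.n_per_group)]
    sample_ids = [f"{g}-{i + 1:02d}" for g in groups
                  for i in range(design.n_per_group)]
    mean = np.full((n, p), design.baseline_log_mean)
    col = {f: j for j, f in enumerate(annotations.feature_ids)}
    for f, shifts in design.planted_markers.items():
        for g, s in shifts.items():
            rows = [i for i, lab in enumerate(labels) if lab == g]
            mean[rows, col[f]] += s * design.noise_sd
    rho = design.equicorrelation
    eps = rng.standard_normal((n, p))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        eps = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
    logs = mean + design.noise_sd * eps
    values = logs if scale == "log2" else np.exp2(logs)
    meta = {
        "planted_markers": {f: dict(s) for f, s in design.planted_markers.items()},
        "noise_sd": design.noise_sd,
        "baseline_log_mean": design.baseline_log_mean,
        "seed": design.seed,
        "group_names": groups,
        "n_per_group": design.n_per_group,
    }
    return ExpressionMatrix(values, sample_ids, annotations.feature_ids[:],
                            labels, scale=scale, metadata=meta)  # type: ignore[arg-type]


def make_plant_fixture(seed: int = 1, n_planted: int = DEFAULT_N_PLANTED,
                       shift_sd: float = 3.0,
                       n_per_group: int = 6, n_features: int = 809,
                       subset_sizes: Sequence[int] = DEFAULT_SUBSET_SIZES,
                       ) -> tuple[ExpressionMatrix, AnnotationScheme, list[str]]:
    """Canonical study-scale fixture: 24 x 809 matrix with planted markers
    elevated by ``shift_sd`` SD in both STEMI cohorts, inside the cardiac
    subset.  Returns (matrix, annotations, planted feature ids)."""
    ann = generate_annotations(n_features, subset_sizes, seed=seed)
    planted = default_planted_markers(ann, n_planted=n_planted,
                                      shift_sd=shift_sd)
    design = CohortDesign(n_per_group=n_per_group, n_features=n_features,
                          planted_markers=planted, seed=seed)
    return generate_expression(design, ann), ann, sorted(planted)


# ---------------------------------------------------------------------------
# sensor-side generators


def generate_calibration_points(A: float, Cr: float,
                                concentrations: Sequence[float],
                                noise_sd_volts: float = 0.0,
                                seed: int = 0,
                                constants: PhysicalConstants = DEFAULT_CONSTANTS,
                                ) -> list[tuple[float, float]]:
    """(concentration pM, voltage V) pairs from the isotherm plus Gaussian
    voltage noise."""
    if Cr <= 0:
        raise DomainError("reference concentration must be > 0")
    if noise_sd_volts < 0:
        raise DomainError("noise sd must be >= 0")
    curve = CalibrationCurve(analyte="synthetic", A=A, Cr=Cr)
    rng = np.random.default_rng(seed)
    out = []
    for c in concentrations:
        v = voltage_from_concentration(curve, float(c), constants)
        if noise_sd_volts > 0:
            v += noise_sd_volts * rng.standard_normal()
        out.append((float(c), float(v)))
    return out


def generate_cohort_voltages(true_concentrations: Mapping[tuple, float],
                             curves: Mapping[str, CalibrationCurve],
                             noise_sd_volts: float = 0.0,
                             n_per_group: int = 6, seed: int = 0,
                             constants: PhysicalConstants = DEFAULT_CONSTANTS,
                             ) -> pd.DataFrame:
    """Per-sample voltage-shift table for (group, analyte) true levels.

    At zero noise, inverse quantification recovers the inputs exactly.
    """
    analytes = sorted({a for (_, a) in true_concentrations})
    missing = [a for a in analytes if a not in curves]
    if missing:
        raise MissingCalibrationError(f"no calibration curve for {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    groups = sorted({g for (g, _) in true_concentrations})
    for g in groups:
        for i in range(n_per_group):
            sample = f"{g}-{i + 1:02d}"
            for (gg, a), conc in sorted(true_concentrations.items()):
                if gg != g:
                    continue
                v = voltage_from_concentration(curves[a], conc, constants)
                if noise_sd_volts > 0:
                    v += noise_sd_volts * rng.standard_normal()
                rows.append({"sample_id": sample, "group": g, "analyte": a,
                             "voltage_V": v})
    return pd.DataFrame(rows)
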