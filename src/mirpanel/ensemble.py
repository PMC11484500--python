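"""The multi-contrast, multi-penalty, multi-subset selection ensemble.

The screening design crosses 11 binary cohort contrasts (6 unordered
pairs of the 4 cohorts plus 5 merged chronic-vs-acute contrasts) with 2
penalties (LASSO, SCAD) and 4 nested feature subsets.  Each configured
model is tuned by LOOCV, refit on all of its samples at the chosen
lambda, and contributes its selected (nonzero-coefficient) features.
Comparisons in which every configured model is empty are dropped, and
per-feature selection counts over the retained models form the basis of
the frequency ranking (report tier: count >= 6; panel tier: >= 10).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import FoldDegeneracyError, InvalidDesignError, UnsupportedDesignError
from .penalized import (
    BinaryContrast,
    CVResult,
    ExpressionMatrix,
    FitResult,
    LambdaPath,
    PenaltySpec,
    fit_penalized_logistic,
    loocv_tune,
)
from .synthetic import AnnotationScheme

logger = logging.getLogger(__name__)

#: Frequency-threshold presets: the report tier and the panel tier.
THRESHOLD_PRESETS = {"report": 6, "panel": 10}

#: Comparisons found biomarker-free in the four-cohort cardiac study
#: (dropped from the ensemble there, leaving 8 x 2 x 4 = 64 models).
CANONICAL_EMPTY_COMPARISONS = (
    "NCAD vs STEMI-pre",
    "CAD vs STEMI-PCI",
    "STEMI-pre vs STEMI-PCI",
)

ComparisonSpec = BinaryContrast


@dataclass(frozen=True)
class ModelConfiguration:
    """One cell of the grid: a comparison fitted with one penalty on one
    feature subset.  (Distinct from a comparison, which the study design
    counts separately: 11 comparisons, up to 88 configured models.)"""

    comparison: ComparisonSpec
    penalty: str
    subset: str

    @property
    def model_id(self) -> str:
        return f"{self.comparison.name}|{self.penalty}|{self.subset}"


@dataclass
class ModelGrid:
    comparisons: list
    penalties: list
    subsets: dict

    @property
    def configurations(self) -> list[ModelConfiguration]:
        return [ModelConfiguration(c, p, s)
                for c, p, s in itertools.product(
                    self.comparisons, self.penalties, list(self.subsets))]

    @property
    def n_models(self) -> int:
        return len(self.comparisons) * len(self.penalties) * len(self.subsets)


@dataclass
class SelectionRecord:
    """Outcome of one configured model: tuned lambda and the selected
    features with their signed original-scale coefficients."""

    config: ModelConfiguration
    lam: float
    coefficients: dict
    cv: CVResult | None = None

    @property
    def model_id(self) -> str:
        return self.config.model_id

    @property
    def empty(self) -> bool:
        return len(self.coefficients) == 0

    @property
    def selected_features(self) -> list[str]:
        return sorted(self.coefficients)


@dataclass
class FrequencyTable:
    """Per-feature selection counts and the signed presence matrix
    (models x features) over the retained records."""

    counts: dict
    presence: pd.DataFrame

    def count(self, feature: str) -> int:
        return self.counts.get(feature, 0)


def enumerate_comparisons(group_labels: Sequence[str],
                          ) -> list[ComparisonSpec]:
    """The canonical contrast set for a 4-cohort chronic-to-acute design.

    With labels ordered (reference, chronic, acute-pre, acute-post) this
    yields the 6 unordered pairs plus 5 merged contrasts, 11 in total,
    each with the first-listed side as the reference (y = 0).  Two labels
    fall back to the single pairwise contrast; other designs are not
    supported.
    """
    labels = list(group_labels)
    if len(set(labels)) != len(labels):
        raise InvalidDesignError("group labels must be distinct")
    if len(labels) == 2:
        a, b = labels
        return [_make_comparison([a], [b])]
    if len(labels) != 4:
        raise UnsupportedDesignError(
            f"contrast enumeration expects 4 cohort labels (got "
            f"{len(labels)}); use pairwise_comparisons() for generic designs")
    g1, g2, g3, g4 = labels
    sides = [
        ([g1], [g2]), ([g1], [g3]), ([g1], [g4]),
        ([g2], [g3]), ([g2], [g4]), ([g3], [g4]),
        ([g1, g2], [g3]), ([g1, g2], [g4]),
        ([g1], [g3, g4]), ([g2], [g3, g4]),
        ([g1, g2], [g3, g4]),
    ]
    return [_make_comparison(ref, tgt) for ref, tgt in sides]


def pairwise_comparisons(group_labels: Sequence[str]) -> list[ComparisonSpec]:
    """All unordered pairwise contrasts of any >= 2 distinct labels."""
    labels = list(group_labels)
    if len(set(labels)) < 2:
        raise InvalidDesignError("need at least 2 distinct labels")
    return [_make_comparison([a], [b])
            for a, b in itertools.combinations(labels, 2)]


def _make_comparison(ref: list, tgt: list) -> ComparisonSpec:
    name = f"{'+'.join(ref)} vs {'+'.join(tgt)}"
    return ComparisonSpec(name=name, reference_groups=frozenset(ref),
                          target_groups=frozenset(tgt))


def make_feature_subsets(annotations: AnnotationScheme) -> dict[str, list[str]]:
    """The four nested feature subsets induced by the annotation scheme."""
    subsets = annotations.subsets()
    sizes = [len(v) for v in subsets.values()]
    expect = list(annotations.subset_sizes) + [annotations.n_features]
    if sizes != expect:
        raise InvalidDesignError(
            f"subset sizes {sizes} inconsistent with annotation nesting "
            f"{expect}")
    return subsets


def build_model_grid(comparisons: Sequence[ComparisonSpec],
                     penalties: Sequence[str],
                     subsets: Mapping[str, Sequence[str]]) -> ModelGrid:
    if not comparisons or not penalties or not subsets:
        raise InvalidDesignError("grid axes must be nonempty")
    return ModelGrid(list(comparisons), list(penalties),
                     {k: list(v) for k, v in subsets.items()})


@dataclass
class EnsembleConfig:
    """Tuning settings shared by every configured model."""

    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    cv_rule: str = "min"          # "min" or "1se"
    error_metric: str = "deviance"
    scad_a: float = 3.7
    tol: float = 1e-7
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.cv_rule not in ("min", "1se"):
            raise InvalidDesignError("cv_rule must be 'min' or '1se'")


def run_single_model(config: ModelConfiguration, data: ExpressionMatrix,
                     subset_ids: Sequence[str],
                     settings: EnsembleConfig) -> SelectionRecord:
    """Tune one configured model by LOOCV and refit at the chosen lambda."""
    sub = data.subset_features(subset_ids)
    mask, y = config.comparison.code_response(sub.group_labels)
    X = sub.log_values()[mask]
    try:
        cv = loocv_tune(X, y, config.penalty,
                        path=LambdaPath.from_data(
                            X, y, settings.n_lambda, settings.lambda_min_ratio),
                        scad_a=settings.scad_a,
                        error_metric=settings.error_metric,
                        tol=settings.tol, max_iter=settings.max_iter)
    except FoldDegeneracyError as err:
        raise FoldDegeneracyError(f"model {config.model_id}: {err}") from err
    lam = cv.lambda_min if settings.cv_rule == "min" else cv.lambda_1se
    fit = fit_penalized_logistic(
        X, y, PenaltySpec(config.penalty, lam, settings.scad_a),
        tol=settings.tol, max_iter=settings.max_iter,
        feature_ids=list(subset_ids))
    return SelectionRecord(config=config, lam=lam,
                           coefficients=dict(fit.coefficients), cv=cv)


def run_ensemble(grid: ModelGrid, data: ExpressionMatrix,
                 settings: EnsembleConfig | None = None,
                 ) -> list[SelectionRecord]:
    """Run every configured model; a pure function of (data, grid,
    settings) — no randomness enters the ensemble."""
    settings = settings or EnsembleConfig()
    present = set(data.group_labels)
    for comp in grid.comparisons:
        missing = (comp.reference_groups | comp.target_groups) - present
        if missing:
            raise InvalidDesignError(
                f"comparison {comp.name!r} references absent groups "
                f"{sorted(missing)}")
    records = []
    for config in grid.configurations:
        rec = run_single_model(config, data, grid.subsets[config.subset],
                               settings)
        logger.info("model %s: lambda=%.4g, %d feature(s) selected",
                    rec.model_id, rec.lam, len(rec.coefficients))
        records.append(rec)
    return records


def drop_empty_models(records: Sequence[SelectionRecord],
                      ) -> tuple[list[SelectionRecord], list[str]]:
    """Drop a comparison only when ALL of its penalty x subset models are
    empty; returns (retained records, dropped comparison names)."""
    by_comparison: dict[str, list[SelectionRecord]] = {}
    for rec in records:
        by_comparison.setdefault(rec.config.comparison.name, []).append(rec)
    dropped = [name for name, recs in by_comparison.items()
               if all(r.empty for r in recs)]
    retained = [r for r in records
                if r.config.comparison.name not in set(dropped)]
    return retained, dropped


def selection_frequency(records: Sequence[SelectionRecord]) -> FrequencyTable:
    """Selection counts and the signed coefficient presence matrix over the
    given (already-filtered) records."""
    model_ids = [r.model_id for r in records]
    features = sorted({f for r in records for f in r.coefficients})
    presence = pd.DataFrame(0.0, index=model_ids, columns=features)
    for r in records:
        for f, b in r.coefficients.items():
            presence.loc[r.model_id, f] = b
    counts = {f: int((presence[f] != 0).sum()) for f in features}
    return FrequencyTable(counts=counts, presence=presence)


def select_panel(freq: FrequencyTable, min_count: int) -> list[str]:
    """Features selected at least ``min_count`` times, most frequent first
    (ties broken by feature id)."""
    if min_count < 1:
        raise InvalidDesignError("min_count must be >= 1")
    hits = [(f, c) for f, c in freq.counts.items() if c >= min_count]
    hits.sort(key=lambda fc: (-fc[1], fc[0]))
    return [f for f, _ in hits]


def export_drum_graph(records: Sequence[SelectionRecord]) -> dict:
    """Bipartite model-feature selection graph as node-link JSON.

    Feature nodes are restricted to features selected at least once; each
    edge carries the coefficient sign ("+" plots orange, "-" blue in the
    drum rendering) and magnitude (line thickness).
    """
    G = nx.Graph()
    for r in records:
        G.add_node(r.model_id, kind="model",
                   comparison=r.config.comparison.name,
                   penalty=r.config.penalty, subset=r.config.subset)
        for f, b in r.coefficients.items():
            if f not in G:
                G.add_node(f, kind="feature")
            G.add_edge(r.model_id, f, sign="+" if b > 0 else "-",
                       magnitude=abs(b))
    return nx.node_link_data(G, edges="links")
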