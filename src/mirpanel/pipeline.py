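"""End-to-end orchestration: simulate -> select -> calibrate -> quantify
-> evaluate, with a provenance manifest.

Every stage is a pure function of (inputs, config, seed); re-running with
an identical config reproduces the selection outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .calibration import (
    builtin_curves,
    fit_calibration,
    quantify_samples,
    summarize_group_profiles,
)
from .constants import PANEL_9
from .ensemble import (
    EnsembleConfig,
    build_model_grid,
    drop_empty_models,
    enumerate_comparisons,
    export_drum_graph,
    make_feature_subsets,
    run_ensemble,
    select_panel,
    selection_frequency,
    THRESHOLD_PRESETS,
)
from .errors import InvalidDesignError, MirpanelError
from .evaluation import evaluate_panel
from .synthetic import (
    CohortDesign,
    DEFAULT_SUBSET_SIZES,
    default_planted_markers,
    generate_annotations,
    generate_calibration_points,
    generate_cohort_voltages,
    generate_expression,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs, each with a default mirroring the study design."""

    seed: int = 1
    # cohort simulation
    n_per_group: int = 6
    n_features: int = 809
    subset_sizes: tuple = DEFAULT_SUBSET_SIZES
    n_planted: int = 9
    plant_shift_sd: float = 3.0
    noise_sd: float = 1.0
    baseline_log_mean: float = 7.0
    equicorrelation: float = 0.0
    # selection ensemble
    penalties: tuple = ("lasso", "scad")
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    cv_rule: str = "min"
    error_metric: str = "deviance"
    scad_a: float = 3.7
    report_threshold: int = THRESHOLD_PRESETS["report"]
    panel_threshold: int = THRESHOLD_PRESETS["panel"]
    # sensor emulation / calibration
    calibration_concentrations: tuple = (0.1, 1.0, 10.0, 100.0)
    calibration_noise_sd_volts: float = 0.002
    measurement_noise_sd_volts: float = 0.005
    lod_sd_multiplier: float = 3.0
    isotherm_log_base: str = "10"
    # concentration profile fed to the sensor emulation (pM, x LOD)
    baseline_lod_multiple: float = 2.0
    elevated_lod_multiple: float = 20.0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise InvalidDesignError(f"unknown config keys {sorted(bad)}")
        for key in ("subset_sizes", "penalties", "calibration_concentrations"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_full_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages on synthetic data and write every artifact plus a
    provenance manifest under ``outdir``.  Returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": config.config_hash(), "stages": {}}
    (out / "config.json").write_text(
        json.dumps(asdict(config), indent=2, default=list))

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except MirpanelError as err:
            raise type(err)(f"stage {name!r}: {err}") from err
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s done in %.2fs", name,
                    time.perf_counter() - t0)
        return result

    # --- simulate -----------------------------------------------------
    def _simulate():
        ann = generate_annotations(config.n_features, config.subset_sizes,
                                   seed=config.seed)
        planted = default_planted_markers(ann, config.n_planted,
                                          config.plant_shift_sd)
        design = CohortDesign(
            n_per_group=config.n_per_group, n_features=config.n_features,
            planted_markers=planted, noise_sd=config.noise_sd,
            baseline_log_mean=config.baseline_log_mean,
            equicorrelation=config.equicorrelation, seed=config.seed)
        matrix = generate_expression(design, ann)
        io.write_expression_csv(matrix, out / "expression.csv")
        io.write_annotations_csv(ann, out / "annotations.csv")
        return matrix, ann, sorted(planted)

    matrix, ann, planted_ids = stage("simulate", _simulate)
    manifest["planted_markers"] = planted_ids

    # --- select -------------------------------------------------------
    def _select():
        comparisons = enumerate_comparisons(list(dict.fromkeys(
            matrix.group_labels)))
        subsets = make_feature_subsets(ann)
        grid = build_model_grid(comparisons, list(config.penalties), subsets)
        settings = EnsembleConfig(
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
            cv_rule=config.cv_rule, error_metric=config.error_metric,
            scad_a=config.scad_a)
        records = run_ensemble(grid, matrix, settings)
        retained, dropped = drop_empty_models(records)
        freq = selection_frequency(retained)
        panel = select_panel(freq, config.panel_threshold)
        report = select_panel(freq, config.report_threshold)
        io.records_to_json(retained, out / "selection_records.json")
        io.frequency_to_csv(freq, out / "selection_frequency.csv")
        io.presence_to_csv(freq, out / "presence_matrix.csv")
        (out / "drum_graph.json").write_text(
            json.dumps(export_drum_graph(retained), indent=2))
        (out / "panel.json").write_text(json.dumps(
            {"panel": panel, "report_tier": report,
             "panel_threshold": config.panel_threshold,
             "report_threshold": config.report_threshold}, indent=2))
        return records, retained, dropped, panel

    records, retained, dropped, panel = stage("select", _select)
    manifest["n_models_configured"] = len(records)
    manifest["n_models_retained"] = len(retained)
    manifest["dropped_comparisons"] = sorted(dropped)
    manifest["panel"] = panel

    # --- calibrate ----------------------------------------------------
    def _calibrate():
        reference = builtin_curves()
        rng = np.random.default_rng(config.seed + 10_000)
        points, curves = {}, {}
        for i, (name, ref) in enumerate(reference.items()):
            pts = generate_calibration_points(
                ref.A, ref.Cr, config.calibration_concentrations,
                config.calibration_noise_sd_volts,
                seed=int(rng.integers(2 ** 31)))
            points[name] = pts
            curves[name] = fit_calibration(pts, analyte=name,
                                           log_base=config.isotherm_log_base)
        io.write_calibration_points_csv(points, out / "calibration_points.csv")
        io.curves_to_json(curves, out / "calibration_curves.json")
        return curves

    curves = stage("calibrate", _calibrate)

    # --- quantify -----------------------------------------------------
    def _quantify():
        groups = list(dict.fromkeys(matrix.group_labels))
        planted = matrix.metadata.get("planted_markers", {})
        elevated = {g for shifts in planted.values() for g in shifts}
        true_conc = {}
        for g in groups:
            for analyte, curve in curves.items():
                mult = (config.elevated_lod_multiple if g in elevated
                        else config.baseline_lod_multiple)
                true_conc[(g, analyte)] = (curve.lod or 0.01) * mult
        volts = generate_cohort_voltages(
            true_conc, curves, config.measurement_noise_sd_volts,
            n_per_group=config.n_per_group, seed=config.seed + 20_000)
        volts.to_csv(out / "voltage_measurements.csv", index=False)
        quantified = quantify_samples(volts, curves)
        quantified.to_csv(out / "quantified_concentrations.csv", index=False)
        profiles = summarize_group_profiles(quantified, analyte_order=PANEL_9)
        profiles.to_csv(out / "group_profiles.csv", index=False)
        return quantified

    stage("quantify", _quantify)

    # --- evaluate -----------------------------------------------------
    def _evaluate():
        eval_panel = panel if panel else planted_ids
        curves_by_contrast = evaluate_panel(matrix, eval_panel)
        rows = []
        for name, roc in curves_by_contrast.items():
            for t, f, s in zip(roc.thresholds, roc.fpr, roc.tpr):
                rows.append({"contrast": name, "threshold": t,
                             "fpr": f, "tpr": s})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "roc_curves.csv", index=False)
        aucs = {name: roc.auc for name, roc in curves_by_contrast.items()}
        (out / "roc_auc.json").write_text(json.dumps(aucs, indent=2,
                                                     sort_keys=True))
        return aucs

    manifest["auc"] = stage("evaluate", _evaluate)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
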