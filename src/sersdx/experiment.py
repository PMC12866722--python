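"""End-to-end experiment runner for the three diagnostic tasks.

``presence``   — cancer vs non-cancer (all cancer types pooled);
``early_stage``— presence restricted to early-stage cancers
                 (TNM T1N0M0 / T2N0M0, FIGO I for ovarian);
``multiclass`` — the eleven-class typing task.

A run executes simulate (or load) -> preprocess -> grouped 5-fold CV ->
sample aggregation -> evaluation -> interpretability statistics, and
writes metrics, tables and a manifest. Reruns with the same config and
seed reproduce the metrics JSON byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import CohortDataset
from .diagnose import aggregate_all, evaluate, probability_heatmap
from .interpret import differential_spectrum, peak_ratio_test
from .io import read_spectra
from .model import ModelConfig, cross_validate
from .preprocess import PreprocessConfig, preprocess_pipeline
from .simulate import (EARLY_STAGES, MARKER_DOWN, MARKER_UP, CohortPlan,
                       default_binary_plan, default_multiclass_plan,
                       simulate_cohort)

__all__ = ["RunConfig", "run_experiment"]

log = logging.getLogger(__name__)

TASKS = ("presence", "early_stage", "multiclass")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; hashed into the output manifest."""

    task: str = "presence"
    out_dir: str = "results"
    seed: int = 0
    plan: CohortPlan | None = None        # simulate when input_path is None
    input_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig | None = None      # defaults derived from task/seed
    k_folds: int = 5
    positive_class: str = "cancer"
    threshold: float = 0.5
    early_stages: tuple[str, ...] = EARLY_STAGES + ("FIGO_I",)
    write_heatmap: bool = False

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_jsonable(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _default_plan(cfg: RunConfig) -> CohortPlan:
    if cfg.task == "multiclass":
        return default_multiclass_plan(seed=cfg.seed)
    return default_binary_plan(seed=cfg.seed)


def _prepare_dataset(cfg: RunConfig) -> CohortDataset:
    if cfg.input_path is not None:
        ds = read_spectra(cfg.input_path)
    else:
        plan = cfg.plan or _default_plan(cfg)
        ds = simulate_cohort(plan)

    if cfg.task in ("presence", "early_stage"):
        cancer_types = [c for c in ds.classes if c != "non_cancer"]
        if cfg.task == "early_stage":
            stages = ds.meta["stage"].astype(str)
            is_cancer = ds.meta["class_label"] != "non_cancer"
            keep = (~is_cancer) | stages.isin(cfg.early_stages)
            n_excl = ds.meta.loc[~keep, "sample_id"].nunique()
            log.info("early_stage filter: excluded %d non-early cancer "
                     "samples", n_excl)
            ds = ds.subset(keep.to_numpy())
        if cancer_types != ["cancer"]:
            ds = ds.relabel({c: "cancer" for c in cancer_types},
                            classes=["cancer", "non_cancer"])
        else:
            ds = CohortDataset(ds.grid, ds.intensities, ds.meta,
                               classes=["cancer", "non_cancer"],
                               attrs=ds.attrs)
    return ds


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the configured task end to end; returns the metrics dict.

    Writes to ``cfg.out_dir``: ``metrics.json``, ``manifest.json``,
    ``diagnoses.csv``, ``predictions.csv``, ``confusion.csv`` and
    per-fold training histories.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        ds = _prepare_dataset(cfg)
        stage = "preprocess"
        pp = preprocess_pipeline(ds, cfg.preprocess)
        stage = "crossval"
        mc = cfg.model or ModelConfig(n_classes=len(pp.classes),
                                      seed=cfg.seed)
        cv = cross_validate(pp, mc, k=cfg.k_folds)
        stage = "diagnose"
        binary = len(pp.classes) == 2 and cfg.positive_class in pp.classes
        kwargs = (dict(positive_class=cfg.positive_class,
                       threshold=cfg.threshold) if binary else {})
        diag_ref = aggregate_all(cv.predictions, cv.classes,
                                 kind="refined", **kwargs)
        diag_cnn = aggregate_all(cv.predictions, cv.classes,
                                 kind="cnn", **kwargs)
        report = evaluate(diag_ref, classes=cv.classes)
        report_cnn = evaluate(diag_cnn, classes=cv.classes)
        stage = "interpret"
        # ratios on baseline-corrected, un-normalized intensities
        ratio_cfg = dataclasses.replace(
            cfg.preprocess, step_order=("despike", "baseline", "smooth"))
        pp_raw = preprocess_pipeline(ds, ratio_cfg)
        groups = ((cfg.positive_class, "non_cancer") if binary else None)
        ratios = {}
        diffs = {}
        if binary:
            for center in (MARKER_UP, MARKER_DOWN):
                r = peak_ratio_test(pp_raw, center, groups=groups,
                                    seed=cfg.seed)
                ratios[f"{int(center)}_over_643"] = {
                    "group_means": list(r.group_means),
                    "group_sds": list(r.group_sds),
                    "t": r.t_statistic, "p": r.p_value, "stars": r.stars,
                }
        for cls in pp.classes:
            if cls == "non_cancer":
                continue
            d = differential_spectrum(pp, cls)
            diffs[cls] = {"delta_1080": d.at(MARKER_UP),
                          "delta_1380": d.at(MARKER_DOWN)}
    except Exception as e:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {e}") \
            from e

    metrics = {
        "task": cfg.task,
        "seed": cfg.seed,
        "n_samples": report.n_samples,
        "n_spectra": int(len(pp)),
        "classes": cv.classes,
        "sample_accuracy_refined": report.accuracy,
        "sample_accuracy_cnn": report_cnn.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "auc": report.auc,
        "macro_auc": report.macro_auc,
        "confusion": report.confusion.tolist(),
        "peak_ratios": ratios,
        "differential_markers": diffs,
    }
    (out / "metrics.json").write_bytes(
        json.dumps(_jsonable(metrics), sort_keys=True, indent=2).encode())

    manifest = {
        "package": "sersdx",
        "version": __version__,
        "task": cfg.task,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_spectra": int(len(pp)),
        "n_samples": int(report.n_samples),
    }
    (out / "manifest.json").write_bytes(
        json.dumps(manifest, sort_keys=True, indent=2).encode())

    diag_ref.to_csv(out / "diagnoses.csv", index=False)
    cv.to_csv(out / "predictions.csv")
    pd.DataFrame(report.confusion, index=cv.classes,
                 columns=cv.classes).to_csv(out / "confusion.csv")
    for f, hist in enumerate(cv.histories):
        hist.to_csv(out / f"history_fold{f}.csv", index=False)
    if cfg.write_heatmap:
        probability_heatmap(cv.predictions, cv.classes,
                            csv_path=out / "probability_heatmap.csv",
                            image_path=out / "probability_heatmap.png")
    log.info("task %s: refined sample accuracy %.3f (CNN %.3f)",
             cfg.task, report.accuracy, report_cnn.accuracy)
    return metrics
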