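"""End-to-end tumor-segmentation pipeline.

Filter -> contrast enhancement -> intensity clustering -> brightest-
cluster extraction, with filter-quality metrics computed against the
input and, when a reference mask is supplied, pixelwise confusion rates
of the predicted tumor mask. The default configuration is adaptive
median filtering, CLAHE, GCPSO with k=3 clusters, and brightest-cluster
extraction with small-island removal.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._validation import check_image, check_mask
from .clustering import ClusterModel, kmeans_segment, kmedian_segment
from .extraction import ExtractionConfig, extract_tumor
from .metrics import ConfusionReport, FilterQualityReport, confusion_rates, filter_quality
from .preprocessing import (
    adaptive_median_filter,
    average_filter,
    clahe,
    global_hist_equalize,
    median_filter,
)
from .swarm import SwarmConfig, SwarmSegmenter

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineStageError",
    "TumorSegmentationPipeline",
    "run_pipeline",
    "report_row",
    "write_report_csv",
    "write_run_log",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Full run configuration; field choices mirror the CLI flags."""

    filter_kind: str = "adaptive_median"  # {median, adaptive_median, average, none}
    window: int = 3
    smax: int = 7
    enhance_kind: str = "clahe"  # {global_he, clahe, none}
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    segmenter: str = "gcpso"  # {kmeans, kmedian, pso, iwpso, gcpso}
    k: int = 3
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    seed: int = 0

    def __post_init__(self):
        if self.filter_kind not in ("median", "adaptive_median", "average", "none"):
            raise ValueError(f"unknown filter_kind {self.filter_kind!r}")
        if self.enhance_kind not in ("global_he", "clahe", "none"):
            raise ValueError(f"unknown enhance_kind {self.enhance_kind!r}")
        if self.segmenter not in ("kmeans", "kmedian", "pso", "iwpso", "gcpso"):
            raise ValueError(f"unknown segmenter {self.segmenter!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.smax < self.window or self.smax % 2 == 0:
            raise ValueError("smax must be an odd integer >= window")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    filtered: np.ndarray
    enhanced: np.ndarray
    model: ClusterModel
    mask: np.ndarray
    filter_report: FilterQualityReport | None
    confusion: ConfusionReport | None
    config: PipelineConfig


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("filter")
def _run_filter(img, cfg: PipelineConfig):
    if cfg.filter_kind == "median":
        return median_filter(img, cfg.window)
    if cfg.filter_kind == "adaptive_median":
        return adaptive_median_filter(img, cfg.window, cfg.smax)
    if cfg.filter_kind == "average":
        return average_filter(img, cfg.window)
    return img.copy()


@_stage("enhance")
def _run_enhance(img, cfg: PipelineConfig):
    if cfg.enhance_kind == "global_he":
        return global_hist_equalize(img)
    if cfg.enhance_kind == "clahe":
        return clahe(img, cfg.clahe_tiles, cfg.clahe_clip)
    return img.copy()


@_stage("segment")
def _run_segment(img, cfg: PipelineConfig) -> ClusterModel:
    if cfg.segmenter == "kmeans":
        return kmeans_segment(img, k=cfg.k, seed=cfg.seed)
    if cfg.segmenter == "kmedian":
        return kmedian_segment(img, k=cfg.k, seed=cfg.seed)
    sw = cfg.swarm
    est = SwarmSegmenter(
        variant=cfg.segmenter,
        k=cfg.k,
        n_particles=sw.n_particles,
        max_iter=sw.max_iter,
        c1=sw.c1,
        c2=sw.c2,
        w_mode=sw.w_mode,
        w=sw.w,
        v_max=sw.v_max,
        sc=sw.sc,
        fc=sw.fc,
        rho0=sw.rho0,
        rho_expand=sw.rho_expand,
        rho_contract=sw.rho_contract,
        patience=sw.patience,
        random_state=cfg.seed,
    ).fit(img)
    return est.to_model()


@_stage("extract")
def _run_extract(model: ClusterModel, cfg: PipelineConfig):
    return extract_tumor(model.labels, model.centers, cfg.extraction)


def run_pipeline(image, truth=None, config: PipelineConfig | None = None) -> RunReport:
    """Run filter -> enhance -> segment -> extract on one image.

    All stochastic stages consume ``config.seed``; identical inputs and
    seed give identical reports. ``truth`` (a binary mask) enables the
    confusion report.
    """
    config = config or PipelineConfig()
    img = check_image(image)
    if truth is not None:
        truth = check_mask(truth, name="truth")
        if truth.shape != img.shape:
            raise ValueError("truth mask shape must match the image")
    filtered = _run_filter(img, config)
    enhanced = _run_enhance(filtered, config)
    model = _run_segment(enhanced, config)
    mask = _run_extract(model, config)
    try:
        fq = filter_quality(img, filtered)
    except ValueError:
        warnings.warn("filter-quality metrics undefined for this input", stacklevel=2)
        fq = None
    confusion = confusion_rates(mask, truth) if truth is not None else None
    return RunReport(
        filtered=filtered,
        enhanced=enhanced,
        model=model,
        mask=mask,
        filter_report=fq,
        confusion=confusion,
        config=config,
    )


class TumorSegmentationPipeline:
    """Estimator-style wrapper over :func:`run_pipeline`.

    ``fit(X, y)`` runs the full pipeline on image ``X`` (with optional
    reference mask ``y``); the predicted tumor mask lands in ``mask_``
    and the full :class:`RunReport` in ``report_``.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def get_params(self, deep: bool = True):
        return {"config": self.config}

    def set_params(self, **params):
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        report = run_pipeline(X, truth=y, config=self.config)
        self.report_ = report
        self.mask_ = report.mask
        self.labels_ = report.model.labels
        self.centers_ = report.model.centers
        return self

    def predict(self, X=None):
        """Return the fitted tumor mask (the pipeline is transductive)."""
        return self.mask_


def report_row(name: str, report: RunReport) -> dict:
    """Flatten one run into a CSV row mirroring the evaluation tables."""
    row = {"Image": name}
    c = report.confusion
    if c is not None:
        row.update(
            TPR=round(c.tpr, 4),
            TNR=round(c.tnr, 4),
            FPR=round(c.fpr, 4),
            FNR=round(c.fnr, 4),
            Accuracy=round(c.accuracy, 4),
            PixelAccuracy=round(c.pixel_accuracy, 4),
        )
    f = report.filter_report
    if f is not None:
        row.update(SSI=round(f.ssi, 4), SMPI=round(f.smpi, 4))
    return row


def write_report_csv(rows: list[dict], path) -> None:
    """Write per-image metric rows as CSV (one row per processed image)."""
    pd.DataFrame(rows).to_csv(path, index=False)


def write_run_log(report: RunReport, path) -> None:
    """JSON run log: config echo, seed, and the per-iteration trace."""
    cfg = dataclasses.asdict(report.config)
    log = {
        "config": cfg,
        "seed": report.config.seed,
        "centers": list(map(float, report.model.centers)),
        "objective": report.model.objective,
        "trace": list(map(float, report.model.objective_trace)),
    }
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2)
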