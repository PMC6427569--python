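"""End-to-end orchestration: trace -> features -> classifier -> metrics.

Chains the kinematic transforms, contraction detection, block aggregation
and the SVM, logging the sample count entering and leaving every stage so
that block exclusions (too few peaks) are visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import blocks, classifier, contractions, kinematics
from .config import PipelineConfig
from .io import AccelerometerTrace, LabelTrack

log = logging.getLogger(__name__)


@dataclass
class FeatureResult:
    table: pd.DataFrame  # finalised when labels were given, else unlabelled
    threshold: float
    curve: contractions.SensitivityCurve | None
    stage_counts: dict = field(default_factory=dict)


def extract_features(
    trace: AccelerometerTrace,
    labels: LabelTrack | None = None,
    config: PipelineConfig | None = None,
) -> FeatureResult:
    """Run the signal pipeline on one trace and aggregate block features.

    Stages: jerk -> magnitude -> rolling variance -> rolling mean ->
    peak detection -> prominence threshold (knee-selected or fixed) ->
    inter-contraction intervals, plus the rolling-median baseline (JVB);
    both are averaged over contiguous blocks. When a label track is given
    the blocks are anchored at its first interval, labelled by fused
    collar classes, and incomplete rows are dropped.
    """
    cfg = config or PipelineConfig()
    counts = {"samples": trace.n}
    jerk = kinematics.differentiate(trace)
    mag = kinematics.magnitude(jerk)
    counts["jerk"] = len(mag)
    var = kinematics.rolling_variance(mag, cfg.variance_window_s)
    counts["variance"] = len(var)
    smooth = kinematics.rolling_mean(var, cfg.smoothing_window_s)
    counts["smoothed"] = len(smooth)

    peaks = contractions.detect_peaks(smooth)
    counts["peaks"] = len(peaks)
    curve = None
    if cfg.prominence_mode == "fixed":
        threshold = float(cfg.prominence_threshold)
    else:
        curve = contractions.sensitivity_curve(smooth)
        threshold = contractions.select_threshold(curve)
    kept = contractions.apply_threshold(peaks, threshold)
    counts["retained_peaks"] = len(kept)
    ici = contractions.inter_contraction_intervals(kept)
    counts["intervals"] = len(ici)

    jvb = contractions.jerk_variance_baseline(smooth, cfg.jvb_window_s)

    start = labels.intervals[0][0] if labels is not None and len(labels) else None
    table = blocks.aggregate_blocks(
        ici, jvb, block_s=cfg.block_s, start=start,
        min_intervals=cfg.min_intervals_per_block,
    )
    counts["blocks"] = len(table)
    if labels is not None:
        table = blocks.attach_labels(table, labels, rule=cfg.label_rule)
        table = blocks.finalise(table, log_base=cfg.log_base)
        counts["labelled_blocks"] = len(table)
    for stage, n in counts.items():
        log.info("stage %-16s %d", stage, n)
    return FeatureResult(table=table, threshold=threshold, curve=curve, stage_counts=counts)


@dataclass
class PipelineResult:
    features: FeatureResult
    model: classifier.TrainedModel
    metrics: classifier.MetricsReport
    folds: classifier.FoldReport
    train_table: pd.DataFrame
    test_table: pd.DataFrame


def run_end_to_end(
    trace: AccelerometerTrace,
    labels: LabelTrack,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Features, balanced 80/20 split, SVM fit, test metrics and k-fold CV."""
    cfg = config or PipelineConfig()
    feats = extract_features(trace, labels, cfg)
    train_tab, test_tab = classifier.split_balanced(
        feats.table, train_fraction=cfg.train_fraction, seed=cfg.seed
    )
    model = classifier.train(train_tab, C=cfg.C, seed=cfg.seed)
    pred = classifier.predict_table(model, test_tab)
    metrics = classifier.evaluate(pred, test_tab["label"].to_numpy())
    folds = classifier.kfold_validate(train_tab, k=cfg.k_folds, seed=cfg.seed, C=cfg.C)
    return PipelineResult(
        features=feats,
        model=model,
        metrics=metrics,
        folds=folds,
        train_table=train_tab,
        test_table=test_tab,
    )
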