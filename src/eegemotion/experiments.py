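"""Evaluation protocols: channel-wise, subband-wise and emotion-wise.

All three experiments share one template: select a pool of feature rows,
split it 70/30 stratified by emotion, min-max scale, fit an extreme
learning machine on the training rows and score the held-out rows.

* channel-wise: one pool per channel (all five subbands, all emotions) —
  which recording site carries the most emotion information;
* subband-wise: one pool per (channel, band) cell — which rhythm does;
* emotion-wise: a single (channel, band) pool, with the one-vs-rest
  metric block reported per emotion.

Reported measures are accuracy, and one-vs-rest sensitivity (recall),
specificity, precision and F1 per class, with macro and micro aggregates.
Micro-averaged sensitivity always equals the plain accuracy in the
multiclass single-label setting; both are still reported.  All randomness
(split shuffling, hidden-layer draw) flows from one master seed through
named sub-seeds recorded in every report.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from . import elm
from .errors import InputError
from .features import FEATURE_COLUMNS, BAND_SORT_ORDER, minmax_fit_transform

_SPLIT_STREAM = 21
_ELM_STREAM = 22


@dataclass(frozen=True)
class SplitSpec:
    """70/30 train/test split, stratified by emotion by default."""

    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise InputError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs shared by all three experiments."""

    hidden_count: int = elm.DEFAULT_HIDDEN
    ridge: float | None = None
    train_fraction: float = 0.70
    stratified: bool = True
    scaling: str = "train-only"  # or "full-data"
    seed: int = 0


@dataclass
class MetricsReport:
    """Confusion matrix plus the five measures, per class and aggregated."""

    confusion: np.ndarray
    classes: tuple
    accuracy: float
    per_class: pd.DataFrame  # columns = classes; rows = the metric names
    macro: dict[str, float]
    micro: dict[str, float]
    n_test: int
    warnings: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)


def _subseed(master: int, stream: int, *parts: int) -> int:
    ss = np.random.SeedSequence([int(master), stream, *[int(p) for p in parts]])
    return int(ss.generate_state(1)[0] >> 1)  # keep below 2**31


def split(matrix: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test partition of feature rows.

    Stratification preserves per-emotion proportions and requires at least
    2 rows per class.
    """
    if len(matrix) < 2:
        raise InputError("need at least 2 rows to split")
    strat = None
    if spec.stratified:
        counts = matrix["emotion"].value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise InputError(f"stratified split needs >= 2 rows per class; offending: {bad}")
        strat = matrix["emotion"]
    train, test = train_test_split(
        matrix,
        train_size=spec.train_fraction,
        stratify=strat,
        random_state=spec.seed,
        shuffle=True,
    )
    return train, test


def metrics_from_confusion(
    confusion: np.ndarray, classes: Sequence | None = None
) -> MetricsReport:
    """One-vs-rest metric block from a square confusion matrix (rows = true).

    Undefined 0/0 ratios are reported as 0 and flagged in ``warnings``.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise InputError("confusion matrix must be square")
    if np.any(cm < 0) or not np.allclose(cm, np.round(cm)):
        raise InputError("confusion matrix must hold nonnegative integer counts")
    cm = np.round(cm).astype(int)
    k = cm.shape[0]
    classes = tuple(classes) if classes is not None else tuple(range(k))
    if len(classes) != k:
        raise InputError("class list length must match the confusion matrix")
    total = int(cm.sum())
    if total == 0:
        raise InputError("empty confusion matrix")

    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    warnings: list[str] = []

    def _ratio(num, den, name):
        out = np.zeros_like(num, dtype=float)
        for i in range(k):
            if den[i] == 0:
                warnings.append(f"{name} undefined (0/0) for class {classes[i]}; reported 0")
            else:
                out[i] = num[i] / den[i]
        return out

    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    prec = _ratio(tp, tp + fp, "precision")
    f1 = np.zeros(k)
    for i in range(k):
        if prec[i] + sens[i] == 0:
            warnings.append(f"f1 undefined (0/0) for class {classes[i]}; reported 0")
        else:
            f1[i] = 2 * prec[i] * sens[i] / (prec[i] + sens[i])
    acc_ovr = (tp + tn) / total

    per_class = pd.DataFrame(
        [acc_ovr, spec, sens, prec, f1],
        index=["accuracy", "specificity", "sensitivity", "precision", "f1"],
        columns=list(classes),
    )
    accuracy = float(tp.sum() / total)
    macro = {
        "sensitivity": float(sens.mean()),
        "specificity": float(spec.mean()),
        "precision": float(prec.mean()),
        "f1": float(f1.mean()),
    }
    micro = {
        "sensitivity": float(tp.sum() / (tp.sum() + fn.sum())),
        "specificity": float(tn.sum() / (tn.sum() + fp.sum())),
        "precision": float(tp.sum() / (tp.sum() + fp.sum())),
    }
    micro["f1"] = (
        2 * micro["precision"] * micro["sensitivity"]
        / (micro["precision"] + micro["sensitivity"])
        if micro["precision"] + micro["sensitivity"] > 0
        else 0.0
    )
    return MetricsReport(
        confusion=cm,
        classes=classes,
        accuracy=accuracy,
        per_class=per_class,
        macro=macro,
        micro=micro,
        n_test=total,
        warnings=warnings,
    )


def evaluate_pool(
    pool: pd.DataFrame, config: ExperimentConfig, *seed_parts: int
) -> MetricsReport:
    """Split one pool of feature rows, fit an ELM, score the test rows."""
    split_seed = _subseed(config.seed, _SPLIT_STREAM, *seed_parts)
    elm_seed = _subseed(config.seed, _ELM_STREAM, *seed_parts)
    train, test = split(
        pool, SplitSpec(config.train_fraction, config.stratified, split_seed)
    )
    train, test, _ = minmax_fit_transform(train, test, mode=config.scaling)
    cols = list(FEATURE_COLUMNS)
    model = elm.fit(
        train[cols].to_numpy(),
        train["emotion"].tolist(),
        k=config.hidden_count,
        seed=elm_seed,
        ridge=config.ridge,
    )
    predicted = elm.predict(test[cols].to_numpy(), model)
    cm = _sk_confusion(test["emotion"].tolist(), predicted, labels=list(model.classes))
    report = metrics_from_confusion(cm, model.classes)
    report.seeds = {"split": split_seed, "elm": elm_seed, "master": config.seed}
    for w in report.warnings:
        _warnings.warn(w, stacklevel=2)
    return report


def channel_wise_experiment(
    features: pd.DataFrame, config: ExperimentConfig
) -> tuple[dict[str, MetricsReport], str]:
    """One pooled 4-class run per channel; returns reports + best channel."""
    channels = sorted(features["channel"].unique())
    if not channels:
        raise InputError("no channels present in the feature matrix")
    reports: dict[str, MetricsReport] = {}
    for c_idx, channel in enumerate(channels):
        pool = features[features["channel"] == channel]
        reports[channel] = evaluate_pool(pool, config, 1, c_idx)
    best = max(channels, key=lambda c: reports[c].accuracy)
    return reports, best


def subband_wise_experiment(
    features: pd.DataFrame, config: ExperimentConfig
) -> tuple[pd.DataFrame, tuple[str, str]]:
    """Accuracy grid over (channel, band) cells; returns grid + argmax cell."""
    channels = sorted(features["channel"].unique())
    bands = [b for b in BAND_SORT_ORDER if b in set(features["band"])]
    grid = pd.DataFrame(index=channels, columns=bands, dtype=float)
    for c_idx, channel in enumerate(channels):
        for b_idx, band in enumerate(bands):
            pool = features[(features["channel"] == channel) & (features["band"] == band)]
            if len(pool) == 0:
                raise InputError(f"empty pool for ({channel}, {band})")
            report = evaluate_pool(pool, config, 2, c_idx, b_idx)
            grid.loc[channel, band] = report.accuracy
    flat_idx = np.argmax(grid.to_numpy())
    best = (channels[flat_idx // len(bands)], bands[flat_idx % len(bands)])
    return grid, best


def emotion_wise_experiment(
    features: pd.DataFrame,
    channel: str,
    band: str,
    config: ExperimentConfig,
) -> MetricsReport:
    """Single (channel, band) pool; per-emotion one-vs-rest metric block."""
    if channel not in set(features["channel"]):
        raise InputError(f"unknown channel {channel!r}")
    if band not in set(features["band"]):
        raise InputError(f"unknown band {band!r}")
    pool = features[(features["channel"] == channel) & (features["band"] == band)]
    c_idx = sorted(features["channel"].unique()).index(channel)
    b_idx = BAND_SORT_ORDER.index(band)
    return evaluate_pool(pool, config, 3, c_idx, b_idx)
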