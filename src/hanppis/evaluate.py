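"""Confusion-matrix metrics, the feature-ablation harness, and the
sliding-window sweep.

Also houses the published benchmark statistics for sequence-based
interaction-site predictors on the fused Dset_186 / Dset_72 / Dset_164
set, used for arithmetic consistency checks (e.g. recomputing F1 from a
method's reported precision and recall).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import FEATURE_BLOCKS, TrainConfig
from .fragmenter import DatasetSplit, build_dataset
from .han_model import HanParams, predict_fragments, train

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "f1_from_precision_recall",
    "evaluate_fragments",
    "ablate",
    "window_sweep",
    "PUBLISHED_TEST_RESULTS",
    "PUBLISHED_DATASET_COUNTS",
]

#: Reported test-set results (accuracy, precision, recall, F1) of
#: sequence-based PPI-site predictors on the fused benchmark.
PUBLISHED_TEST_RESULTS = {
    "SPPIDER": (0.622, 0.209, 0.459, 0.287),
    "ISIS": (0.694, 0.211, 0.362, 0.267),
    "RF_PPI": (0.598, 0.173, 0.512, 0.258),
    "PSIVER": (0.653, 0.253, 0.468, 0.328),
    "SPRINGS": (0.631, 0.248, 0.598, 0.350),
    "GCNPPIS": (0.623, 0.233, 0.395, 0.293),
    "HANPPIS": (0.631, 0.291, 0.605, 0.393),
}

#: Per-dataset composition: (proteins, interaction sites, non-sites).
PUBLISHED_DATASET_COUNTS = {
    "Dset_186": (186, 1923, 16217),
    "Dset_72": (72, 5517, 30702),
    "Dset_164": (164, 6096, 27585),
}


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def confusion(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; call = 1 iff p >= threshold."""
    y = np.asarray(y_true)
    p = np.asarray(y_prob)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    calls = p >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & (y == 1))),
        fp=int(np.sum(calls & (y == 0))),
        tn=int(np.sum(~calls & (y == 0))),
        fn=int(np.sum(~calls & (y == 1))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0")
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, and their harmonic-mean F1."""
    if c.total == 0:
        raise ValueError("no samples")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_fragments(params: HanParams, frags, config: TrainConfig) -> MetricsReport:
    """Predict a fragment list and score against its labels."""
    probs = predict_fragments(params, frags, config)
    y = np.array([f.label for f in frags])
    return metrics(confusion(y, probs, config.threshold))


def ablate(split: DatasetSplit, config: TrainConfig, drop: str) -> MetricsReport:
    """Retrain with one feature block deleted and score the test partition.

    The block is removed from the fused vector (the input width shrinks;
    deleting the embedding also removes the projection layer), under the
    otherwise-identical config and seed.
    """
    if drop not in FEATURE_BLOCKS:
        raise ValueError(f"unknown feature block {drop!r}")
    cfg = replace(config, dropped_blocks=tuple(set(config.dropped_blocks) | {drop}))
    params, _ = train(split, cfg)
    return evaluate_fragments(params, split.test, cfg)


def window_sweep(
    records,
    feature_source,
    config: TrainConfig,
    sizes: Sequence[int] = (7, 9, 11, 13, 15),
) -> pd.DataFrame:
    """Rebuild fragments, retrain and score for each sliding-window size."""
    for w in sizes:
        if w % 2 == 0:
            raise ValueError(f"window sizes must be odd, got {w}")
    rows = []
    for w in sizes:
        cfg = replace(config, window=w)
        split = build_dataset(records, feature_source, cfg)
        params, _ = train(split, cfg)
        report = evaluate_fragments(params, split.test, cfg)
        rows.append({"window": w, **report.as_dict()})
    return pd.DataFrame(rows).set_index("window")
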