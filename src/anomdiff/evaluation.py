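"""Confusion matrices, per-class metrics and multi-instance metric bands.

Class order everywhere is FBM, CD, DM, ND.  Per-class precision, recall and
F1 come straight from the confusion matrix (rows = true labels, columns =
predictions); aggregate values are unweighted (macro) class means — with
class-balanced test sets macro and micro accuracy coincide.

For reporting against coarse diffusion categories, the four classes fold into
three: FBM and CD are subdiffusion, ND is normal diffusion, DM is
superdiffusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .dataset import LabeledDataset
from .model import ArchitectureConfig, build_network
from .simulate import CLASSES
from .training import TrainConfig, train

__all__ = [
    "EvaluationReport",
    "MetricBands",
    "confusion_matrix",
    "classification_metrics",
    "aggregate_three_class",
    "metrics_over_instances",
    "metrics_from_confusion_sequence",
]

THREE_CLASS = ("subdiffusion", "normal diffusion", "superdiffusion")
_COARSE = {"FBM": "subdiffusion", "CD": "subdiffusion", "ND": "normal diffusion", "DM": "superdiffusion"}


@dataclass
class EvaluationReport:
    confusion: np.ndarray  # 4x4 counts, rows true / columns predicted
    precision: Dict[str, float]
    recall: Dict[str, float]
    f1: Dict[str, float]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    #: classes whose precision was undefined (never predicted), reported as 0
    undefined_precision: Tuple[str, ...] = ()


@dataclass
class MetricBands:
    """Per-epoch mean and 95% half-width of each metric over k instances."""

    metrics: Dict[str, np.ndarray]  # name -> (epochs,) means
    half_widths: Dict[str, np.ndarray]
    k: int


def confusion_matrix(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> np.ndarray:
    """4x4 count matrix ``C[i, j]`` = #(true class i, predicted class j)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(CLASSES)}
    conf = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r}); allowed: {CLASSES}")
        conf[index[t], index[p]] += 1
    return conf


def classification_metrics(confusion: np.ndarray) -> EvaluationReport:
    """Per-class precision/recall/F1 and macro aggregates from counts."""
    conf = np.asarray(confusion)
    if conf.shape != (len(CLASSES), len(CLASSES)):
        raise ValueError(f"confusion matrix must be {len(CLASSES)}x{len(CLASSES)}")
    if np.any(conf < 0) or not np.issubdtype(conf.dtype, np.integer):
        raise ValueError("confusion matrix must contain non-negative integers")
    total = conf.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    precision, recall, f1 = {}, {}, {}
    undefined = []
    for j, cls in enumerate(CLASSES):
        col = conf[:, j].sum()
        row = conf[j, :].sum()
        if col == 0:
            precision[cls] = 0.0
            undefined.append(cls)
        else:
            precision[cls] = conf[j, j] / col
        recall[cls] = conf[j, j] / row if row > 0 else 0.0
        pr, rc = precision[cls], recall[cls]
        f1[cls] = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
    return EvaluationReport(
        confusion=conf,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(np.trace(conf) / total),
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        undefined_precision=tuple(undefined),
    )


def aggregate_three_class(predicted_labels: Sequence[str]) -> Dict[str, float]:
    """Proportions over {subdiffusion, normal diffusion, superdiffusion}.

    FBM and CD fold into subdiffusion, ND into normal diffusion, DM into
    superdiffusion; unrounded proportions sum to 1.
    """
    if len(predicted_labels) == 0:
        raise ValueError("no predictions to aggregate")
    counts = dict.fromkeys(THREE_CLASS, 0)
    for lab in predicted_labels:
        if lab not in _COARSE:
            raise ValueError(f"unknown label {lab!r}; allowed: {CLASSES}")
        counts[_COARSE[lab]] += 1
    n = len(predicted_labels)
    return {k: v / n for k, v in counts.items()}


def metrics_from_confusion_sequence(
    confusions: Sequence[np.ndarray],
) -> Dict[str, np.ndarray]:
    """Macro metric trajectories (one value per epoch) from per-epoch counts."""
    out = {"accuracy": [], "precision": [], "recall": [], "f1": []}
    for conf in confusions:
        rep = classification_metrics(conf)
        out["accuracy"].append(rep.accuracy)
        out["precision"].append(rep.macro_precision)
        out["recall"].append(rep.macro_recall)
        out["f1"].append(rep.macro_f1)
    return {k: np.array(v) for k, v in out.items()}


def metrics_over_instances(
    dataset: LabeledDataset,
    arch_config: ArchitectureConfig,
    train_config: TrainConfig,
    k: int,
    seeds: Sequence[int],
) -> MetricBands:
    """Train ``k`` independent instances and band their metric trajectories.

    Each instance trains with its own seed; per-epoch validation confusion
    matrices give accuracy and macro precision/recall/F1 trajectories, which
    are then summarized as mean +/- 1.96*sd/sqrt(k) (normal-approximation
    95% band).
    """
    if k < 2:
        raise ValueError("k must be >= 2 to estimate a confidence band")
    if len(seeds) != k:
        raise ValueError("need exactly k seeds")
    per_instance: List[Dict[str, np.ndarray]] = []
    for seed in seeds:
        net = build_network(arch_config, np.random.default_rng(seed))
        cfg = TrainConfig(
            batch_size=train_config.batch_size,
            learning_rate=train_config.learning_rate,
            cost=train_config.cost,
            max_epochs=train_config.max_epochs,
            selective_mode=train_config.selective_mode,
            seed=seed,
        )
        try:
            history = train(net, dataset, cfg)
        except Exception as exc:
            raise RuntimeError(f"instance with seed {seed} failed: {exc}") from exc
        per_instance.append(metrics_from_confusion_sequence(history.val_confusion))
    names = per_instance[0].keys()
    metrics, half = {}, {}
    for name in names:
        stack = np.vstack([inst[name] for inst in per_instance])  # (k, epochs)
        metrics[name] = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        half[name] = 1.96 * sd / np.sqrt(k)
    return MetricBands(metrics=metrics, half_widths=half, k=k)
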