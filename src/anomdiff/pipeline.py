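"""End-to-end experiment orchestration: simulate -> train -> evaluate.

An :class:`ExperimentManifest` bundles the three configs plus seeds; running
it generates (or reuses, keyed by a content hash of the simulation config)
the synthetic corpus, trains the classifier, evaluates the test split and
writes every artifact under one run directory, so a completed manifest alone
reproduces the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset import LabeledDataset, generate_dataset, read_dataset, write_dataset
from .evaluation import classification_metrics, confusion_matrix
from .model import ArchitectureConfig, build_network, count_parameters, save_checkpoint
from .simulate import CLASSES, SimulationConfig
from .training import TrainConfig, predict, train

__all__ = [
    "ExperimentManifest",
    "run_experiment",
    "run_ablation_grid",
    "load_configs",
    "dataset_hash",
]

logger = logging.getLogger(__name__)

ABLATION_AXES = (
    "depth",
    "kernel",
    "x0",
    "aux_features",
    "autocorrelation",
    "selective",
    "cost",
    "activation",
    "batch_size",
)


@dataclass
class ExperimentManifest:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    model_seed: int = 0
    artifacts: Dict[str, str] = field(default_factory=dict)
    metrics: Dict[str, Any] = field(default_factory=dict)
    failed_stage: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "simulation": asdict(self.simulation),
            "architecture": asdict(self.architecture),
            "training": asdict(self.training),
            "model_seed": self.model_seed,
            "artifacts": self.artifacts,
            "metrics": self.metrics,
            "failed_stage": self.failed_stage,
        }


def dataset_hash(config: SimulationConfig) -> str:
    """Content hash identifying a simulated corpus (config + seed)."""
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _tuplify(raw: dict, key: str) -> None:
    if key in raw and isinstance(raw[key], list):
        raw[key] = tuple(raw[key])


def load_configs(path: Path) -> ExperimentManifest:
    """Read a YAML config with simulation/architecture/training blocks."""
    with open(path) as f:
        doc = yaml.safe_load(f) or {}
    sim_raw = doc.get("simulation", {})
    for key in ("range_D", "range_N", "range_B", "range_R", "range_alpha", "range_Q"):
        _tuplify(sim_raw, key)
    arch_raw = doc.get("architecture", {})
    _tuplify(arch_raw, "aux_features")
    train_raw = doc.get("training", {})
    _tuplify(train_raw, "selective_mode")
    return ExperimentManifest(
        simulation=SimulationConfig(**sim_raw),
        architecture=ArchitectureConfig(**arch_raw),
        training=TrainConfig(**train_raw),
        model_seed=doc.get("model_seed", 0),
    )


def _ensure_dataset(
    config: SimulationConfig, cache_dir: Optional[Path]
) -> LabeledDataset:
    """Generate the corpus, reusing an on-disk copy keyed by content hash."""
    if cache_dir is None:
        return generate_dataset(config)
    key = dataset_hash(config)
    ds_dir = Path(cache_dir) / f"dataset-{key}"
    if (ds_dir / "manifest.csv").exists():
        logger.info("reusing cached dataset %s", ds_dir)
        return read_dataset(ds_dir)
    dataset = generate_dataset(config)
    write_dataset(dataset, ds_dir)
    return dataset


def run_experiment(
    manifest: ExperimentManifest,
    out_dir: Path,
    dataset_cache: Optional[Path] = None,
    write_artifacts: bool = True,
) -> ExperimentManifest:
    """Run a full experiment and return the completed manifest.

    Stages: dataset (simulate or reuse by content hash), train, evaluate on
    the held-out test split.  A failing stage is recorded on the manifest and
    re-raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "dataset"
    try:
        dataset = _ensure_dataset(manifest.simulation, dataset_cache)
        stage = "train"
        network = build_network(
            manifest.architecture, np.random.default_rng(manifest.model_seed)
        )
        manifest.metrics["parameter_count"] = count_parameters(network)
        history = train(network, dataset, manifest.training)
        stage = "evaluate"
        test_set = dataset.subset("test")
        probs = predict(network, test_set.trajectories())
        pred_labels = [CLASSES[i] for i in probs.argmax(axis=1)]
        conf = confusion_matrix(test_set.labels(), pred_labels)
        report = classification_metrics(conf)
        manifest.metrics.update(
            {
                "best_epoch": history.best_epoch,
                "train_accuracy": history.train_accuracy[history.best_epoch - 1],
                "val_accuracy": history.val_accuracy[history.best_epoch - 1],
                "test_accuracy": report.accuracy,
                "macro_f1": report.macro_f1,
                "confusion": conf.tolist(),
            }
        )
        if write_artifacts:
            stage = "write"
            ckpt = out_dir / "checkpoint.npz"
            save_checkpoint(network, ckpt)
            hist = pd.DataFrame(
                {
                    "epoch": np.arange(1, len(history.val_accuracy) + 1),
                    "train_acc": history.train_accuracy,
                    "val_acc": history.val_accuracy,
                    "loss": history.mean_loss,
                    "bp_fraction": history.bp_fraction,
                }
            )
            hist_path = out_dir / "history.csv"
            hist.to_csv(hist_path, index=False)
            report_path = out_dir / "report.json"
            with open(report_path, "w") as f:
                json.dump(
                    {
                        "confusion": conf.tolist(),
                        "accuracy": report.accuracy,
                        "precision": report.precision,
                        "recall": report.recall,
                        "f1": report.f1,
                        "macro_f1": report.macro_f1,
                    },
                    f,
                    indent=1,
                )
            manifest.artifacts = {
                "checkpoint": str(ckpt),
                "history": str(hist_path),
                "report": str(report_path),
            }
            with open(out_dir / "manifest.yaml", "w") as f:
                yaml.safe_dump(manifest.to_dict(), f)
    except Exception:
        manifest.failed_stage = stage
        raise
    return manifest


def _apply_axis(manifest: ExperimentManifest, axis: str, value) -> ExperimentManifest:
    arch, tr = manifest.architecture, manifest.training
    if axis == "depth":
        arch = replace(arch, depth=int(value))
    elif axis == "kernel":
        arch = replace(arch, kernel=int(value))
    elif axis == "x0":
        arch = replace(arch, x0=int(value))
    elif axis == "aux_features":
        arch = replace(arch, aux_features=tuple(value))
    elif axis == "autocorrelation":
        arch = replace(arch, use_autocorrelation=bool(value))
    elif axis == "activation":
        arch = replace(arch, activation=str(value))
    elif axis == "selective":
        tr = replace(tr, selective_mode=tuple(value) if value else None)
    elif axis == "cost":
        tr = replace(tr, cost=str(value))
    elif axis == "batch_size":
        tr = replace(tr, batch_size=int(value))
    else:
        raise ValueError(f"unknown ablation axis {axis!r}; allowed: {ABLATION_AXES}")
    return ExperimentManifest(
        simulation=manifest.simulation,
        architecture=arch,
        training=tr,
        model_seed=manifest.model_seed,
    )


def run_ablation_grid(
    base: ExperimentManifest,
    axis: str,
    values: Sequence,
    out_dir: Path,
    dataset_cache: Optional[Path] = None,
) -> pd.DataFrame:
    """One experiment per axis value; returns a summary table.

    Columns mirror the ablation reports: value, parameter count, training and
    validation accuracy at the best epoch, best epoch.  Unsupported values
    are skipped with a warning and recorded with null metrics.
    """
    if axis not in ABLATION_AXES:
        raise ValueError(f"unknown ablation axis {axis!r}; allowed: {ABLATION_AXES}")
    rows = []
    out_dir = Path(out_dir)
    for i, value in enumerate(values):
        try:
            manifest = _apply_axis(base, axis, value)
        except (ValueError, TypeError) as exc:
            warnings.warn(f"skipping unsupported {axis}={value!r}: {exc}")
            rows.append({"value": value, "skipped": True})
            continue
        run_dir = out_dir / f"{axis}-{i}"
        manifest = run_experiment(manifest, run_dir, dataset_cache=dataset_cache)
        rows.append(
            {
                "value": value,
                "parameters": manifest.metrics["parameter_count"],
                "train_accuracy": manifest.metrics["train_accuracy"],
                "val_accuracy": manifest.metrics["val_accuracy"],
                "best_epoch": manifest.metrics["best_epoch"],
                "skipped": False,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / f"ablation-{axis}.csv", index=False)
    return table
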