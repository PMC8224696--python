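"""Labeled corpus assembly, stratified splitting, on-disk layout and encoding.

The default corpus mirrors the study conditions: 5,000 noisy trajectories per
diffusion class (20,000 total), split 70/15/15 into train/validation/test with
stratification so every split is class-balanced (3,500/750/750 per class).

Network inputs are fixed-size 1-D vectors: each trajectory is translated so it
starts at the origin, its x/y coordinates are flattened into a single channel
(x0, y0, x1, y1, ...) and the tail is zero-padded to ``2*fixed_length``.  A
two-channel (x, y) layout is available behind a flag for experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import (
    CLASSES,
    ModelParams,
    SimulationConfig,
    Trajectory,
    add_noise,
    child_rng,
    sample_model_params,
    simulate,
)

__all__ = [
    "SPLITS",
    "Record",
    "LabeledDataset",
    "EncodedBatch",
    "generate_dataset",
    "stratified_split",
    "encode_batch",
    "one_hot",
    "write_dataset",
    "read_dataset",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

SPLITS = ("train", "validation", "test")

#: Default encoder length: the maximum trajectory length of the corpus.
DEFAULT_FIXED_LENGTH = 600


@dataclass
class Record:
    id: str
    trajectory: Trajectory
    label: str
    split: Optional[str]
    params: ModelParams


@dataclass
class LabeledDataset:
    records: List[Record]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "LabeledDataset":
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}; allowed: {SPLITS}")
        return LabeledDataset([r for r in self.records if r.split == split])

    def labels(self) -> List[str]:
        return [r.label for r in self.records]

    def trajectories(self) -> List[Trajectory]:
        return [r.trajectory for r in self.records]


@dataclass
class EncodedBatch:
    """Fixed-size network inputs.

    inputs:  float32 array (batch, channels, length)
    targets: one-hot rows over the class order FBM, CD, DM, ND
    lengths: original n_points per sample
    """

    inputs: np.ndarray
    targets: np.ndarray
    lengths: np.ndarray


def one_hot(labels: Sequence[str]) -> np.ndarray:
    idx = np.array([CLASSES.index(lab) for lab in labels])
    out = np.zeros((len(idx), len(CLASSES)), dtype=np.float32)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def stratified_split(
    dataset: LabeledDataset,
    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15),
    rng: Optional[np.random.Generator] = None,
) -> LabeledDataset:
    """Assign train/validation/test splits independently within each class.

    Per-class counts follow the largest-remainder rounding of the fractions
    (ties broken in split order), so proportions deviate from the target by at
    most one record per class.  Assignment within a class is a random
    permutation from ``rng`` (order-preserving when ``rng`` is None).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    # canonical class order (then first appearance) so the random stream is
    # consumed identically in every process
    present = list(dict.fromkeys(r.label for r in dataset.records))
    present.sort(key=lambda lab: CLASSES.index(lab) if lab in CLASSES else len(CLASSES))
    for lab in present:
        idx = [i for i, r in enumerate(dataset.records) if r.label == lab]
        n = len(idx)
        raw = [f * n for f in fractions]
        counts = [int(np.floor(v)) for v in raw]
        remainders = [v - c for v, c in zip(raw, counts)]
        for k in sorted(range(3), key=lambda k: (-remainders[k], k))[: n - sum(counts)]:
            counts[k] += 1
        order = np.array(idx)
        if rng is not None:
            order = order[rng.permutation(n)]
        bounds = np.cumsum(counts)
        for split, chunk in zip(SPLITS, np.split(order, bounds[:-1])):
            for i in chunk:
                dataset.records[i].split = split
    return dataset


def generate_dataset(config: SimulationConfig) -> LabeledDataset:
    """Simulate the full labeled corpus defined by ``config``.

    For each class, ``n_per_class`` trajectories are generated with freshly
    sampled parameters and SNR-derived localization noise, then the stratified
    70/15/15 split is applied.  Each trajectory consumes its own child seed of
    ``config.seed``, so the corpus is bit-reproducible.
    """
    records: List[Record] = []
    index = 0
    for kind in CLASSES:
        for _ in range(config.n_per_class):
            rng = child_rng(config.seed, index)
            params = sample_model_params(kind, config, rng)
            traj = simulate(params, rng)
            traj = add_noise(traj, params.sigma_noise, rng)
            records.append(
                Record(
                    id=f"{index:06d}",
                    trajectory=traj,
                    label=kind,
                    split=None,
                    params=params,
                )
            )
            index += 1
    dataset = LabeledDataset(records)
    split_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2**20,))
    )
    return stratified_split(dataset, rng=split_rng)


def encode_batch(
    trajectories: Sequence[Trajectory],
    fixed_length: int = DEFAULT_FIXED_LENGTH,
    labels: Optional[Sequence[str]] = None,
    channels: int = 1,
) -> EncodedBatch:
    """Encode trajectories into fixed-size network inputs.

    Each trajectory is re-centred on its first position; with ``channels=1``
    (default) x and y are interleaved into one channel of length
    ``2*fixed_length``, with ``channels=2`` they form two channels of length
    ``fixed_length``.  Tails are zero-padded; original lengths are retained.
    """
    if channels not in (1, 2):
        raise ValueError("channels must be 1 or 2")
    n = len(trajectories)
    lengths = np.array([t.n_points for t in trajectories])
    if np.any(lengths > fixed_length):
        bad = int(np.argmax(lengths > fixed_length))
        raise ValueError(
            f"trajectory {bad} has {lengths[bad]} points, exceeding fixed_length={fixed_length}"
        )
    xy = np.zeros((n, 2, fixed_length), dtype=np.float32)
    for i, t in enumerate(trajectories):
        m = t.n_points
        xy[i, 0, :m] = t.xs - t.xs[0]
        xy[i, 1, :m] = t.ys - t.ys[0]
    if channels == 2:
        inputs = xy
    else:
        # flatten the (2, L) coordinate block row-major: [x_0..x_L, y_0..y_L]
        inputs = np.ascontiguousarray(xy.reshape(n, 1, 2 * fixed_length))
    targets = one_hot(labels) if labels is not None else np.zeros((n, len(CLASSES)), np.float32)
    return EncodedBatch(inputs=inputs, targets=targets, lengths=lengths)


# ---------------------------------------------------------------------------
# on-disk layout: manifest.csv + one t,x,y CSV per trajectory
# ---------------------------------------------------------------------------

_PARAM_COLS = ["kind", "D", "N", "dt", "v", "beta", "R", "rc", "B", "H", "alpha", "Q", "sigma_noise"]


def write_trajectory_csv(traj: Trajectory, path: Path) -> None:
    pd.DataFrame({"t": traj.times, "x": traj.xs, "y": traj.ys}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_trajectory_csv(path: Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return Trajectory(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy())


def write_dataset(dataset: LabeledDataset, directory: Path) -> Path:
    """Write the dataset as ``manifest.csv`` plus per-trajectory CSVs.

    Returns the manifest path.  Round-trips losslessly (coordinates at full
    float precision, labels, splits, generative parameters).
    """
    directory = Path(directory)
    traj_dir = directory / "trajectories"
    traj_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.records:
        fname = f"trajectories/{rec.id}.csv"
        write_trajectory_csv(rec.trajectory, directory / fname)
        row = {"id": rec.id, "file": fname, "label": rec.label, "split": rec.split}
        for col in _PARAM_COLS:
            row[col] = getattr(rec.params, col)
        rows.append(row)
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.17g")
    return manifest


def read_dataset(directory: Path) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {directory}")
    df = pd.read_csv(manifest, float_precision="round_trip")
    records = []
    for i, row in df.iterrows():
        path = directory / row["file"]
        if not path.exists():
            raise FileNotFoundError(f"manifest row {i} (id {row['id']}): missing file {path}")
        try:
            traj = read_trajectory_csv(path)
        except Exception as exc:  # re-raise with row context
            raise ValueError(f"manifest row {i} (id {row['id']}): {exc}") from exc
        kwargs = {}
        for col in _PARAM_COLS:
            val = row[col]
            if col == "kind":
                kwargs[col] = val
            elif col == "N":
                kwargs[col] = int(val)
            else:
                kwargs[col] = None if pd.isna(val) else float(val)
        split = row["split"] if isinstance(row["split"], str) else None
        records.append(
            Record(
                id=str(row["id"]).zfill(6),
                trajectory=traj,
                label=row["label"],
                split=split,
                params=ModelParams(**kwargs),
            )
        )
    return LabeledDataset(records)
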