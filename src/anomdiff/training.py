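"""Training loop: MSE-on-softmax objective, Adam, selective backprop.

The classifier is trained on one-hot targets with the squared error between
the softmax output and the target (cross-entropy is available as an
alternative), batches of 512 and learning rate 3e-4 by default.  Training
always runs to ``max_epochs`` and restores the weights of the epoch with the
highest validation accuracy.

Selective backprop prioritizes high-loss samples: per batch, either the
shortest prefix of descending losses covering a fraction of the total loss
(``loss_coverage``) or a fixed fraction of the highest-loss samples
(``top_fraction``) contributes to the gradient; the rest of the batch only
runs forward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .dataset import LabeledDataset, encode_batch, one_hot
from .features import compute_features, increment_autocorrelation
from .model import AUTOCORR_LAGS, ArchitectureConfig, Network
from .simulate import CLASSES, Trajectory

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "train",
    "predict",
    "predict_encoded",
    "prepare_inputs",
    "select_backprop_subset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 512
    learning_rate: float = 3e-4
    cost: str = "MSE"  # or "cross-entropy"
    max_epochs: int = 70
    #: ``None`` or ``("loss_coverage", f)`` / ``("top_fraction", f)``
    selective_mode: Optional[Tuple[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.cost not in nn.LOSSES:
            raise ValueError(f"cost must be one of {sorted(nn.LOSSES)}")
        if self.selective_mode is not None:
            mode, frac = self.selective_mode
            if mode not in ("loss_coverage", "top_fraction"):
                raise ValueError("selective mode must be loss_coverage or top_fraction")
            if not 0.0 < frac <= 1.0:
                raise ValueError("selective fraction must lie in (0, 1]")


@dataclass
class TrainingHistory:
    train_accuracy: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    mean_loss: List[float] = field(default_factory=list)
    bp_fraction: List[float] = field(default_factory=list)
    #: per-epoch validation confusion matrix (true x predicted, class order
    #: FBM, CD, DM, ND) — enables metric trajectories without re-evaluation
    val_confusion: List[np.ndarray] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-based index of the epoch with the highest validation accuracy."""
        if not self.val_accuracy:
            raise ValueError("no epochs recorded")
        return int(np.argmax(self.val_accuracy)) + 1


def select_backprop_subset(
    losses: np.ndarray, mode: Optional[Tuple[str, float]]
) -> np.ndarray:
    """Indices of the samples whose gradients are kept, per the selective mode.

    ``loss_coverage(f)``: sort losses descending and take the shortest prefix
    whose sum reaches ``f`` of the total (all indices if the total is zero).
    ``top_fraction(f)``: the ``ceil(f*n)`` highest-loss samples.  Ties break
    on the original index; ``None`` keeps everything.
    """
    losses = np.asarray(losses, dtype=float)
    if losses.size == 0:
        raise ValueError("losses must be non-empty")
    if np.any(losses < 0):
        raise ValueError("losses must be non-negative")
    n = losses.size
    if mode is None:
        return np.arange(n)
    kind, frac = mode
    order = np.lexsort((np.arange(n), -losses))  # descending, stable in index
    if kind == "top_fraction":
        k = math.ceil(frac * n)
        return np.sort(order[:k])
    if kind == "loss_coverage":
        total = losses.sum()
        if total == 0:
            return np.arange(n)
        csum = np.cumsum(losses[order])
        k = int(np.searchsorted(csum, frac * total - 1e-12 * total)) + 1
        return np.sort(order[:k])
    raise ValueError(f"unknown selective mode {kind!r}")


def prepare_inputs(
    trajectories: Sequence[Trajectory], config: ArchitectureConfig
) -> Tuple[np.ndarray, Optional[np.ndarray], np.ndarray]:
    """Encode trajectories into the tensors the network expects.

    Returns ``(inputs, aux, lengths)``: the fixed-size input tensor (with
    tiled autocorrelation channels appended when configured), the auxiliary
    feature matrix (or None), and the per-sample trajectory lengths used for
    masked pooling.
    """
    batch = encode_batch(
        trajectories, fixed_length=config.fixed_length, channels=config.input_channels
    )
    inputs = batch.inputs
    if config.dimension == 2:
        # one-channel 2-D array: coordinates as rows
        if config.input_channels != 2:
            n = inputs.shape[0]
            inputs = inputs.reshape(n, 1, config.fixed_length, 2).transpose(0, 1, 3, 2)
        else:
            inputs = inputs[:, None, :, :]
    if config.use_autocorrelation:
        acf = np.zeros((len(trajectories), len(AUTOCORR_LAGS)), dtype=np.float32)
        for i, t in enumerate(trajectories):
            for j, lag in enumerate(AUTOCORR_LAGS):
                if lag < t.n_points - 1:
                    acf[i, j] = increment_autocorrelation(t, lag)
        sp = inputs.shape[2:]
        tiles = np.broadcast_to(
            acf.reshape(acf.shape + (1,) * len(sp)), acf.shape + sp
        ).astype(np.float32)
        inputs = np.concatenate([inputs, tiles], axis=1)
    aux = None
    if config.aux_features:
        aux = np.zeros((len(trajectories), len(config.aux_features)), dtype=np.float32)
        for i, t in enumerate(trajectories):
            fv = compute_features(t)
            for j, name in enumerate(config.aux_features):
                aux[i, j] = getattr(fv, name)
    return inputs, aux, batch.lengths


def _forward_in_batches(
    network: Network,
    inputs: np.ndarray,
    aux: Optional[np.ndarray],
    lengths: Optional[np.ndarray],
    batch: int = 256,
) -> np.ndarray:
    outs = []
    for i in range(0, len(inputs), batch):
        a = aux[i : i + batch] if aux is not None else None
        ln = lengths[i : i + batch] if lengths is not None else None
        outs.append(
            network.forward(inputs[i : i + batch], a, training=False, lengths=ln)
        )
    return np.concatenate(outs, axis=0)


def predict_encoded(
    network: Network,
    inputs: np.ndarray,
    aux: Optional[np.ndarray] = None,
    lengths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-class probability rows for already-encoded inputs."""
    return nn.softmax(_forward_in_batches(network, inputs, aux, lengths))


def predict(network: Network, trajectories: Sequence[Trajectory]) -> np.ndarray:
    """Per-class probability rows (class order FBM, CD, DM, ND)."""
    inputs, aux, lengths = prepare_inputs(trajectories, network.config)
    return predict_encoded(network, inputs, aux, lengths)


def _accuracy_and_confusion(
    probs: np.ndarray, targets: np.ndarray
) -> Tuple[float, np.ndarray]:
    pred = probs.argmax(axis=1)
    true = targets.argmax(axis=1)
    k = len(CLASSES)
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (true, pred), 1)
    return float((pred == true).mean()), conf


def train(
    network: Network,
    dataset: LabeledDataset,
    config: TrainConfig,
) -> TrainingHistory:
    """Fit ``network`` on the train split, track the validation split.

    Returns the training history; the network is left holding the weights of
    the best validation epoch.
    """
    train_set = dataset.subset("train")
    val_set = dataset.subset("validation")
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("dataset needs non-empty train and validation splits")

    arch = network.config
    x_train, aux_train, len_train = prepare_inputs(train_set.trajectories(), arch)
    y_train = one_hot(train_set.labels())
    x_val, aux_val, len_val = prepare_inputs(val_set.trajectories(), arch)
    y_val = one_hot(val_set.labels())

    loss_fn = nn.LOSSES[config.cost]
    opt = nn.Adam(network.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    history = TrainingHistory()
    best_state: Optional[dict] = None
    best_acc = -1.0
    n = len(train_set)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses_epoch = []
        n_selected = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            ab = aux_train[idx] if aux_train is not None else None
            yb = y_train[idx]
            logits = network.forward(xb, ab, training=True, lengths=len_train[idx])
            losses, dlogits = loss_fn(logits, yb)
            if not np.all(np.isfinite(losses)):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            losses_epoch.append(losses)
            sel = select_backprop_subset(losses, config.selective_mode)
            n_selected += len(sel)
            mask = np.zeros((len(idx), 1), dtype=nn.DTYPE)
            mask[sel] = 1.0 / len(sel)
            opt.zero_grad()
            network.backward(dlogits * mask)
            opt.step()
        # end-of-epoch re-evaluation in inference mode
        train_probs = predict_encoded(network, x_train, aux_train, len_train)
        val_probs = predict_encoded(network, x_val, aux_val, len_val)
        train_acc, _ = _accuracy_and_confusion(train_probs, y_train)
        val_acc, val_conf = _accuracy_and_confusion(val_probs, y_val)
        history.train_accuracy.append(train_acc)
        history.val_accuracy.append(val_acc)
        history.mean_loss.append(float(np.concatenate(losses_epoch).mean()))
        history.bp_fraction.append(n_selected / n)
        history.val_confusion.append(val_conf)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = network.state()
        logger.info(
            "epoch %d: train_acc=%.4f val_acc=%.4f loss=%.4f bp=%.2f",
            epoch,
            train_acc,
            val_acc,
            history.mean_loss[-1],
            history.bp_fraction[-1],
        )
    if best_state is not None:
        network.load_state(best_state)
    return history
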