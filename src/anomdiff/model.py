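"""The configurable 1-D/2-D residual classifier family.

The classifier is a reduced residual network: a convolutional stem, ``depth``
stages whose feature-map widths follow the doubling schedule
``x_i = x0 * 2**(i-1)``, two residual units per stage (the first unit of every
stage after the first downsamples by stride 2), global average pooling and a
single 4-unit dense softmax head.

Two stem/shortcut variants are supported:

* **plain** — a single wide stem convolution (kernel 7) and stride-2 1x1
  projection shortcuts;
* **xresnet** — the "bag of tricks" refinements: a stem of three small
  convolutions with widths ``(x0/4, x0, x0)``, average-pool-then-1x1
  projection shortcuts, and (optionally) zero-initialized final
  normalization scales so each residual unit starts as the identity.

Every normalization layer carries a learnable per-channel *activation
threshold* in addition to its scale and shift (three parameters per channel);
the threshold shifts the level above which the following activation fires.
The default configuration is the reduced model: 1-D, XResNet variant, depth 3,
32 base feature maps, kernel 5, ReLU, thresholds on — 399,556 trainable
parameters.

Optional inputs: selected auxiliary scalar features are concatenated to the
pooled representation right before the dense head (+4 parameters each), and
step-autocorrelation values at lags 8, 16 and 24 can join as extra tiled
input channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .features import FEATURE_NAMES

__all__ = [
    "ArchitectureConfig",
    "Network",
    "feature_map_widths",
    "build_network",
    "count_parameters",
    "describe_network",
    "save_checkpoint",
    "load_checkpoint",
    "AUTOCORR_LAGS",
]

#: Frame lags of the optional autocorrelation input channels.
AUTOCORR_LAGS = (8, 16, 24)


@dataclass(frozen=True)
class ArchitectureConfig:
    """Configuration space of the residual classifier family.

    Defaults reproduce the reduced final model.
    """

    use_xresnet: bool = True
    dimension: int = 1
    depth: int = 3
    x0: int = 32
    kernel: int = 5
    n_classes: int = 4
    activation: str = "relu"
    activation_threshold: bool = True
    aux_features: Tuple[str, ...] = ()
    use_autocorrelation: bool = False
    input_channels: int = 1
    fixed_length: int = 600
    blocks_per_stage: int = 2
    #: pool only over positions backed by real samples (zero-padded tails of
    #: short trajectories are excluded from the global average)
    masked_pooling: bool = True
    #: start every residual branch at zero by zeroing its final norm scale;
    #: off by default — at learning rate 3e-4 the scales grow too slowly for
    #: the branches to contribute within the epoch budgets used here
    zero_init_residual: bool = False

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.x0 < 1:
            raise ValueError("x0 must be >= 1")
        for f in self.aux_features:
            if f not in FEATURE_NAMES:
                raise ValueError(f"unknown aux feature {f!r}; allowed: {FEATURE_NAMES}")

    @property
    def total_input_channels(self) -> int:
        return self.input_channels + (len(AUTOCORR_LAGS) if self.use_autocorrelation else 0)

    @property
    def input_length(self) -> int:
        """Spatial length of the encoded input (the x and y blocks are
        flattened into one channel when ``input_channels`` is 1)."""
        return 2 * self.fixed_length // self.input_channels


def feature_map_widths(x0: int, depth: int) -> List[int]:
    """Doubling width schedule ``[x0, 2*x0, 4*x0, ...]`` of length ``depth``."""
    if x0 < 1 or depth < 1:
        raise ValueError("x0 and depth must be >= 1")
    return [x0 * 2 ** (i - 1) for i in range(1, depth + 1)]


class Network:
    """A built classifier: body -> global pool -> [aux concat] -> dense head."""

    def __init__(self, config: ArchitectureConfig, rng: np.random.Generator):
        self.config = config
        nd = config.dimension
        k = config.kernel
        kern = (k,) * nd
        act = config.activation
        thr = config.activation_threshold
        c_in = config.total_input_channels
        widths = feature_map_widths(config.x0, config.depth)

        def conv(ci, co, kernel, stride, name):
            return nn.Conv(ci, co, kernel, stride=stride, rng=rng, name=name)

        layers: List[nn.Layer] = []
        if config.use_xresnet:
            stem_widths = [max(1, config.x0 // 4), config.x0, config.x0]
            prev = c_in
            for j, w in enumerate(stem_widths):
                layers += [
                    conv(prev, w, kern, 2 if j == 0 else 1, f"stem.conv{j + 1}"),
                    nn.BatchNorm(w, threshold=thr, name=f"stem.bn{j + 1}"),
                    nn.Activation(act, name=f"stem.act{j + 1}"),
                ]
                prev = w
        else:
            layers += [
                conv(c_in, config.x0, (7,) * nd, 2, "stem.conv1"),
                nn.BatchNorm(config.x0, threshold=thr, name="stem.bn1"),
                nn.Activation(act, name="stem.act1"),
            ]
            prev = config.x0
        layers.append(nn.MaxPool(nd, name="stem.maxpool"))

        for i, w in enumerate(widths, start=1):
            for b in range(config.blocks_per_stage):
                stride = 2 if (i > 1 and b == 0) else 1
                tag = f"stage{i}.block{b + 1}"
                main = nn.Sequential(
                    [
                        conv(prev, w, kern, stride, f"{tag}.conv1"),
                        nn.BatchNorm(w, threshold=thr, name=f"{tag}.bn1"),
                        nn.Activation(act, name=f"{tag}.act1"),
                        conv(w, w, kern, 1, f"{tag}.conv2"),
                        nn.BatchNorm(
                            w,
                            threshold=thr,
                            zero_init=config.use_xresnet and config.zero_init_residual,
                            name=f"{tag}.bn2",
                        ),
                    ],
                    name=f"{tag}.main",
                )
                if stride != 1 or prev != w:
                    short_layers: List[nn.Layer] = []
                    if config.use_xresnet:
                        if stride != 1:
                            short_layers.append(nn.AvgPoolStride2(nd, name=f"{tag}.short.pool"))
                        short_layers.append(conv(prev, w, (1,) * nd, 1, f"{tag}.short.conv"))
                    else:
                        short_layers.append(conv(prev, w, (1,) * nd, stride, f"{tag}.short.conv"))
                    short_layers.append(
                        nn.BatchNorm(w, threshold=thr, name=f"{tag}.short.bn")
                    )
                    shortcut: Optional[nn.Sequential] = nn.Sequential(
                        short_layers, name=f"{tag}.short"
                    )
                else:
                    shortcut = None
                layers.append(
                    nn.ResidualBlock(
                        main, shortcut, nn.Activation(act, name=f"{tag}.act2"), name=tag
                    )
                )
                prev = w

        self.body = nn.Sequential(layers, name="body")
        self.pool = nn.GlobalAvgPool(name="head.gap")
        head_in = widths[-1] + len(config.aux_features)
        self.head = nn.Dense(head_in, config.n_classes, rng=rng, name="head.dense")
        self._aux_cache: Optional[np.ndarray] = None

    # -- forward / backward -------------------------------------------------
    def _pool_mask(self, lengths: np.ndarray, L_in: int) -> np.ndarray:
        """Validity mask at the body's output resolution.

        Marks input positions backed by real samples (both coordinate blocks
        in the flattened one-channel layout), then follows the body's
        stride-2 reductions (ceil rounding, a pooled position is valid if
        either parent is).
        """
        cfg = self.config
        n = len(lengths)
        mask = np.zeros((n, L_in), dtype=bool)
        for i, m in enumerate(np.asarray(lengths, dtype=int)):
            if cfg.input_channels == 1:
                mask[i, :m] = True
                mask[i, cfg.fixed_length : cfg.fixed_length + m] = True
            else:
                mask[i, :m] = True
        n_halvings = 2 + max(cfg.depth - 1, 0)
        for _ in range(n_halvings):
            L = mask.shape[1]
            even = L - (L % 2)
            nxt = mask[:, 0:even:2] | mask[:, 1:even:2]
            if L % 2:
                nxt = np.concatenate([nxt, mask[:, -1:]], axis=1)
            mask = nxt
        return mask

    def forward(
        self,
        x: np.ndarray,
        aux: Optional[np.ndarray] = None,
        training: bool = False,
        lengths: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Logits for a batch; softmax is applied by the loss / predictor."""
        n_aux = len(self.config.aux_features)
        if n_aux and (aux is None or aux.shape[1] != n_aux):
            raise ValueError(f"this network expects {n_aux} auxiliary features per sample")
        if (
            lengths is not None
            and self.config.masked_pooling
            and self.config.dimension == 1
        ):
            self.pool.set_mask(self._pool_mask(lengths, x.shape[-1]))
        else:
            self.pool.set_mask(None)
        h = self.body.forward(x.astype(nn.DTYPE, copy=False), training)
        h = self.pool.forward(h, training)
        if n_aux:
            h = np.concatenate([h, aux.astype(nn.DTYPE)], axis=1)
            self._aux_cache = h if training else None
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        if len(self.config.aux_features):
            g = g[:, : -len(self.config.aux_features)]
        g = self.pool.backward(np.ascontiguousarray(g))
        self.body.backward(g)

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> List[nn.Parameter]:
        return self.body.parameters() + self.head.parameters()

    def _norm_layers(self) -> List[nn.BatchNorm]:
        found: List[nn.BatchNorm] = []

        def walk(layer: nn.Layer) -> None:
            if isinstance(layer, nn.BatchNorm):
                found.append(layer)
            elif isinstance(layer, nn.Sequential):
                for sub in layer.layers:
                    walk(sub)
            elif isinstance(layer, nn.ResidualBlock):
                walk(layer.main)
                if layer.shortcut is not None:
                    walk(layer.shortcut)

        walk(self.body)
        return found

    def state(self) -> dict:
        st = {p.name: p.data.copy() for p in self.parameters()}
        for i, bn in enumerate(self._norm_layers()):
            st[f"__running_mean.{i}"] = bn.running_mean.copy()
            st[f"__running_var.{i}"] = bn.running_var.copy()
        return st

    def load_state(self, state: dict) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise ValueError(f"checkpoint is missing parameter {p.name}")
            if state[p.name].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: checkpoint {state[p.name].shape}, "
                    f"network {p.data.shape}"
                )
            p.data[...] = state[p.name]
        for i, bn in enumerate(self._norm_layers()):
            bn.running_mean[...] = state[f"__running_mean.{i}"]
            bn.running_var[...] = state[f"__running_var.{i}"]


def build_network(
    config: ArchitectureConfig, rng: Optional[np.random.Generator] = None
) -> Network:
    """Construct the residual classifier described by ``config``."""
    return Network(config, rng or np.random.default_rng(0))


def count_parameters(network: Network) -> int:
    """Exact number of trainable scalars in the network."""
    return sum(p.size for p in network.parameters())


def describe_network(network: Network) -> List[dict]:
    """Per-parameter audit table: name, shape and scalar count."""
    return [
        {"name": p.name, "shape": list(p.data.shape), "params": int(p.size)}
        for p in network.parameters()
    ]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(network: Network, path: Path) -> None:
    """Single-file checkpoint: weights, running stats and the config."""
    payload = dict(network.state())
    payload["__config__"] = np.frombuffer(
        json.dumps(asdict(network.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path: Path) -> Network:
    """Rebuild a network from a checkpoint, verifying config/weight shapes."""
    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["__config__"].tobytes()).decode())
        cfg_raw["aux_features"] = tuple(cfg_raw["aux_features"])
        config = ArchitectureConfig(**cfg_raw)
        net = build_network(config)
        state = {k: data[k] for k in data.files if k != "__config__"}
    net.load_state(state)
    return net
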