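"""Architecture construction, width schedule and exact parameter counting."""

import json
from importlib import resources

import numpy as np
import pytest

from anomdiff import nn
from anomdiff.model import (
    ArchitectureConfig,
    build_network,
    count_parameters,
    describe_network,
    feature_map_widths,
    load_checkpoint,
    save_checkpoint,
)


def _count(**kw) -> int:
    return count_parameters(build_network(ArchitectureConfig(**kw)))


def analytic_count(x0: int, depth: int, taps: int, xresnet: bool = True,
                   c_in: int = 1, n_classes: int = 4, n_aux: int = 0,
                   stem_taps: int = 7) -> int:
    """Closed-form parameter count, independent of the layer implementation.

    Convolutions carry ``taps * C_in * C_out`` weights (no bias); every norm
    layer carries 3 per-channel parameters (scale, shift, threshold); the
    head is a single dense layer with bias.  The plain (non-XResNet) stem is
    one kernel-7 convolution: 7 taps in 1-D, 49 in 2-D.
    """
    widths = [x0 * 2 ** (i - 1) for i in range(1, depth + 1)]
    total = 0
    if xresnet:
        stem = [max(1, x0 // 4), x0, x0]
        prev = c_in
        for w in stem:
            total += taps * prev * w + 3 * w
            prev = w
    else:
        total += stem_taps * c_in * x0 + 3 * x0
        prev = x0
    for i, w in enumerate(widths):
        for b in range(2):
            total += taps * prev * w + 3 * w  # conv1 + norm
            total += taps * w * w + 3 * w  # conv2 + norm
            if prev != w or (i > 0 and b == 0):
                total += prev * w + 3 * w  # 1x1 projection + norm
            prev = w
    total += (widths[-1] + n_aux) * n_classes + n_classes
    return total


# ---------------------------------------------------------------------------
# width schedule
# ---------------------------------------------------------------------------


def test_feature_map_width_schedule():
    assert feature_map_widths(64, 4) == [64, 128, 256, 512]
    assert feature_map_widths(32, 3) == [32, 64, 128]
    assert feature_map_widths(1, 1) == [1]
    with pytest.raises(ValueError):
        feature_map_widths(0, 3)


# ---------------------------------------------------------------------------
# parameter counts
# ---------------------------------------------------------------------------


def test_final_architecture_count():
    assert _count() == 399_556


def test_counts_match_analytic_formula_across_config_grid():
    for x0, depth, k, xres in [
        (32, 3, 5, True),
        (64, 3, 5, True),
        (16, 3, 5, True),
        (64, 4, 3, True),
        (64, 2, 3, True),
        (64, 4, 3, False),
        (8, 1, 7, True),
    ]:
        built = _count(x0=x0, depth=depth, kernel=k, use_xresnet=xres)
        assert built == analytic_count(x0, depth, k, xresnet=xres, stem_taps=7)
    built_2d = _count(x0=16, depth=2, kernel=3, use_xresnet=False, dimension=2)
    assert built_2d == analytic_count(16, 2, 9, xresnet=False, stem_taps=49)


@pytest.mark.parametrize(
    "kw,expected",
    [
        (dict(x0=64), 1_590_148),
        (dict(x0=16), 100_900),
        (dict(x0=64, kernel=3), 973_668),
        (dict(x0=64, kernel=7), 2_206_628),
        (dict(x0=64, kernel=9), 2_823_108),
        (dict(x0=64, kernel=11), 3_439_588),
        (dict(dimension=2, depth=4, x0=64, kernel=3), 11_220_420),
        (dict(dimension=2, depth=3, x0=64, kernel=3), 2_823_108),
        (dict(dimension=2, depth=2, x0=64, kernel=3), 721_604),
        (dict(dimension=2, depth=3, x0=64, kernel=1), 357_188),
        (dict(use_xresnet=False, dimension=2, depth=4, x0=64, kernel=3), 11_177_092),
    ],
)
def test_published_count_grid(kw, expected):
    assert _count(**kw) == expected


def test_each_aux_feature_costs_four_parameters():
    base = _count()
    assert _count(aux_features=("asymmetry",)) == base + 4
    assert (
        _count(aux_features=("asymmetry", "efficiency", "fractal_dimension", "tamsd_lag20"))
        == base + 16
    )


def test_count_monotonic_in_width_depth_kernel():
    assert _count(x0=16) < _count(x0=32) < _count(x0=64)
    assert _count(depth=2) < _count(depth=3) < _count(depth=4)
    assert _count(kernel=3) < _count(kernel=5) < _count(kernel=7)


def test_dense_layer_count_oracle():
    dense = nn.Dense(128, 4)
    assert sum(p.size for p in dense.parameters()) == 128 * 4 + 4


def test_golden_per_layer_manifest():
    with resources.files("anomdiff").joinpath(
        "data/final_architecture_layers.json"
    ).open() as f:
        golden = json.load(f)
    net = build_network(ArchitectureConfig())
    desc = describe_network(net)
    assert golden["total_parameters"] == 399_556
    assert desc == golden["layers"]
    assert sum(e["params"] for e in desc) == count_parameters(net)


# ---------------------------------------------------------------------------
# construction and forward contracts
# ---------------------------------------------------------------------------


def test_softmax_output_contract(rng):
    net = build_network(ArchitectureConfig(x0=8, depth=2, fixed_length=64), rng)
    x = rng.standard_normal((5, 1, 128)).astype(np.float32)
    probs = nn.softmax(net.forward(x))
    assert probs.shape == (5, 4)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_zeroed_residual_scale_makes_units_identity(rng):
    """With the branch's final norm scale zero, a non-downsampling unit maps
    non-negative inputs (post-activation outputs) to themselves exactly."""
    net = build_network(
        ArchitectureConfig(x0=8, depth=2, fixed_length=64, zero_init_residual=True), rng
    )
    block = next(l for l in net.body.layers if isinstance(l, nn.ResidualBlock))
    assert block.shortcut is None
    assert np.all(block.main.layers[-1].gamma.data == 0)
    x = np.abs(rng.standard_normal((3, 8, 32))).astype(np.float32)
    y = block.forward(x, training=False)
    assert np.allclose(y, x, atol=1e-6)


def test_constructed_widths_follow_schedule():
    net = build_network(ArchitectureConfig(x0=16, depth=3))
    convs = {}
    for layer in net.body.layers:
        if isinstance(layer, nn.ResidualBlock):
            first_conv = layer.main.layers[0]
            convs.setdefault(layer.name.split(".")[0], first_conv.out_channels)
    assert [convs[f"stage{i}"] for i in (1, 2, 3)] == feature_map_widths(16, 3)


def test_eval_forward_is_deterministic(rng):
    net = build_network(ArchitectureConfig(x0=8, depth=2, fixed_length=64), rng)
    x = rng.standard_normal((4, 1, 128)).astype(np.float32)
    a = net.forward(x)
    b = net.forward(x)
    assert np.array_equal(a, b)


def test_aux_features_are_required_when_configured(rng):
    net = build_network(
        ArchitectureConfig(x0=8, depth=2, fixed_length=64, aux_features=("efficiency",)),
        rng,
    )
    x = rng.standard_normal((2, 1, 128)).astype(np.float32)
    with pytest.raises(ValueError, match="auxiliary"):
        net.forward(x)
    out = net.forward(x, aux=np.ones((2, 1), np.float32))
    assert out.shape == (2, 4)


def test_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        ArchitectureConfig(kernel=4)


def test_checkpoint_round_trip(tmp_path, rng):
    cfg = ArchitectureConfig(x0=8, depth=2, fixed_length=64)
    net = build_network(cfg, rng)
    x = rng.standard_normal((3, 1, 128)).astype(np.float32)
    before = net.forward(x)
    path = tmp_path / "model.npz"
    save_checkpoint(net, path)
    restored = load_checkpoint(path)
    assert restored.config == cfg
    assert np.allclose(restored.forward(x), before, atol=1e-7)
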