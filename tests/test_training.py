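"""Tests of the training loop, selective backprop and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anomdiff.dataset import LabeledDataset, Record, stratified_split
from anomdiff.model import ArchitectureConfig, build_network
from anomdiff.simulate import (
    ModelParams,
    SimulationConfig,
    drift_speed_from_ratio,
    sample_model_params,
    simulate,
    simulate_dm,
    simulate_nd,
)
from anomdiff.training import (
    TrainConfig,
    predict,
    select_backprop_subset,
    train,
)


# ---------------------------------------------------------------------------
# selective backprop subset selection
# ---------------------------------------------------------------------------


def test_loss_coverage_prefix_by_hand():
    losses = np.array([0.7, 0.2, 0.08, 0.02])
    sel = select_backprop_subset(losses, ("loss_coverage", 0.98))
    assert list(sel) == [0, 1, 2]


def test_top_fraction_takes_largest():
    sel = select_backprop_subset(np.array([0.1, 0.9, 0.5, 0.7]), ("top_fraction", 0.5))
    assert list(sel) == [1, 3]


def test_full_coverage_and_none_keep_everything():
    losses = np.array([0.3, 0.3, 0.4])
    assert list(select_backprop_subset(losses, ("loss_coverage", 1.0))) == [0, 1, 2]
    assert list(select_backprop_subset(losses, None)) == [0, 1, 2]
    # all-zero losses: coverage mode falls back to the full batch
    assert list(select_backprop_subset(np.zeros(4), ("loss_coverage", 0.98))) == [0, 1, 2, 3]


def test_ties_break_on_original_index():
    sel = select_backprop_subset(np.array([0.5, 0.5, 0.5, 0.5]), ("top_fraction", 0.5))
    assert list(sel) == [0, 1]


@given(
    losses=st.lists(
        st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        min_size=1,
        max_size=50,
    ),
    frac=st.floats(min_value=0.05, max_value=1.0),
)
@settings(deadline=None, derandomize=True, max_examples=200)
def test_loss_coverage_prefix_is_shortest_sufficient(losses, frac):
    """The selected prefix covers the requested loss share, and no strictly
    shorter descending-loss prefix would."""
    arr = np.array(losses)
    sel = select_backprop_subset(arr, ("loss_coverage", frac))
    total = arr.sum()
    tol = 1e-9 * max(total, 1.0)
    assert arr[sel].sum() >= frac * total - tol
    if total > 0 and len(sel) > 1:
        smallest = arr[sel].min()
        assert arr[sel].sum() - smallest < frac * total + tol


@given(
    losses=st.lists(
        st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        min_size=1,
        max_size=50,
    ),
    frac=st.floats(min_value=0.05, max_value=1.0),
)
@settings(deadline=None, derandomize=True, max_examples=200)
def test_top_fraction_size_and_membership(losses, frac):
    """top_fraction keeps exactly ceil(f*n) samples, none of which has a
    smaller loss than any excluded sample."""
    arr = np.array(losses)
    sel = select_backprop_subset(arr, ("top_fraction", frac))
    import math

    assert len(sel) == math.ceil(frac * len(arr))
    excluded = np.setdiff1d(np.arange(len(arr)), sel)
    if len(excluded):
        assert arr[sel].min() >= arr[excluded].max() - 1e-12


# ---------------------------------------------------------------------------
# training on a tiny separable problem
# ---------------------------------------------------------------------------


def _easy_two_class_dataset(n_per_class=50, N=100, seed=0):
    """Noiseless ND vs strongly drifting DM: separable by the drift."""
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for kind in ("ND", "DM"):
        for _ in range(n_per_class):
            if kind == "ND":
                p = ModelParams(kind="ND", D=1.0, N=N, dt=1 / 30)
                traj = simulate_nd(p, rng)
            else:
                v = drift_speed_from_ratio(17.0, 1.0, N / 30)
                p = ModelParams(
                    kind="DM", D=1.0, N=N, dt=1 / 30, v=v,
                    beta=float(rng.uniform(0, 2 * np.pi)),
                )
                traj = simulate_dm(p, rng)
            records.append(Record(f"{i:06d}", traj, kind, None, p))
            i += 1
    ds = LabeledDataset(records)
    return stratified_split(ds, (0.7, 0.15, 0.15), np.random.default_rng(seed))


_TINY_ARCH = ArchitectureConfig(x0=8, depth=2, fixed_length=100)


def test_overfits_separable_two_class_problem():
    ds = _easy_two_class_dataset()
    arch = ArchitectureConfig(x0=16, depth=2, fixed_length=100)
    net = build_network(arch, np.random.default_rng(1))
    cfg = TrainConfig(batch_size=16, learning_rate=1e-3, max_epochs=30, seed=1)
    hist = train(net, ds, cfg)
    assert max(hist.train_accuracy) >= 0.99


def test_single_epoch_best_epoch_is_one():
    ds = _easy_two_class_dataset(n_per_class=10, N=40)
    net = build_network(ArchitectureConfig(x0=4, depth=2, fixed_length=40))
    hist = train(net, ds, TrainConfig(batch_size=8, max_epochs=1, seed=0))
    assert hist.best_epoch == 1
    assert len(hist.val_accuracy) == 1


def test_training_is_deterministic():
    ds = _easy_two_class_dataset(n_per_class=10, N=40)
    outs = []
    for _ in range(2):
        net = build_network(ArchitectureConfig(x0=4, depth=2, fixed_length=40),
                            np.random.default_rng(3))
        hist = train(net, ds, TrainConfig(batch_size=8, max_epochs=2, seed=3))
        outs.append((hist.val_accuracy, net.state()))
    assert outs[0][0] == outs[1][0]
    for k in outs[0][1]:
        assert np.array_equal(outs[0][1][k], outs[1][1][k])


def test_every_sample_visited_once_per_epoch_without_selection():
    ds = _easy_two_class_dataset(n_per_class=10, N=40)
    net = build_network(ArchitectureConfig(x0=4, depth=2, fixed_length=40))
    hist = train(net, ds, TrainConfig(batch_size=6, max_epochs=2, seed=0))
    assert hist.bp_fraction == [1.0, 1.0]


def test_empty_split_is_rejected():
    ds = _easy_two_class_dataset(n_per_class=4, N=40)
    for r in ds.records:
        if r.split == "validation":
            r.split = "test"
    net = build_network(ArchitectureConfig(x0=4, depth=2, fixed_length=40))
    with pytest.raises(ValueError, match="split"):
        train(net, ds, TrainConfig(batch_size=4, max_epochs=1))


# ---------------------------------------------------------------------------
# prediction contracts
# ---------------------------------------------------------------------------


def test_predict_rows_are_probabilities(rng):
    config = SimulationConfig(range_N=(30, 50))
    trajs = []
    for kind in ("ND", "CD"):
        p = sample_model_params(kind, config, rng)
        trajs.append(simulate(p, rng))
    net = build_network(ArchitectureConfig(x0=4, depth=2, fixed_length=64))
    probs = predict(net, trajs)
    assert probs.shape == (2, 4)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_duplicated_inputs_give_identical_rows(rng):
    p = sample_model_params("ND", SimulationConfig(range_N=(40, 40)), rng)
    traj = simulate(p, rng)
    net = build_network(ArchitectureConfig(x0=4, depth=2, fixed_length=64))
    probs = predict(net, [traj, traj, traj])
    assert np.allclose(probs[0], probs[1]) and np.allclose(probs[1], probs[2])


# ---------------------------------------------------------------------------
# scaled-down run properties (shared session fixtures)
# ---------------------------------------------------------------------------


def test_selective_coverage_uses_strict_subset_after_warmup(selective_training):
    _, hist = selective_training
    assert all(f < 1.0 for f in hist.bp_fraction[3:])


def test_mse_and_cross_entropy_both_train_well(
    scaled_training, cross_entropy_training
):
    """Cost-function choice barely moves validation accuracy: on the shared
    scaled-down run both costs clear the run's accuracy bar and land within a
    few points of each other."""
    _, hist_mse = scaled_training
    _, hist_ce = cross_entropy_training
    best_mse = max(hist_mse.val_accuracy)
    best_ce = max(hist_ce.val_accuracy)
    assert best_mse >= 0.80
    assert best_ce >= 0.80
    assert abs(best_mse - best_ce) <= 0.06
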