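"""Compare plain training with 98%-loss-coverage selective backprop.

Selective backprop propagates gradients only for the highest-loss samples of
each batch (here: the shortest descending-loss prefix covering 98% of the
batch loss).  As training progresses the easy samples drop out, so the
back-propagated fraction falls below 1 while validation accuracy stays
within a couple of points of the plain run.
"""

import numpy as np

from anomdiff.dataset import generate_dataset
from anomdiff.model import ArchitectureConfig, build_network
from anomdiff.simulate import SimulationConfig
from anomdiff.training import TrainConfig, train

dataset = generate_dataset(SimulationConfig(n_per_class=100, range_N=(30, 200), seed=2))
arch = ArchitectureConfig(fixed_length=200)

for mode in (None, ("loss_coverage", 0.98)):
    net = build_network(arch, np.random.default_rng(2))
    hist = train(
        net, dataset, TrainConfig(batch_size=32, max_epochs=8, selective_mode=mode, seed=2)
    )
    label = "plain" if mode is None else "selective(0.98)"
    print(f"{label:16s} best val acc {max(hist.val_accuracy):.3f} "
          f"bp fractions {[round(f, 2) for f in hist.bp_fraction]}")
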