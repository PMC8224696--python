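"""Small end-to-end run: simulate, train, evaluate on the held-out split.

Uses a reduced corpus (100 trajectories per class, lengths 30-200) and a
narrow network so it finishes in about a minute; the printed report has the
same shape as a full run (confusion matrix rows/columns ordered FBM, CD, DM,
ND; per-class recall; overall accuracy).
"""

import numpy as np

from anomdiff.dataset import generate_dataset
from anomdiff.evaluation import classification_metrics, confusion_matrix
from anomdiff.model import ArchitectureConfig, build_network
from anomdiff.simulate import CLASSES, SimulationConfig
from anomdiff.training import TrainConfig, predict, train

sim = SimulationConfig(n_per_class=100, range_N=(30, 200), seed=1)
dataset = generate_dataset(sim)
arch = ArchitectureConfig(fixed_length=200)
net = build_network(arch, np.random.default_rng(1))
history = train(net, dataset, TrainConfig(batch_size=32, max_epochs=8, seed=1))

print("validation accuracy per epoch:",
      " ".join(f"{v:.2f}" for v in history.val_accuracy))
print("best epoch:", history.best_epoch)

test = dataset.subset("test")
probs = predict(net, test.trajectories())
pred = [CLASSES[i] for i in probs.argmax(axis=1)]
report = classification_metrics(confusion_matrix(test.labels(), pred))
print("test confusion (rows true / cols predicted, FBM CD DM ND):")
print(report.confusion)
print("test accuracy:", f"{report.accuracy:.3f}")
print("per-class recall:", {k: round(v, 3) for k, v in report.recall.items()})
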