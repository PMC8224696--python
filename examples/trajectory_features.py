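"""Auxiliary scalar features of simulated trajectories.

Asymmetry (gyration-tensor elongation), efficiency (net displacement share),
Katz fractal dimension and the TAMSD at lag 20 frames are the four scalars
that can optionally join the network head.  Directed motion tends to high
efficiency and low fractal dimension; confined diffusion the opposite — but
the distributions overlap, which is why they add little to the classifier.
"""

import numpy as np

from anomdiff.features import compute_features
from anomdiff.simulate import CLASSES, SimulationConfig, sample_model_params, simulate

rng = np.random.default_rng(4)
config = SimulationConfig(range_N=(100, 300))

print(f"{'mode':5s} {'asymmetry':>10s} {'efficiency':>11s} {'fractal_dim':>12s} {'tamsd20':>9s}")
for kind in CLASSES:
    params = sample_model_params(kind, config, rng)
    fv = compute_features(simulate(params, rng))
    print(
        f"{kind:5s} {fv.asymmetry:10.3f} {fv.efficiency:11.4f} "
        f"{fv.fractal_dimension:12.3f} {fv.tamsd_lag20:9.3f}"
    )
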