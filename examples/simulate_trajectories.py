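"""Simulate one trajectory per diffusion mode and fit its anomalous exponent.

The fitted TAMSD exponent alpha separates the modes: confined diffusion and
subdiffusive FBM give alpha < 1, normal diffusion alpha ~ 1, directed motion
alpha > 1 (up to 2 for drift-dominated paths).
"""

import numpy as np

from anomdiff.features import fit_anomalous_exponent
from anomdiff.simulate import CLASSES, SimulationConfig, sample_model_params, simulate

config = SimulationConfig(range_N=(300, 600))
rng = np.random.default_rng(0)

print(f"{'mode':5s} {'N':>4s} {'D [um^2/s]':>11s} {'alpha_fit':>10s}")
for kind in CLASSES:
    params = sample_model_params(kind, config, rng)
    traj = simulate(params, rng)
    fit = fit_anomalous_exponent(traj, max_lag=30)
    print(f"{kind:5s} {params.N:4d} {params.D:11.2f} {fit.alpha:10.2f}")
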