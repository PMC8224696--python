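"""Build the reduced residual classifier and audit its parameter budget.

Prints the per-layer parameter table of the final 1-D configuration (depth 3,
32 base feature maps, kernel 5) whose total is 399,556 trainable scalars, and
shows how the count scales with width and with auxiliary head features.
"""

from anomdiff.model import (
    ArchitectureConfig,
    build_network,
    count_parameters,
    describe_network,
)

net = build_network(ArchitectureConfig())
for entry in describe_network(net):
    print(f"{entry['name']:40s} {str(entry['shape']):>14s} {entry['params']:>9d}")
print(f"{'TOTAL':40s} {'':>14s} {count_parameters(net):>9d}")

print("\nwidth scaling (base feature maps -> parameters):")
for x0 in (16, 32, 64):
    n = count_parameters(build_network(ArchitectureConfig(x0=x0)))
    print(f"  x0={x0:3d}: {n:>9,d}")

print("\nauxiliary head features add 4 parameters each:")
for aux in [(), ("asymmetry",), ("asymmetry", "efficiency", "fractal_dimension", "tamsd_lag20")]:
    n = count_parameters(build_network(ArchitectureConfig(aux_features=aux)))
    print(f"  {len(aux)} features: {n:,d}")
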