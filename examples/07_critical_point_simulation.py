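"""Simulated critical transmission rate by finite-size scaling.

For each network size, the pseudo-threshold is where quasi-stationary
prevalence is sustained (no extinction over the window); extrapolating the
pseudo-thresholds linearly in 1/N estimates the infinite-network critical
point.  ODE thresholds of the closure families bracket it from below.
"""

import numpy as np

from sisnet import (EpidemicParams, build_k3_motif_family,
                    build_neighbourhood_family, critical_tau_ode,
                    critical_tau_simulation)

print("ODE thresholds, k = 3, gamma = 1:")
for label, build in [
        ("mean-field (m=1)", lambda t: build_k3_motif_family(1, 1e4, EpidemicParams(t, 1.0))),
        ("pairwise  (m=2) ", lambda t: build_k3_motif_family(2, 1e4, EpidemicParams(t, 1.0))),
        ("motif m=3       ", lambda t: build_k3_motif_family(3, 1e4, EpidemicParams(t, 1.0))),
        ("motif m=4       ", lambda t: build_k3_motif_family(4, 1e4, EpidemicParams(t, 1.0))),
        ("nbhd  n=2       ", lambda t: build_neighbourhood_family(2, 1e4, 3, EpidemicParams(t, 1.0))),
        ("nbhd  n=3       ", lambda t: build_neighbourhood_family(3, 1e4, 3, EpidemicParams(t, 1.0)))]:
    tc = critical_tau_ode(build, bracket=(0.2, 0.8), tol=1e-3, method="growth")
    print(f"  {label}: tau_c = {tc:.3f}")

est = critical_tau_simulation(3, 1.0, sizes=[2000, 5000, 10000, 20000],
                              tau_grid=np.arange(0.50, 0.601, 0.01), seed=1)
print(f"\nfinite-size-scaling simulation estimate: "
      f"tau_C = {est.tau_c:.3f} +- {est.uncertainty:.3f}")
print("per-size pseudo-thresholds:",
      {n: round(v, 3) for n, v in est.per_size.items()})
print("\nThe closure thresholds increase with order toward the simulated")
print("critical point; the mean-field value gamma/k = 1/3 is far too low.")
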